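"""Core data containers for polarization imaging.

A qBRM acquisition is an ordered set of camera frames, one per
illumination-polarizer angle; the containers here carry the frames, the
angle metadata, and the optical-train parameters needed to simulate or
invert them.  Angles are degrees everywhere in the public API; radians
appear only inside trigonometric kernels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["SpecimenMap", "OpticalTrain", "PolStack", "read_stack", "write_stack"]


@dataclass(frozen=True)
class SpecimenMap:
    """Ground-truth birefringence description of a thin section.

    Parameters
    ----------
    transmittance : ndarray
        Per-pixel DC intensity ``I0`` (arbitrary units, >= 0).
    retardance_waves : ndarray
        Per-pixel phase retardance ``delta`` in waves of optical path
        difference (>= 0).  The measurable quantity is ``|sin(2*pi*delta)|``.
    orientation_deg : ndarray
        In-plane optic-axis orientation ``phi`` in degrees, stored in
        ``[0, 180)``.
    inclination_deg : ndarray, optional
        Out-of-plane tilt of the optic axis in degrees (0 = in-plane).
        When present, the effective in-plane retardance is reduced by
        ``cos^2`` of the inclination before simulation.
    """

    transmittance: np.ndarray
    retardance_waves: np.ndarray
    orientation_deg: np.ndarray
    inclination_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.transmittance, dtype=float)
        d = np.asarray(self.retardance_waves, dtype=float)
        o = np.asarray(self.orientation_deg, dtype=float) % 180.0
        object.__setattr__(self, "transmittance", t)
        object.__setattr__(self, "retardance_waves", d)
        object.__setattr__(self, "orientation_deg", o)
        if self.inclination_deg is not None:
            inc = np.asarray(self.inclination_deg, dtype=float)
            object.__setattr__(self, "inclination_deg", inc)
        if np.any(t < 0):
            raise ValueError("transmittance must be nonnegative")
        if np.any(d < 0):
            raise ValueError("retardance_waves must be nonnegative")
        shapes = {t.shape, d.shape, o.shape}
        if self.inclination_deg is not None:
            shapes.add(self.inclination_deg.shape)
        if len(shapes) != 1:
            raise ValueError(f"specimen rasters must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.transmittance.shape

    @classmethod
    def uniform(cls, shape, transmittance, retardance_waves, orientation_deg,
                inclination_deg=None) -> "SpecimenMap":
        """Build a spatially uniform specimen (convenience for tests/demos)."""
        full = lambda v: np.full(shape, float(v))
        inc = None if inclination_deg is None else full(inclination_deg)
        return cls(full(transmittance), full(retardance_waves),
                   full(orientation_deg), inc)


@dataclass(frozen=True)
class OpticalTrain:
    """Illumination/detection configuration of the polarization microscope.

    ``analyzer_error_waves`` is the deviation of the detection quarter-wave
    plate from exact quarter-wave retardance; 0 gives an ideal circular
    analyzer and the closed-form intensity law exactly.  ``photon_budget``
    is the expected photon count for a pixel of unit intensity (shot-noise
    scale); ``read_noise`` is the additive Gaussian sigma in counts.
    """

    angles_deg: tuple = (0.0, 60.0, 120.0)
    wavelength_nm: float = 625.0
    analyzer_error_waves: float = 0.0
    photon_budget: float = 1e4
    read_noise: float = 2.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles_deg", tuple(float(a) for a in self.angles_deg))
        if len(self.angles_deg) == 0:
            raise ValueError("angles_deg must be nonempty")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        if self.read_noise < 0:
            raise ValueError("read_noise must be nonnegative")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be a positive integer")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


_KINDS = ("sample", "background", "corrected")


@dataclass(frozen=True)
class PolStack:
    """Ordered polarization frames with their illumination angles.

    ``kind`` distinguishes raw sample/background acquisitions (nonnegative
    intensities) from background-corrected stacks, whose mean-subtracted
    sinusoid may legitimately go negative.
    """

    frames: np.ndarray  # (n_angles, H, W)
    angles_deg: tuple
    kind: str = "sample"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=float)
        if fr.ndim == 2:
            fr = fr[None]
        object.__setattr__(self, "frames", fr)
        object.__setattr__(self, "angles_deg", tuple(float(a) for a in self.angles_deg))
        if fr.ndim != 3:
            raise ValueError("frames must be a (n_angles, H, W) array")
        if fr.shape[0] != len(self.angles_deg):
            raise ValueError(
                f"{fr.shape[0]} frames but {len(self.angles_deg)} angles")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.kind != "corrected" and np.any(fr < 0):
            raise ValueError(f"{self.kind} stacks may not contain negative values")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame(self, angle_deg: float, atol: float = 1e-6) -> np.ndarray:
        """Return the frame acquired at ``angle_deg`` (within ``atol``)."""
        for a, f in zip(self.angles_deg, self.frames):
            if abs(a - angle_deg) <= atol:
                return f
        raise KeyError(f"no frame at {angle_deg} deg in {self.angles_deg}")

    def with_kind(self, kind: str) -> "PolStack":
        return replace(self, kind=kind)


def write_stack(path, stack: PolStack, train: OpticalTrain | None = None) -> None:
    """Write a stack as a multi-page float32 TIFF plus a YAML sidecar.

    The sidecar (``<stem>.yaml``) records the angle list, kind, and — when a
    train is given — wavelength, seed and noise parameters, so the stack is
    self-describing for downstream inversion.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "angles_deg": list(stack.angles_deg),
        "kind": stack.kind,
    }
    if train is not None:
        meta.update(
            wavelength_nm=train.wavelength_nm,
            analyzer_error_waves=train.analyzer_error_waves,
            photon_budget=train.photon_budget,
            read_noise=train.read_noise,
            bit_depth=train.bit_depth,
            seed=train.seed,
        )
    meta.update(stack.meta)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_stack(path) -> PolStack:
    """Read a multi-page TIFF stack and its YAML/JSON sidecar."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = None
    for suffix in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(suffix)
        if cand.exists():
            sidecar = cand
            break
    if sidecar is None:
        raise FileNotFoundError(
            f"missing angle metadata sidecar (.yaml/.json) for {path}")
    if sidecar.suffix == ".json":
        meta = json.loads(sidecar.read_text())
    else:
        meta = yaml.safe_load(sidecar.read_text())
    angles = meta.pop("angles_deg")
    kind = meta.pop("kind", "sample")
    return PolStack(frames, tuple(angles), kind=kind, meta=meta)
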