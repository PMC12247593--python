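"""Myelin-like synthetic phantoms with per-pixel ground truth.

Myelin sheaths are birefringent with an optic axis radial to the axon, so
in a thin section:

* an axon running **in** the section plane ("longitudinal") shows
  retardance only along the two edge bands of its sheath, where the radial
  axis has an in-plane component perpendicular to the axon direction; over
  the top of the sheath the axis points out of plane and contributes no
  in-plane contrast;
* an axon cut **across** ("transverse"), and likewise a spherical lipid
  vesicle formed by degenerating myelin, appears as an annulus whose
  optic-axis orientation rotates radially around the ring.

The generator rasterises lists of such primitives into a
:class:`~qbrm.stack.SpecimenMap` plus the ground-truth parameter maps the
inversion should recover, so the entire simulate -> invert -> quantify
pipeline can be validated without microscope data.  Degradation scenarios
emulate myelin damage: scaling down axonal retardance, sprinkling seeded
vesicles, and jittering the local optic-axis orientation.  Everything is a
pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .stack import SpecimenMap

__all__ = [
    "LongitudinalAxon",
    "TransverseAxon",
    "Vesicle",
    "PhantomSpec",
    "Phantom",
    "DegradationScenario",
    "generate_phantom",
    "apply_degradation",
    "generate_zstack",
]

#: Default peak retardance (waves) for axon sheaths.  Kept below 0.25 waves
#: so |sin(2*pi*delta)| is monotone in delta, as expected of thin sections.
DEFAULT_DELTA_PEAK = 0.08


@dataclass(frozen=True)
class LongitudinalAxon:
    """In-plane axon segment: two parallel birefringent edge bands."""
    center: tuple[float, float]        # (row, col)
    length: float                      # px
    direction_deg: float               # axon direction in the image plane
    outer_radius: float                # px, sheath outer radius
    sheath_thickness: float            # px, edge-band width
    delta_peak: float = DEFAULT_DELTA_PEAK
    focal_plane: int = 0

    def validate(self) -> None:
        if self.outer_radius < 1.0 or self.sheath_thickness < 1.0:
            raise ValueError(
                "axon radius and sheath thickness must be at least one pixel")
        if self.delta_peak < 0:
            raise ValueError("delta_peak must be nonnegative")


@dataclass(frozen=True)
class TransverseAxon:
    """Axon cut across the section: an annulus with radial optic axis."""
    center: tuple[float, float]
    radius: float
    thickness: float
    delta_peak: float = DEFAULT_DELTA_PEAK
    focal_plane: int = 0

    def validate(self) -> None:
        if self.radius < 1.0 or self.thickness < 1.0:
            raise ValueError("annulus radius/thickness must be at least one pixel")
        if self.delta_peak < 0:
            raise ValueError("delta_peak must be nonnegative")


@dataclass(frozen=True)
class Vesicle(TransverseAxon):
    """Spherical lipid vesicle — geometrically an annulus, like a
    transverse axon, but tagged separately because degradation scenarios
    add vesicles rather than axons."""


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description: raster shape, primitives, and z-stack layout."""
    shape: tuple[int, int] = (128, 128)
    structures: tuple = ()
    background_transmittance: float = 1.0
    n_z_planes: int = 1
    z_step_um: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "structures", tuple(self.structures))
        if self.background_transmittance < 0:
            raise ValueError("background_transmittance must be nonnegative")
        if self.n_z_planes < 1 or self.z_step_um <= 0:
            raise ValueError("need n_z_planes >= 1 and positive z_step_um")


@dataclass(frozen=True)
class DegradationScenario:
    """Myelin-damage emulation: retardance loss, vesicles, axis disorder."""
    retardance_scale: float = 1.0
    vesicle_count: int = 0
    orientation_jitter_deg: float = 0.0
    vesicle_radius: float = 6.0
    vesicle_thickness: float = 2.0
    vesicle_delta_peak: float = DEFAULT_DELTA_PEAK

    def __post_init__(self):
        if not 0.0 <= self.retardance_scale <= 1.0:
            raise ValueError("retardance_scale must lie in [0, 1]")
        if self.vesicle_count < 0 or self.orientation_jitter_deg < 0:
            raise ValueError("vesicle_count and jitter must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return (self.retardance_scale == 1.0 and self.vesicle_count == 0
                and self.orientation_jitter_deg == 0.0)


@dataclass(frozen=True)
class Phantom:
    """Rasterised scene: the specimen to image plus its ground truth."""
    spec: PhantomSpec
    specimen: SpecimenMap
    axon_mask: np.ndarray        # pixels contributed by axons (not vesicles)
    structure_mask: np.ndarray   # any birefringent pixel
    focal_plane_idx: np.ndarray  # per-pixel focal plane (int, -1 = background)

    @property
    def ground_truth(self) -> dict:
        """Maps the inversion should recover: I0, |sin(2*pi*delta)|, phi."""
        return {
            "transmittance": self.specimen.transmittance,
            "retardance": np.abs(
                np.sin(2 * np.pi * self.specimen.retardance_waves)),
            "orientation_deg": self.specimen.orientation_deg,
        }


def _grid(shape):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return rr.astype(float), cc.astype(float)


def _paint_longitudinal(delta, phi, mask, s: LongitudinalAxon):
    rr, cc = _grid(delta.shape)
    ang = np.deg2rad(s.direction_deg)
    # axon direction unit vector (row, col); image rows grow downward but
    # orientation bookkeeping is self-consistent as long as rasteriser and
    # ground truth share it.
    dr, dc = np.sin(ang), np.cos(ang)
    relr, relc = rr - s.center[0], cc - s.center[1]
    along = relr * dr + relc * dc
    across = np.abs(-relr * dc + relc * dr)   # distance from center line
    inner = s.outer_radius - s.sheath_thickness
    band = ((np.abs(along) <= s.length / 2.0)
            & (across <= s.outer_radius) & (across >= inner))
    delta[band] = s.delta_peak
    # radial optic axis projected in-plane: perpendicular to the axon
    phi[band] = (s.direction_deg + 90.0) % 180.0
    mask[band] = True


def _paint_annulus(delta, phi, mask, s: TransverseAxon):
    rr, cc = _grid(delta.shape)
    relr, relc = rr - s.center[0], cc - s.center[1]
    dist = np.hypot(relr, relc)
    band = (dist <= s.radius) & (dist >= s.radius - s.thickness)
    delta[band] = s.delta_peak
    # radial axis: polar angle of the pixel about the center, mod 180
    polar = np.rad2deg(np.arctan2(relr, relc)) % 180.0
    phi[band] = polar[band]
    mask[band] = True


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise a phantom scene with its ground truth.

    Later structures overwrite earlier ones where they overlap.  An empty
    structure list yields a uniform background with zero retardance.
    """
    for s in spec.structures:
        s.validate()
    delta = np.zeros(spec.shape)
    phi = np.zeros(spec.shape)
    axon_mask = np.zeros(spec.shape, dtype=bool)
    struct_mask = np.zeros(spec.shape, dtype=bool)
    focal = np.full(spec.shape, -1, dtype=int)
    for s in spec.structures:
        here = np.zeros(spec.shape, dtype=bool)
        if isinstance(s, LongitudinalAxon):
            _paint_longitudinal(delta, phi, here, s)
        elif isinstance(s, TransverseAxon):  # includes Vesicle
            _paint_annulus(delta, phi, here, s)
        else:
            raise TypeError(f"unknown structure type {type(s).__name__}")
        struct_mask |= here
        focal[here] = s.focal_plane
        # later structures overwrite: a vesicle claims pixels away from axons
        axon_mask[here] = not isinstance(s, Vesicle)
    trans = np.full(spec.shape, float(spec.background_transmittance))
    specimen = SpecimenMap(trans, delta, phi)
    return Phantom(spec, specimen, axon_mask, struct_mask, focal)


def apply_degradation(phantom: Phantom, scenario: DegradationScenario,
                      seed: int) -> Phantom:
    """Apply a damage scenario, deterministically under ``seed``.

    Axon ``delta_peak`` values are multiplied by ``retardance_scale``;
    ``vesicle_count`` vesicles are added at uniform random positions; and
    per-pixel Gaussian orientation jitter (sigma =
    ``orientation_jitter_deg``) is added on structure pixels.  The scene is
    re-rasterised from the modified spec, so the identity scenario
    reproduces the input bit for bit.
    """
    if scenario.is_identity:
        return phantom
    rng = np.random.default_rng(seed)
    structures = []
    for s in phantom.spec.structures:
        if isinstance(s, Vesicle) or not isinstance(
                s, (LongitudinalAxon, TransverseAxon)):
            structures.append(s)
        else:
            structures.append(replace(
                s, delta_peak=s.delta_peak * scenario.retardance_scale))
    h, w = phantom.spec.shape
    for _ in range(scenario.vesicle_count):
        r = scenario.vesicle_radius
        center = (float(rng.uniform(r, h - r)), float(rng.uniform(r, w - r)))
        structures.append(Vesicle(center, scenario.vesicle_radius,
                                  scenario.vesicle_thickness,
                                  scenario.vesicle_delta_peak))
    degraded = generate_phantom(replace(phantom.spec,
                                        structures=tuple(structures)))
    if scenario.orientation_jitter_deg > 0:
        jitter = rng.normal(0.0, scenario.orientation_jitter_deg,
                            size=phantom.spec.shape)
        phi = degraded.specimen.orientation_deg.copy()
        phi[degraded.structure_mask] = (
            phi[degraded.structure_mask]
            + jitter[degraded.structure_mask]) % 180.0
        degraded = replace(degraded, specimen=SpecimenMap(
            degraded.specimen.transmittance,
            degraded.specimen.retardance_waves, phi))
    return degraded


def generate_zstack(phantom: Phantom, blur_um_per_um: float = 0.8):
    """Render per-plane specimens for a through-focus stack.

    Each structure sits at its ``focal_plane``; in plane ``z`` its
    contribution is Gaussian-blurred with sigma proportional to the defocus
    distance ``|z - focal| * z_step_um`` (a simple defocus stand-in — no
    diffraction PSF).  Returns a list of :class:`SpecimenMap`, one per
    plane.
    """
    spec = phantom.spec
    planes = []
    for z in range(spec.n_z_planes):
        delta = np.zeros(spec.shape)
        phi_x = np.zeros(spec.shape)
        phi_y = np.zeros(spec.shape)
        for s in spec.structures:
            d = np.zeros(spec.shape)
            p = np.zeros(spec.shape)
            m = np.zeros(spec.shape, dtype=bool)
            if isinstance(s, LongitudinalAxon):
                _paint_longitudinal(d, p, m, s)
            else:
                _paint_annulus(d, p, m, s)
            sigma = blur_um_per_um * abs(z - s.focal_plane) * spec.z_step_um
            if sigma > 0:
                d = ndimage.gaussian_filter(d, sigma)
            delta += d
            # orientation blended via doubled-angle vector average
            two = np.deg2rad(2 * p)
            wx, wy = d * np.cos(two), d * np.sin(two)
            phi_x += wx
            phi_y += wy
        phi = (np.rad2deg(np.arctan2(phi_y, phi_x)) / 2.0) % 180.0
        trans = np.full(spec.shape, float(spec.background_transmittance))
        planes.append(SpecimenMap(trans, delta, phi))
    return planes
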