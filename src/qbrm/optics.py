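"""Jones-calculus forward model for birefringence microscopy.

Two acquisition geometries are simulated for a thin linear-retarder
specimen characterised per pixel by transmittance ``I0``, phase retardance
``delta`` (waves) and in-plane optic-axis orientation ``phi``:

* **qBRM** — linearly polarized illumination at angle ``theta``, detected
  through a circular analyzer.  With an ideal analyzer the intensity is

      I(theta) = I0/2 * [1 + sin(2(theta - phi)) * sin(2*pi*delta)]

  a sinusoid in ``2*theta`` whose DC, amplitude and phase encode the three
  birefringence parameters.

* **CCP** — crossed circular polarizers of opposite handedness on either
  side of the specimen, giving ``I = I0 * sin^2(pi*delta)`` independent of
  the optic-axis orientation (extinction at zero retardance).

Handedness conventions are fixed internally: right-circular illumination
for CCP and the analyzer circular state ``(1, -i)/sqrt(2)``, which yields
the ``+`` sign in the sinusoid above.  Only intensities are observable, so
the choice is a documentation matter, not a parameter.

An imperfect detection quarter-wave plate (retardance ``0.25 + e`` waves,
``e`` = ``OpticalTrain.analyzer_error_waves``) turns the circular analyzer
elliptical; the full Jones product is then evaluated, which is how
instrument "system birefringence" is emulated.
"""

from __future__ import annotations

import numpy as np

from .stack import OpticalTrain, PolStack, SpecimenMap

__all__ = [
    "eval_intensity",
    "simulate_qbrm",
    "simulate_ccp",
    "compose_layers",
    "project_inclination",
    "retarder_jones",
]

# Sign of the sinusoid term, set by the analyzer handedness; the inversion
# module imports it so the forward model and inversion always agree.
SINUSOID_SIGN = +1.0


def eval_intensity(transmittance, retardance_waves, orientation_deg, theta_deg):
    """Closed-form qBRM intensity for an ideal circular analyzer.

    All arguments broadcast; angles are degrees.  Raises on negative
    transmittance.
    """
    I0 = np.asarray(transmittance, dtype=float)
    if np.any(I0 < 0):
        raise ValueError("transmittance must be nonnegative")
    delta = np.asarray(retardance_waves, dtype=float)
    phi = np.deg2rad(np.asarray(orientation_deg, dtype=float))
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    out = I0 / 2.0 * (1.0 + SINUSOID_SIGN * np.sin(2.0 * (theta - phi))
                      * np.sin(2.0 * np.pi * delta))
    return out if out.ndim else float(out)


def retarder_jones(orientation_deg, retardance_waves):
    """Jones matrix of a linear retarder, as four broadcastable components.

    Returns ``(j00, j01, j10, j11)`` of
    ``cos(G/2)*I + i*sin(G/2)*(cos(2phi)*s3 + sin(2phi)*s1)`` with
    ``G = 2*pi*delta``; stacking avoids materialising per-pixel 2x2 arrays.
    """
    phi = np.deg2rad(np.asarray(orientation_deg, dtype=float))
    half = np.pi * np.asarray(retardance_waves, dtype=float)  # G/2
    c, s = np.cos(half), np.sin(half)
    j00 = c + 1j * s * np.cos(2 * phi)
    j11 = c - 1j * s * np.cos(2 * phi)
    j01 = 1j * s * np.sin(2 * phi)
    return j00, j01, j01, j11


def _effective_retardance(specimen: SpecimenMap) -> np.ndarray:
    delta = specimen.retardance_waves
    if specimen.inclination_deg is not None:
        delta = project_inclination(delta, specimen.inclination_deg)
    return delta


def _apply_noise(intensity: np.ndarray, train: OpticalTrain,
                 rng: np.random.Generator) -> np.ndarray:
    """Shot + read noise and digitization, returned in intensity units.

    Expected counts are ``intensity * photon_budget``; the digitized counts
    (clipped to the camera full well ``2**bit_depth - 1``) are divided back
    by the photon budget so noisy and noiseless stacks share a scale.
    """
    counts = rng.poisson(np.clip(intensity, 0, None) * train.photon_budget)
    counts = counts + rng.normal(0.0, train.read_noise, size=counts.shape)
    full_well = 2 ** train.bit_depth - 1
    counts = np.clip(np.rint(counts), 0, full_well)
    return counts / train.photon_budget


def simulate_qbrm(specimen: SpecimenMap, train: OpticalTrain,
                  noiseless: bool = False,
                  rng: np.random.Generator | None = None) -> PolStack:
    """Simulate a qBRM angle stack (one frame per illumination angle).

    With ``noiseless=True`` and ``analyzer_error_waves == 0`` each frame
    equals :func:`eval_intensity` applied pixelwise, exactly.  With an
    analyzer error the full Jones product (polarizer -> specimen retarder ->
    imperfect quarter-wave plate at 45 deg -> polarizer) is evaluated.
    Noise is reproducible from ``train.seed`` unless an explicit ``rng``
    is passed.
    """
    delta = _effective_retardance(specimen)
    I0 = specimen.transmittance
    frames = []
    if train.analyzer_error_waves == 0.0:
        for theta in train.angles_deg:
            frames.append(eval_intensity(I0, delta, specimen.orientation_deg, theta))
    else:
        j00, j01, j10, j11 = retarder_jones(specimen.orientation_deg, delta)
        # imperfect QWP at 45 deg: W = cq*I + i*sq*s1
        gq_half = np.pi * (0.25 + train.analyzer_error_waves)
        cq, sq = np.cos(gq_half), np.sin(gq_half)
        for theta in train.angles_deg:
            th = np.deg2rad(theta)
            e0, e1 = np.cos(th), np.sin(th)
            a0 = j00 * e0 + j01 * e1  # specimen output
            a1 = j10 * e0 + j11 * e1
            out0 = cq * a0 + 1j * sq * a1  # row 0 of W @ a -> final polarizer
            frames.append(I0 * np.abs(out0) ** 2)
    frames = np.stack(frames)
    if not noiseless:
        rng = train.rng() if rng is None else rng
        frames = _apply_noise(frames, train, rng)
    return PolStack(frames, train.angles_deg, kind="sample")


def simulate_ccp(specimen: SpecimenMap, train: OpticalTrain,
                 noiseless: bool = False,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate a crossed-circular-polarizer frame: ``I0 * sin^2(pi*delta)``.

    Contrast depends only on retardance — any birefringent structure shows
    against a dark (extinguished) background regardless of its optic-axis
    orientation.  An analyzer error again routes through the Jones product.
    """
    delta = _effective_retardance(specimen)
    I0 = specimen.transmittance
    if train.analyzer_error_waves == 0.0:
        img = I0 * np.sin(np.pi * delta) ** 2
    else:
        j00, j01, j10, j11 = retarder_jones(specimen.orientation_deg, delta)
        e0, e1 = 1.0 / np.sqrt(2.0), 1j / np.sqrt(2.0)  # right-circular in
        a0 = j00 * e0 + j01 * e1
        a1 = j10 * e0 + j11 * e1
        gq_half = np.pi * (0.25 + train.analyzer_error_waves)
        out0 = np.cos(gq_half) * a0 + 1j * np.sin(gq_half) * a1
        img = I0 * np.abs(out0) ** 2
    img = np.asarray(img, dtype=float)
    if not noiseless:
        rng = train.rng() if rng is None else rng
        img = _apply_noise(img, train, rng)
    return img


def project_inclination(retardance_waves, inclination_deg):
    """Effective in-plane retardance of an inclined optic axis.

    Thin-retarder approximation: the in-plane component scales as
    ``cos^2`` of the out-of-plane inclination, vanishing for an axis along
    the propagation direction (light passes unaltered).  This is a standard
    approximation, not an exact wave-optics result.
    """
    inc = np.asarray(inclination_deg, dtype=float)
    if np.any((inc < 0) | (inc > 90)):
        raise ValueError("inclination_deg must lie in [0, 90]")
    out = np.asarray(retardance_waves, dtype=float) * np.cos(np.deg2rad(inc)) ** 2
    return out if out.ndim else float(out)


def compose_layers(layers: list[SpecimenMap]) -> SpecimenMap:
    """Compose stacked retarder layers into one effective specimen.

    Per pixel, the linear-retarder Jones matrices are multiplied in order
    (first layer encountered by the light first, i.e. rightmost in the
    product) and the SU(2) product is reduced to an equivalent retarder:
    total retardance angle ``G_eff = 2*atan2(|n|, c0)`` and in-plane axis
    from the linear part of the rotation axis.  Co-axial retardances add;
    equal orthogonal retarders cancel exactly (the crossing-fiber
    cancellation seen in tissue).  A residual circular component, which a
    product of non-parallel linear retarders generally acquires, is folded
    into the total retardance and noted, not reported separately.

    Transmittances combine multiplicatively after normalising each layer to
    its maximum (relative transmittance), so one layer's absolute intensity
    scale survives.
    """
    if not layers:
        raise ValueError("compose_layers requires at least one layer")
    if len({l.shape for l in layers}) != 1:
        raise ValueError("all layers must share one shape")
    if len(layers) == 1:
        return layers[0]

    u00 = np.ones(layers[0].shape, dtype=complex)
    u01 = np.zeros_like(u00)
    u10 = np.zeros_like(u00)
    u11 = np.ones_like(u00)
    for layer in layers:
        delta = _effective_retardance(layer)
        j00, j01, j10, j11 = retarder_jones(layer.orientation_deg, delta)
        u00, u01, u10, u11 = (j00 * u00 + j01 * u10,
                              j00 * u01 + j01 * u11,
                              j10 * u00 + j11 * u10,
                              j10 * u01 + j11 * u11)

    # SU(2) decomposition U = c0*I + i(c1*s1 + c2*s2 + c3*s3); the product of
    # unimodular retarders is unimodular, so the coefficients are real.
    c0 = np.real(u00 + u11) / 2.0
    c3 = np.imag(u00 - u11) / 2.0
    c1 = np.imag(u01 + u10) / 2.0
    c2 = np.real(u01 - u10) / 2.0
    amp = np.sqrt(c1 ** 2 + c2 ** 2 + c3 ** 2)
    gamma_eff = 2.0 * np.arctan2(amp, c0)          # in [0, 2*pi)
    delta_eff = gamma_eff / (2.0 * np.pi)          # waves
    phi_eff = np.rad2deg(np.arctan2(c1, c3)) / 2.0 % 180.0

    scale = max(float(np.max(layers[0].transmittance)), np.finfo(float).tiny)
    trans = layers[0].transmittance.astype(float).copy()
    for layer in layers[1:]:
        peak = max(float(np.max(layer.transmittance)), np.finfo(float).tiny)
        trans *= layer.transmittance / peak
    return SpecimenMap(trans, delta_eff, phi_eff)
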