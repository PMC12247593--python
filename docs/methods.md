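# Methods

## Forward model

The specimen is treated, per pixel, as a thin linear retarder with
transmittance I₀ (arbitrary intensity units, ≥ 0), phase retardance δ in
waves of optical path difference, and in-plane optic-axis orientation φ ∈
[0°, 180°). Its Jones matrix is

    J(φ, Γ) = cos(Γ/2)·𝟙 + i·sin(Γ/2)·(cos 2φ·σ₃ + sin 2φ·σ₁),   Γ = 2πδ,

with σ₁, σ₃ the Pauli matrices in the linear-polarization basis.

**qBRM geometry.** Linear polarizer at θ → specimen → circular analyzer.
With the analyzer circular state fixed to (1, −i)/√2, the detected
intensity works out to

    I(θ) = I₀/2 · [1 + sin(2(θ − φ)) · sin Γ].

The handedness choice only flips the sign in front of the sine; since
intensity is the sole observable, the convention is internal
(`optics.SINUSOID_SIGN`) and a single `sign` flag on the model covers
instruments with the opposite convention. When the analyzer error is zero
the simulator evaluates this closed form directly, so noiseless frames are
*bitwise* equal to the analytic law; the full Jones product is reserved for
the imperfect-analyzer path.

**CCP geometry.** Circular polarizers of opposite handedness on either
side of the specimen give I = I₀·sin²(πδ), independent of φ: uniform
extinction with no specimen, maximal transmission for a half-wave
retarder.

**System birefringence.** The detection quarter-wave plate is modeled with
retardance 0.25 + e waves (e = `analyzer_error_waves`), making the analyzer
elliptical for e ≠ 0, which is how a monochromatic waveplate behaves across
an LED's bandwidth. One scalar suffices to produce the characteristic
spurious blank-field modulation (a blank shows apparent retardance
|cos 2π(0.25+e)| = |sin 2πe|, ≈ 0.125 at e = 0.02) and to exercise the
background correction. No attempt is made to model the wavelength-resolved
physics.

**Inclination.** An optic axis tilted out of plane by angle ι contributes
the reduced in-plane retardance δ·cos²ι (thin-retarder approximation, an
explicit modeling choice rather than an exact wave-optics result); at
ι = 90° the light passes unaltered.

**Layer composition.** Stacked retarders multiply as Jones matrices. The
product of non-parallel linear retarders is generally an *elliptical*
retarder; `compose_layers` reduces the SU(2) product U = c₀𝟙 +
i(c₁σ₁ + c₂σ₂ + c₃σ₃) to an equivalent retarder with total retardance
angle 2·atan2(√(c₁²+c₂²+c₃²), c₀) and axis ½·atan2(c₁, c₃) from the linear
part. The circular component (c₂) is folded into the total retardance and
not reported separately — exact for co-axial and orthogonal layers (the
cases with clean physical meaning: addition and cancellation), an
equivalent-retarder summary otherwise. This is how crossing fibers reduce
observed retardance: two equal retarders at 90° compose to the identity.

**Camera.** Expected photon counts are intensity × `photon_budget`
(`photon_budget` = photons at unit intensity; default 10⁴). Poisson shot
noise, additive Gaussian read noise (default σ = 2 counts), clipping to the
full well 2^`bit_depth` − 1 (default 16-bit) and rounding to integer counts,
then division by the photon budget so noisy and noiseless stacks share one
intensity scale. Consequence worth knowing: intensities above
(2^bits − 1)/photon_budget saturate, exactly as a real camera would.

## Inversion

Each pixel's angle series is the sinusoid a + b·cos 2θ + c·sin 2θ with
a = I₀/2 and amplitude √(b²+c²) = I₀·|sin Γ|/2 — three parameters, so three
angles suffice. Estimators:

* **three_point** ({0°, 60°, 120°} only): I₀ = (2/3)ΣIᵢ and retardance
  2√Q/ΣIᵢ with Q = ½[(I₁−I₂)² + (I₁−I₃)² + (I₂−I₃)²] ≥ 0, so the estimate
  is real for any input. Orientation comes from the two-argument
  arctangent of the quadrature pair (C, S) = (I₁ − (I₂+I₃)/2,
  (√3/2)(I₂−I₃)): 2φ = atan2(−C, S), halved and wrapped to [0°, 180°).
  The atan2 form is exact in every quadrant and at zero denominators,
  and is validated by round-trip through the forward model (forward
  re-evaluation of the recovered parameters reproduces the inputs to
  better than 1e−9 relative).
* **fourier** (n ≥ 3 equally spaced angles covering [0°, 180°)): exact
  discrete projection onto the DC and 2θ harmonic. Identical to
  three_point at n = 3 up to round-off. Unequal spacing is rejected rather
  than generalized.
* **fit** (any ≥ 3 distinct angles): least squares. In the (a, b, c)
  parametrization the model is linear, and the map (a, b, c) ↔
  (I₀, retardance, φ) is a bijection for nonnegative amplitude, so a
  single exact linear solve per stack yields the global optimum of the
  sinusoid fit — no iteration and no convergence failures; only a
  rank-deficient design (fewer than three distinct angles mod 180°)
  masks pixels.

Retardance is an amplitude magnitude, so noise can push it above 1; such
pixels are clipped to 1 and counted (`n_clipped`). δ itself is not
recovered: |sin 2πδ| is two-to-one below a full wave, so only the sine
magnitude is reported. Orientation is undefined where the amplitude
vanishes; pixels with retardance below `orientation_floor` (default 0.05,
a display/analysis threshold on a [0, 1] quantity, chosen because typical
shot-noise floors sit near 0.01–0.02 at 10⁴ photons) are masked.

**Background correction** precedes inversion: I_corr = I_sample −
(I_bg − mean_θ(I_bg)) per pixel, with the mean over the angle dimension.
This removes exactly the sinusoidal (system) component of the background
while leaving its DC in place, so a blank field inverts to zero retardance
and a constant background is a no-op. Corrected stacks may contain
negative values and are tagged as such. The background is used per pixel;
averaging it over the field first is left to the caller.

## Phantoms

The generator rasterizes three primitive types with per-pixel ground truth
(I₀, |sin 2πδ|, φ): longitudinal axons (retardance confined to the two
sheath edge bands, axis perpendicular to the axon direction — the in-plane
projection of myelin's radial axis; sheath interior zero), transverse
axons and vesicles (annuli with radially rotating axis equal to the polar
angle mod 180°). Bands are binary (no sub-pixel anti-aliasing): crisp
geometry makes the ground-truth comparisons exact. Default peak retardance
is 0.08 waves, inside the (0, 0.25)-wave range where |sin 2πδ| is monotone
in δ, as expected of thin sections; typical per-pixel myelin retardance is
not otherwise constrained, so δ_peak is a free parameter of every
primitive.

Degradation scenarios emulate myelin damage as seen in processed tissue:
axonal δ scaled by a factor in [0, 1] (retardance loss), seeded random
vesicles (lipid debris), and Gaussian orientation jitter on structure
pixels (local axis disorder). Scenarios re-rasterize the modified scene,
so the identity scenario returns the input object unchanged and
reproducibility is exact under a fixed seed.

Z-stacks assign each structure a focal plane and blur its contribution by
a Gaussian whose σ grows linearly with defocus distance (0.8 px per μm by
default; z-step default 1 μm, with 0.5/1/2 μm the typical settings at
60X/40X/20X). This is a stand-in for a defocus PSF, sufficient to give
focus metrics something to select on — not a diffraction model.

What the phantoms do **not** emulate: realistic axon-diameter
distributions, tissue scattering and depolarization, wavelength-dependent
effects, out-of-focus birefringence crosstalk beyond the Gaussian blur,
and stage/stitching artifacts. Passing tests demonstrate correctness of
the estimators and pipeline plumbing under the stated camera model, not
performance on real tissue.

## Quantification and rendering

ROI retardance is the arithmetic mean over ROI pixels, reported both
intersected with the validity mask and unrestricted, since whether
sub-threshold background pixels belong in the average is a judgement call;
percent change is 100·(before − after)/before (positive = loss). Focus
stacking selects, per pixel, the plane maximizing the local variance of
the Laplacian over an odd window (default 9), ties to the lowest z index;
composite pixels are copied, never blended. The variance-of-Laplacian
metric is a standard, openly specified choice. Abbe resolution is λ/(2·NA).

Orientation maps use HSV with hue = 2·(φ + wheel_rotation) mod 360° (so φ
and φ + 180° coincide), full saturation, and value = display-scaled
retardance; masked pixels render black, and the legend wheel uses the
identical mapping. The hue anchor (0° → red) is a convention and
configurable via the wheel rotation; rotating by 90° displays fiber
direction instead of the radial optic axis. Display scaling is percentile
clip then gamma; a degenerate (constant) range renders positive signal at
full brightness. Raw RGB triplets store the 0°/60°/120° frames as R/G/B
under a single shared scale factor — per-channel normalization would
destroy the qualitative orientation encoding.

## Numerical choices and problem sizes

Angles are degrees at every API boundary, radians only inside kernels.
Orientation comparisons use the period-180° circular metric. Zero-signal
pixels (ΣI = 0) yield I₀ = 0, retardance 0, masked. The acceptance script
and test suite run on deliberately modest problem sizes — 100×100
round-trip grids, 10³-pixel Monte-Carlo noise studies, 96×96 phantoms —
chosen so the full validation completes in seconds while keeping
Monte-Carlo standard errors well below the effects being measured.

## Known limitations

* Single-wavelength, fully polarized, non-depolarizing model: no Mueller
  calculus, scattering, or spectral integration.
* The equivalent-retarder reduction in `compose_layers` summarizes
  elliptical products by total retardance; applications needing the
  circular component separately should consume the Jones product directly.
* Out-of-plane orientation is not estimated from transmittance; inclination
  enters only through the cos² forward projection.
* No image registration between before/after sessions; quantification
  assumes pre-aligned maps.
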