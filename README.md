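# qbrm — quantitative birefringence microscopy in silico

Myelin — the lipid sheath wrapped around axons — is strongly birefringent,
with an optic axis radial to the axon. Polarized-light (birefringence)
microscopy exploits this to image myelinated axons label-free in thin brain
sections and to quantify myelin damage as a loss of retardance. `qbrm`
implements the computational side of that workflow end to end: a
Jones-calculus forward model of the microscope, a closed-form three-angle
inversion for the birefringence parameter maps, background correction for
instrument ("system") birefringence, the standard visualizations, and ROI
quantification — together with a seeded myelin-phantom generator so every
stage can be validated against known ground truth without a microscope.

It is intended for people building or analyzing polarized-light microscopy
data (quantitative birefringence / polarization-sensitive imaging of brain
tissue and other anisotropic specimens) and for method development on
synthetic scenes.

## The model

When a thin linear-retarder specimen is illuminated with linear
polarization at angle θ and detected through a circular analyzer, each
pixel's intensity follows

    I(θ) = I₀/2 · [1 + sin(2(θ − φ)) · sin(2πδ)]

where I₀ is the transmittance (DC term), δ the phase retardance in waves,
and φ the in-plane optic-axis orientation. Sampling at the three polarizer
angles {0°, 60°, 120°} (I₁, I₂, I₃) gives closed-form estimators — no
fitting required:

    I₀          = (2/3)(I₁ + I₂ + I₃)
    |sin(2πδ)|  = 2√(I₁² + I₂² + I₃² − I₁I₂ − I₁I₃ − I₂I₃) / (I₁ + I₂ + I₃)
    φ           = ½ · atan2 of the quadrature components of the 2θ harmonic

Discrete Fourier analysis at n ≥ 3 equally spaced angles and per-pixel
least-squares sinusoid fitting are provided as well; all three estimators
coincide exactly on three-angle stacks. Crossed-circular-polarizer imaging
(contrast I₀·sin²(πδ), orientation-independent) is also simulated. System
birefringence — an imperfect detection quarter-wave plate acting as an
elliptical analyzer — is modeled through the full Jones product and removed
by subtracting the sinusoidal component of a no-sample background stack:

    I_corr = I_sample − (I_bg − mean_θ(I_bg))

## Worked example

```python
import qbrm

spec = qbrm.PhantomSpec(
    shape=(96, 96),
    structures=(
        qbrm.LongitudinalAxon(center=(30, 48), length=80, direction_deg=0.0,
                              outer_radius=6, sheath_thickness=2, delta_peak=0.08),
        qbrm.LongitudinalAxon(center=(60, 48), length=70, direction_deg=30.0,
                              outer_radius=5, sheath_thickness=2, delta_peak=0.06),
        qbrm.Vesicle(center=(20, 75), radius=5, thickness=2, delta_peak=0.05),
    ))
phantom = qbrm.generate_phantom(spec)

train = qbrm.OpticalTrain(photon_budget=1e4, seed=0)   # 0/60/120 deg, shot noise
stack = qbrm.simulate_qbrm(phantom.specimen, train)

res = qbrm.BirefringenceModel(stack).fit()   # closed-form three-point inversion
print(res.summary())

roi = qbrm.ROIMask(phantom.axon_mask, "axons")
mean_ret, n = qbrm.roi_mean_retardance(res, roi)
print(f"mean retardance over {n} axon pixels: {mean_ret:.4f}")

damaged = qbrm.apply_degradation(
    phantom, qbrm.DegradationScenario(retardance_scale=0.7), seed=1)
res2 = qbrm.BirefringenceModel(qbrm.simulate_qbrm(
    damaged.specimen, qbrm.OpticalTrain(photon_budget=1e4, seed=2))).fit()
mean2, _ = qbrm.roi_mean_retardance(res2, roi)
print(f"after 0.7x retardance scaling: {mean2:.4f} "
      f"({qbrm.percent_change(mean_ret, mean2):.1f}% decrease)")
```

prints

```
                       mean        std       min         max
map
transmittance      0.999921   0.008226  0.966133    1.027533
retardance         0.051327   0.119914  0.000133    0.513878
orientation_deg  100.570262  19.769316  1.150775  179.799449

mean retardance over 758 axon pixels: 0.4401
after 0.7x retardance scaling: 0.3134 (28.8% decrease)
```

The retardance summary averages over the whole frame (mostly empty
background, hence the small mean); on the axon sheath pixels the inversion
recovers the phantom's |sin(2π·0.08)| ≈ 0.48 and |sin(2π·0.06)| ≈ 0.37 edge
bands, and the simulated degradation (δ scaled by 0.7) is read back as a
28.8% retardance loss — the statistic used to quantify myelin damage.
Orientation statistics are computed over the unmasked (birefringent) pixels
only.

A command-line pipeline mirrors the library:

```sh
qbrm simulate --config scene.yaml --out run/ --seed 1 --background
qbrm invert --stack run/sample.tif --background run/background.tif --out run/maps
qbrm render --maps run/maps --stack run/sample.tif --out run/renders --wheel-rotation 90
qbrm quantify --before run/maps --after run/maps2 --out report.csv
qbrm focus-stack --zstack z.tif --out fs/
qbrm resolution --na 0.13          # -> 2403.8 nm (2.40 um)
```

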