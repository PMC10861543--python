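# cardiodwi

Motion-compensated cardiac diffusion MRI, end to end, at desk scale.

Diffusion-weighted imaging of the beating heart fails with conventional
encoding: the Stejskal-Tanner gradient pair nulls only the zeroth gradient
moment, so bulk wall motion during the encoding accrues phase through the
first and second moments (velocity and acceleration), and the intravoxel
spread of velocities dephases the spins until the myocardium simply
disappears from the image. The fix is **gradient moment nulling**: reshape
the diffusion encoding so that m₀, m₁ and m₂ all vanish ("M012"
encoding), making the acquired signal insensitive to rigid translation,
velocity and acceleration while keeping the diffusion weighting.

`cardiodwi` implements that whole chain as a small scientific Python
package, aimed at sequence developers and imaging scientists who want a
reference implementation and an experimentation testbed rather than
scanner software:

* **Waveform design** (`cardiodwi.waveforms`) — Stejskal-Tanner (M0) and
  moment-nulled (M01/M012) trapezoid-lobe designs under gradient amplitude
  and slew-rate limits (defaults: 440 mT/m, 3440 T/m/s — a 9.4 T
  small-animal system), with exact raster-level moment and b-value
  calculators. The b-value generalizes the closed form
  b = γ²G²δ²(Δ − δ/3) to arbitrary shapes via b = ∫|q(t)|²dt,
  q(t) = γ∫G_eff dt′.
* **Signal simulation** (`cardiodwi.simulate`) — the tensor model
  S = S₀·exp(−b·gᵀDg) with moment-phase accrual
  γ(m₀·r₀ + m₁·v + ½m₂·a), Gaussian intravoxel dephasing
  exp(−½γ²m₁²σ_v²), and Rician magnitude noise.
* **Synthetic phantoms** (`cardiodwi.phantoms`) — a six-vial PVP
  diffusion phantom (ADC 1.37–2.21 × 10⁻³ mm²/s), a short-axis rat-heart
  annulus with transmural fiber helix (−60°→+60°) and ring/sector injury
  patterns, and seeded cohorts with between-subject variability.
* **Reconstruction** (`cardiodwi.reconstruct`) — log-linear tensor fit
  from 6 directions + b0, eigenvalue decomposition, ADC (= trace/3) and
  FA maps, ROI statistics.
* **Cardiac metrics & statistics** (`cardiodwi.metrics`, `cardiodwi.stats`)
  — Simpson-disk LV volumes and ejection fraction, ECV from hematocrit and
  pre/post-contrast T1, and Shapiro-Wilk-driven group comparisons
  (Welch t / Mann-Whitney / ANOVA / Kruskal-Wallis).

## Worked example

Design the second-order motion-compensated encoding at b = 350 s/mm²:

```sh
$ cardiodwi design --b 350 --order 2 --out wf.csv
b = 350.000 s/mm^2, duration = 17.78 ms, moments = (-7.105e-19, -4.441e-21, 1.735e-23)
```

The achieved b equals the target to machine precision and all three
moments are at numerical zero (tolerances 10⁻⁹/10⁻¹²/10⁻¹⁵), so the
encoding carries full diffusion weighting but no motion sensitivity.

Run the six-vial phantom experiment (noiseless, both encodings):

```sh
$ cardiodwi run pvp.json --out-dir out --seed 1   # pvp.json: {"experiment": "pvp"}
{
  "true_md_1e-3_mm2_per_s":  [2.21, 2.04, 1.84, 1.67, 1.41, 1.37],
  "adc_m0_1e-3_mm2_per_s":   [2.21, 2.04, 1.84, 1.67, 1.41, 1.37],
  "adc_m012_1e-3_mm2_per_s": [2.21, 2.04, 1.84, 1.67, 1.41, 1.37],
  "correlation_m0_vs_m012": 1.0
}
```

Both encodings recover every vial's ground-truth ADC exactly (noiseless
round trip) and correlate perfectly across the series. The motion
demonstration shows why the compensation matters — with a systolic
intravoxel velocity spread of 10 mm/s the uncompensated encoding retains
essentially none of the myocardial diffusion-weighted signal while M012
retains all of it:

```sh
$ cardiodwi run motion.json --out-dir out2 --seed 1   # {"experiment": "motion-demo"}
  "myocardial_signal_retention": { "m0": 3.59e-39, "m012": 1.0 }
```

The same machinery is scriptable:

```python
from cardiodwi import (EncodingSpec, HardwareLimits,
                       design_motion_compensated, make_cardiac_phantom,
                       simulate_dwi, fit_tensor, eigen_adc, roi_stats)

wf = design_motion_compensated(EncodingSpec(b_target=350, nulling_order=2),
                               HardwareLimits())
phantom = make_cardiac_phantom(myo_md=1.578e-3)   # healthy rat myocardium
dwi = simulate_dwi(phantom, wf, snr=25, seed=0)
adc = eigen_adc(fit_tensor(dwi))
print(roi_stats(adc, phantom.region_map, names=phantom.region_names))
```

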