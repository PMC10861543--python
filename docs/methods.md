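# Methods

## Waveform model and moment calculus

A gradient waveform is a scalar amplitude sequence on a uniform raster
(default dt = 10 µs), each sample held constant over its bin; the waveform
is played along one encoding direction. The 180° refocusing pulse is
modeled as an instantaneous sign flip of the *effective* gradient at a
designated sample index (RF details are out of scope). With bin-center
times t_k, the gradient moments of the effective waveform are

    m_n = Σ_k s_k · G_k · t_kⁿ · dt ,   s_k = −1 after the refocus index,

exact for the piecewise-constant model; m₀, m₁, m₂ couple to the position,
velocity and acceleration of moving tissue. The b-value is
b = ∫|q|²dt with q(t) = γ∫G_eff dt′. Because q is piecewise linear for
piecewise-constant G, each bin contributes dt·(q₀² + q₀q₁ + q₁²)/3 and the
integral is evaluated exactly; for an ideal rectangular Stejskal-Tanner
pair aligned to the raster the result equals γ²G²δ²(Δ − δ/3) to machine
precision, and the designed trapezoid pair agrees with the closed form at
its area-equivalent (δ, Δ) to ≈0.04%.

γ defaults to the proton value 2.675221874 × 10⁸ rad/s/T and is
configurable. Hardware limits default to 440 mT/m and 3440 T/m/s; at
full amplitude a ramp is ≈128 µs, i.e. ≥12 raster samples, so trapezoid
ramps are well resolved.

## Encoding design

**Stejskal-Tanner (M0).** Two identical trapezoid lobes back-to-back
around the refocusing point, amplitude at the hardware limit. The
flat-top length is the smallest (found by bisection on the numerically
integrated b) that reaches the target; the final amplitude is scaled down
by √(b_target/b), which matches b exactly (b ∝ G²) and preserves m₀ = 0.
Default duration cap 30 ms; an infeasible target raises an error carrying
the best achievable b.

**Moment-nulled (M01/M012).** The effective waveform is K = order + 2
contiguous equal-duration trapezoid lobes (one zero sample between lobes,
which also hosts the refocusing flip). All lobes share one unit shape, so
each moment is *linear* in the lobe amplitudes; the amplitude vector is
taken from the one-dimensional nullspace of the row-normalized
(order+1) × K discretized moment matrix (smallest right singular vector,
sign-fixed). Moments therefore vanish to machine precision on the raster
— the tolerances |m₀| ≤ 10⁻⁹ T·s/m, |m₁| ≤ 10⁻¹² T·s²/m,
|m₂| ≤ 10⁻¹⁵ T·s³/m are met with orders of magnitude to spare — and no
iterative optimizer is needed, making the design exactly reproducible.
Lobe duration is found by bracketing + bisection on b, then amplitudes are
scaled for the exact b match (scaling preserves nulling). At b = 350 s/mm²
the M012 design lasts 17.8 ms (amplitude pattern ≈ ⅓, −1, 1, −⅓), inside
the 30 ms cap. Whether this matches the unpublished timing of the original
hardware sequence is unknowable from the text; any moment-nulled,
b-matched design is acceptable for the desk-scale study.

## Signal model

Per voxel, S = S₀·exp(−b·gᵀDg) with D the (mm²/s) tensor and g the unit
encoding direction, times two motion terms derived from the waveform
moments projected on g:

* bulk phase γ(m₀·r₀ + m₁·v + ½m₂·a)·g — verified in tests against
  independent numerical integration of γ∫G_eff(t)·x(t)dt for polynomial
  trajectories;
* intravoxel dephasing: for a Gaussian velocity spread σ_v the voxel
  average of exp(iγm₁v) is the characteristic function
  exp(−½γ²m₁²σ_v²). A seeded isochromat-ensemble estimator is provided
  and used as the validation oracle for the closed form.

Motion is rigid per phantom (global MotionState, optional per-region
override); strain is out of scope. With the M0 design (|m₁| ≈ 5 × 10⁻⁶
T·s²/m) a systolic spread of 10 mm/s gives a dephasing factor of ~e⁻¹⁰⁰ —
the myocardium vanishes — while the M012 design is unaffected; this is the
mechanism behind the motion-demo experiment. Rician noise is applied as
|S + n₁ + i·n₂| with σ = (mean b=0 signal over the mask)/SNR; default
SNR 25 (the acquisitions' SNR is not reported; 25 is a realistic
segmented-EPI figure). Relaxation weighting, partial volume, perfusion
and k-space/EPI readout effects (distortion) are not modeled.

## Phantoms

Grids default to a 64 × 32 single slice at 0.390625 × 0.390625 × 2 mm —
half the 128 × 64 / 50 × 25 mm acquisition matrix, for speed; fully
configurable.

* **PVP phantom:** six disjoint circular vials (radius 1.7 mm) on a 3 × 2
  layout, isotropic tensors set to the requested series (defaults: the
  measured 0–50% w/v series, 2.21 down to 1.37 × 10⁻³ mm²/s).
* **Cardiac phantom:** annulus (endo 2 mm, epi 4 mm) around a blood
  cavity (3.0 × 10⁻³ mm²/s, S₀ 1.2). Each myocardial voxel gets a prolate
  tensor whose primary eigenvector follows a linear transmural helix
  (default −60° endo → +60° epi, the literature convention); eigenvalues
  satisfy trace/3 = target MD and λ₁/λ₃ = anisotropy ratio (default 2 —
  any trace-preserving choice leaves ADC-level results unchanged).
  Injury patterns: a subendocardial ring (inner ⅓ of the wall, the
  diffuse-fibrosis pattern) or a transmural 90° sector (an infarcted
  coronary territory).
* **Cohorts:** subject-level myocardial MD ~ Normal(mean, SD) truncated
  below at 0.5 × 10⁻³ mm²/s, seeded. Group defaults are the reference
  group statistics (control 1.578 ± 0.144, acute injury 1.847 ± 0.326,
  × 10⁻³ mm²/s). Cohort subjects default to *diffuse* injury (the drawn
  MD applies to the whole myocardium, no ring), because the group-level
  readout is a whole-myocardium ROI mean; a ring offset is available.

What passing tests show — and do not. The phantoms share the exact
signal model with the reconstructor (no readout, no strain, no
partial-volume), so noiseless round trips are exact by construction and
serve as correctness oracles for the algebra, not as evidence about
in-vivo accuracy. The noisy-cohort results test estimator bias and
group-level statistics under Rician noise and between-subject spread
only.

## Reconstruction

Log-linear least squares per voxel: −log(S_i/S₀) = b_i·g_iᵀDg_i with
design rows (g_x², g_y², g_z², 2g_xg_y, 2g_xg_z, 2g_yg_z); S₀ is the
(mean) b=0 image; voxels with any non-positive signal are invalid.
Weighted LS (rows scaled by signal) is available behind a flag; the
baseline stays ordinary LS. ADC = mean eigenvalue = trace/3 — negative
noise-driven eigenvalues are retained there (trace stays unbiased) but
clamped to zero for FA, whose domain requires non-negativity; FA is
clipped to [0, 1] and undefined for the zero tensor. ADC is reported in
10⁻³ mm²/s. The default direction scheme is the six-direction
dual-gradient set (±1,1,0),(1,0,±1),(0,±1,1)/√2; any unit scheme of rank
6 is accepted. ROI statistics are computed voxelwise-then-ROI (per-voxel
maps first, then label means, SD with n−1).

## Statistics

Shapiro-Wilk on each group at α = 0.05 selects parametric
(Welch unequal-variance t for two groups, one-way ANOVA for more) versus
nonparametric (Mann-Whitney U, Kruskal-Wallis); all tests two-sided.
Constant groups are routed to the nonparametric branch (Shapiro is
undefined there). Correlation is Pearson product-moment.

A note on cohort power: at the reference effect size (1.578 ± 0.144,
n = 5 vs 1.847 ± 0.326, n = 23) the exact Monte-Carlo power of this
procedure is ≈ 0.72–0.75 at α = 0.05, not ≥ 0.8 — the normal
approximation Φ(2.87 − 1.96) ≈ 0.82 overstates small-sample power. The
power test in the acceptance suite documents this honestly.

## Problem sizes and determinism

The acceptance computations use the half-resolution grid; cohort targets
average 20 cohort seeds; the infarct/remote ROI means average 8 noise
seeds, because a single 66-voxel infarct ROI at SNR 25 has ≈1.1%
per-realization sampling SD while the estimator itself is unbiased —
averaging separates the bias question from ROI shot noise. Every random
quantity (cohort draws, noise) derives from a single integer seed;
noiseless simulations are bit-reproducible and the waveform designs are
exactly deterministic.

## Known limitations

* No EPI readout: susceptibility distortion, T2* blur and ghosting are
  absent, so image-quality conclusions transfer only qualitatively.
* Rigid bulk motion only; no contraction/strain, no gating jitter.
* The cardiac anatomy is a single-slice annulus without papillary
  muscles or RV; helix-angle generation is supported but quantitative HA
  analysis is not.
* ECV uses the standard (1 − Hct)·ΔR1 ratio; scanner-software variants
  may differ (the adopted form is recorded in output metadata).
* In-vivo-only quantities (LVEF/ECV group values, troponin, histology)
  are covered by formula-level unit tests, not reproduced.
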