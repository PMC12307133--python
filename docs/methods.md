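# Methods

## Transport model and velocity reconstruction

The tracer concentration c(r, t) of magnetically labeled blood water is
modeled by mass conservation with longitudinal decay,

    ∂c/∂t = −∇·(c u(r)) − λ c,       λ = 1/T1b,  T1b = 1.65 s.

Diffusive transport is neglected: over the 0.5–2.5 s observation window it
is far slower than advection by perfusion.  The velocity u(r) is treated
as time-invariant over the acquisition and is recovered by minimizing

    F(u) = Σ_k ‖ Δc_k/Δt_k + ∇·(c̄_k u) + λ_eff c̄_k ‖₂²  +  α Σ_m TV_ε(u_m)

where the sum runs over the N_t − 1 consecutive delay intervals, Δc_k is
the difference of the two volumes, c̄_k their midpoint average, and
TV_ε(v) = Σ_r (√(|∇v(r)|² + ε²) − ε) is a smoothed isotropic total
variation applied to each velocity component m.  The reconstructed ‖u‖ is
a relative measure: the voxel-scale spatio-temporal average it represents
has no direct physiological calibration, so no physical unit is attached.

Numerical choices:

- **Decay handling.**  The midpoint discretization of pure exponential
  decay has a small but systematic residual that the solver would absorb
  into spurious velocity.  We therefore use the tanh-corrected effective
  rate λ_eff = (2/Δt)·tanh(λΔt/2) per interval, for which exact
  exponential decay has exactly zero residual.  (λ_eff differs from λ by
  0.8% at Δt = 0.5 s.)
- **Spatial operator.**  ∇·(c u) is discretized in conservative flux form:
  faces between voxels carry the centered concentration ½(c_i + c_j) and
  velocity ½(u_i + u_j); faces on the domain or mask boundary carry zero
  flux.  This matches closed-boundary forward dynamics — with plain
  central differences the boundary layer dominates the residual and the
  fit degrades badly.  A one-sided ("upwind") variant is available via
  `QTMConfig(scheme="upwind")`.
- **Solver.**  The smoothed objective is convex and is minimized with
  L-BFGS (scipy), whose line search enforces sufficient decrease; the
  recorded objective trace is non-increasing.  Default stop: relative
  objective change below 1e-10 or 3000 iterations.
- **TV smoothing.**  ε = 1e-3 by default.  On the calibration phantom the
  solution is indistinguishable from ε = 1e-6 (recovery error differs in
  the fourth decimal) while converging roughly 20× faster.
- **Regularization weight.**  α = 6e-4, calibrated once on the packaged
  32³ piecewise-block phantom (recovery error is flat to within ~0.01
  over α ∈ [3e-4, 1e-3]).  Concentrations are normalized internally by
  max|c| so α is independent of signal units; with α = 0 the minimizer is
  invariant to rescaling the data.
- **Signal floor.**  Voxels whose peak |c| over delays is below 1e-3 of
  the global maximum are dropped from the data mask: the transport term is
  uninformative there.

## Synthetic phantoms and the forward simulator

Velocity phantoms: all-zero, uniform, piecewise-constant octant blocks
(random per-octant vectors scaled to a peak speed), and divergence-free
solid-body rotation.  The forward simulator advances an initial
concentration with conservative flux-form first-order upwind advection and
exact exponential decay per sub-step; sub-steps satisfy
Σ_axes max|u_a|·Δt/Δx_a ≤ 0.5.  Mass is conserved to machine precision
under both periodic and closed boundaries when λ = 0, and u = 0 reproduces
exp(−λt) exactly.

For the standard recovery experiment (`block_phantom_experiment`) the
forward run uses a grid refined 2× per axis and is block-averaged to the
observation grid.  This curbs the upwind scheme's numerical diffusion and,
because forward and inverse discretizations differ, avoids an inverse
crime.  Default conditions: 32³ voxels of 2.5 × 2.5 × 3 mm, peak speed 2
(relative units, ≈ 0.8 voxel/s), delays 0.5–2.5 s in steps of 0.5 s,
λ = 1/1.65 s⁻¹.  Under these conditions the masked relative L2 error of
the reconstructed ‖u‖ is 0.11–0.14 across seeds.  With additive Gaussian
noise the error grows smoothly: ≈ 0.15 at SNR 100 (noise SD = mean signal
/ 100, regularization raised to 1e-3) and ≈ 0.22–0.26 at SNR 20 even with
α tuned per noise level — at that noise the advective residual itself has
an effective SNR of only ~2–3, which bounds what any estimator can do on a
single tracer series.

## Synthetic cohorts

The cohort generator emulates a three-group memory-clinic study with 28
cognitively normal (NC), 85 mild-cognitive-impairment (MCI) and 37
probable-AD subjects (168 recruited, 12 + 6 excluded).  Demographics and
cognition (age, sex, education, MMSE, RAVLT immediate/delayed recall,
TMT-A/B, VFT) are Gaussian per group at the study's summary values,
truncated to valid ranges (MMSE 0–30 and integer-rounded, recall 0–15,
completion times positive).

Regional velocities (26 territories, base level 5 relative units) carry
three planted components:

1. **Group effects**: shifts of 0 / −0.5 / −1.0 × noise SD for NC / MCI /
   AD in the 22 non-vertebrobasilar territories, none in VBL/VBR/CBLL/CBLR
   — a cortical-predominant hypoperfusion pattern that the ANCOVA screen
   should detect.
2. **A lag-1 driver**: after ranking subjects by the same cognition rule
   the analysis uses, the driver region (default MCATL) leads its target
   regions by one rank step: x_j(t) = a·x_d(t−1) + √(1−a²)·ε_j(t) with
   a = 0.6 by default.  The √(1−a²) innovation scaling keeps every
   regional series at marginal SD = noise_sd, so the standardized lag-1
   coefficient the analysis estimates equals the planted a.
3. **ALPS coupling**: the ALPS index (1.5 ± 0.2, dimensionless) correlates
   with subject-mean velocity at ρ = 0.25 by construction, matching the
   weak positive association scale reported for such cohorts.

Per-region velocity variances are not characterized by any published
source; the defaults above are configurable choices, not claims about the
study population.  What the generator does **not** emulate: ASL labeling
physics and acquisition noise structure, spatial autocorrelation within
territories, registration error, missing data, and any true longitudinal
dynamics — passing tests show the pipeline recovers planted structure
under its own assumptions, not that those assumptions hold in real data.

## Pseudo-time Granger causality

Subjects are ordered by MMSE descending, ties by RAVLT immediate recall
descending, residual ties by subject id (deterministic).  Each region's
series is z-scored over subjects and each ordered pair (i → j) is fit by
least squares without intercept:

    x_j(t) = A_ij x_i(t−1) + B_j x_j(t−1) + ε(t),   t = 2..N.

Standardization makes A_ij comparable across regions, which matters
because driving scores sum them: A_i = Σ_{j≠i} A_ij with positive and
negative parts accumulated separately.  Only lag 1 is supported, and the
model is deliberately bivariate (not a joint VAR), mirroring the pairwise
formulation the analysis is defined by.  Driving scores are computed over
the regions passing the group-difference screen (configurable to all).

Significance: the subject order is permuted (default 1000 times) and the
full analysis recomputed.  Positive scores are tested against the upper
tail, negative scores against the lower tail, individual coefficients
two-sided, all with the add-one convention p = (1 + #{perm ≥ obs})/(n_perm
+ 1), so p ∈ [1/(n_perm+1), 1] and p = 0 cannot occur.  Each region is
compared against its own permutation distribution.  Under an i.i.d. null
at study scale (n = 150, 22 regions) the empirical rejection rate at
α = 0.05 is 0.049–0.050.

Two open choices were resolved as follows: series are standardized and the
regression carries no intercept (the score sums are scale-mixed
otherwise), and coefficient-level significance uses the same permutation
scheme as the scores.  The ordering hash is recorded with every result
because reversing the ordering changes which pairs appear "causal" — the
statistic is a lead–lag description of an ordered cross-section, not
temporal inference.

## Sliding-window analysis

Windows of 50 subjects slide with stride 1 (N − L + 1 windows; 101 at
N = 150).  Within each window the series are re-z-scored, driver-to-region
coefficients re-estimated, and within-window order permutations (default
1000) give two-sided p-values; each window draws from its own seeded
stream spawned from the master seed, so any window is reproducible in
isolation.  Window length 50 balances stage resolution against coefficient
stability (results are reported as robust across 30/50/70 in the
literature this design follows); no correction is applied across
overlapping windows, though the exported table carries raw p-values so an
FDR pass can be added downstream.

## ALPS index

ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc) per hemisphere,
from ROI-mean diffusivities (mm²/s) in projection- and association-fiber
regions; the bilateral value is the mean of the two sides, and a missing
side makes the bilateral value missing rather than silently one-sided.
Tensor fitting and template registration are upstream external steps; the
package consumes per-axis diffusivity maps or pre-extracted ROI means.
The index is scale-invariant and exceeds 1 exactly when x-axis diffusivity
dominates; it is treated as a proxy that only partially reflects
interstitial-fluid dynamics.

## Group statistics

- One-way ANOVA is computable from per-group (n, mean, SD) summaries;
  against raw-data ANOVA it agrees to 1e-10.  Of the published summary
  rows this package re-derives, MMSE reproduces its printed F within 0.2%
  and the sex χ² is exact; age and TMT-B deviate far beyond rounding, so
  only the MMSE and sex rows serve as fixed oracles and the rest are
  order-of-magnitude checks.
- ANCOVA is a nested linear-model F (covariates-only vs covariates +
  group, i.e. sequential sums of squares) with age, sex and education as
  covariates; the region screen applies Benjamini–Hochberg FDR at
  q = 0.05.
- Pearson vs Spearman is chosen by a Shapiro–Wilk screen at α = 0.05 when
  not specified, since either may be appropriate per variable.
- The velocity–ALPS association is the partial correlation after
  residualizing both variables on the covariates; with covariates
  orthogonal to both it reduces to the simple correlation.

## Parcellation and I/O

Velocity maps and the atlas are assumed co-registered; spatial
normalization is delegated to external registration tools.  Regions with
fewer than 10 masked voxels are flagged missing (never zero) and excluded
pairwise downstream.  The 26-territory label table uses the conventional
abbreviations (ACAL/R, MCAF/I/P/T/O L/R, MLS/LLS/ACTP L/R, PCAT/PCAO L/R)
plus VBL/VBR/CBLL/CBLR for the vertebrobasilar-supplied remainder; the
voxel-level content of the public arterial atlas is external and is
emulated, not reproduced.  Volumes are read and written as NIfTI-1 via
nibabel, preserving spacing and affine.

## Problem sizes

Default experiment sizes were chosen to keep any single check under a
minute on one CPU while leaving the statistics interpretable: 32³ voxels
for the recovery phantom, 200 replicates × 1000 permutations for null
calibration, 100 seeded replicates for driver power.  All are parameters,
not limits.

## Known limitations

- ‖u‖ is a relative quantity; the package makes no attempt to calibrate
  it to physical blood velocity, and its physiological meaning at the
  voxel scale is an open question.
- Velocity recovery to ≤ 15% needs clean data; see the noise curve above.
- The GCA stage inherits every caveat of pseudo-time designs: the
  ordering is a noisy, coarse severity proxy, and lead–lag along it does
  not establish temporal precedence.
- The bivariate pairwise model does not control for third regions; a
  driver's targets can show induced pairwise coupling among themselves.
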