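# qtmflow

Perfusion-velocity mapping from multi-delay arterial spin labeling (ASL)
and cognition-ordered causality analysis of regional velocity change.

`qtmflow` is aimed at neuroimaging researchers studying how cerebral
perfusion changes across the Alzheimer's disease (AD) continuum.  It
implements, as a single reusable pipeline:

1. **Quantitative transport mapping (QTM).**  A tracer concentration
   series c(r, t), sampled at several post-labeling delays (PLDs), is fit
   to the mass-conservation transport equation
   `∂c/∂t = −∇·(c u) − λ c` with `λ = 1/T1b` (T1b = 1.65 s, the T1 of
   labeled blood water).  The voxel-wise, time-invariant velocity field
   u(r) is recovered as

   `u = argmin_u Σ_t ‖∂c/∂t + ∇·(c u) + λ c‖₂² + α ‖∇u‖₁`

   and its Euclidean norm ‖u‖ is reported as a relative (unitless)
   perfusion-velocity magnitude.
2. **Arterial-territory parcellation.**  ‖u‖ is averaged over 26
   territories (ACA / MCA / PCA subdivisions, perforator territories,
   vertebrobasilar regions) on a co-registered integer atlas.
3. **Pseudo-time Granger causality (GCA).**  Subjects are ranked from best
   to worst cognition (MMSE, ties broken by RAVLT immediate recall); the
   ordered regional velocities form a pseudo-time series.  For each region
   pair the first-order model
   `QTM_j(t) = A_ij·QTM_i(t−1) + B_j·QTM_j(t−1) + ε(t)` is fit, per-region
   driving scores `A_i = Σ_{j≠i} A_ij` (positive/negative parts separately)
   are computed, and significance is assessed by permuting the subject
   order (1000 permutations, 5% tails).
4. **Sliding-window GCA** (windows of 50 subjects, stride 1) to localize
   when driver-to-region effects appear along the severity ordering.
5. **DTI-ALPS index** `mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)`
   from ROI diffusivities, and its association with regional velocity
   (partial correlation given age, sex, education).
6. **Group statistics**: summary-statistic one-way ANOVA, χ² tests,
   per-region ANCOVA screening with Benjamini–Hochberg FDR, Bonferroni
   post hocs, Pearson/Spearman correlations.

Because no imaging cohort ships with the package, a first-class
synthetic-data module generates everything the pipeline consumes: velocity
phantoms with a conservative upwind advection–decay forward simulator, and
three-group (NC / MCI / AD) cohorts with realistic cognitive-score
distributions, a planted lag-1 driver region, and a weak positive
velocity–ALPS association.

## Worked example

```python
from qtmflow.synthetic_data import CohortSpec, generate_cohort
from qtmflow.pseudotime_gca import build_pseudotime, permutation_significance
from qtmflow.group_stats import region_selection

cohort = generate_cohort(CohortSpec(seed=1))          # 28 NC, 85 MCI, 37 AD
screen = region_selection(cohort)                     # ANCOVA + FDR screen
selected = screen.loc[screen["selected"], "region"].tolist()

pseudo = build_pseudotime(cohort)                     # cognition-ranked series
res = permutation_significance(pseudo, n_perm=1000, seed=1, regions=selected)
print(res.scores.table.sort_values("positive", ascending=False).head(3))
```

prints

```
region  positive  negative    p_pos
 MCATL 11.293719  0.000000 0.000999
 PCATR  3.035783 -0.018495 0.001998
  MLSL  2.658885  0.000000 0.005994
```

Twenty of 26 regions pass the group-difference screen, and the planted
driving region MCATL (temporal MCA territory, left) has the largest
positive driving score with permutation p ≈ 0.001: velocity change there
leads change in the regions it drives by one step along the severity
ordering, which is exactly the structure the generator planted.

The same stages are available from the command line:

```sh
qtm simulate --seed 1 --out cohort.csv
qtm stats --cohort cohort.csv --out screen.csv
qtm gca --cohort cohort.csv --nperm 1000 --seed 1 --out scores.csv
qtm reconstruct --in series.nii.gz --mask mask.nii.gz \
    --plds 0.5,1.0,1.5,2.0,2.5 --out vel.nii.gz
qtm run-all --seed 1 --out runs/demo
```

## Layout

```
src/qtmflow/
  synthetic_data.py   phantoms, forward tracer simulator, cohort generator
  qtm_model.py        transport objective and velocity reconstruction
  parcellation.py     arterial-territory atlas aggregation, NIfTI I/O
  pseudotime_gca.py   cognition ranking, pairwise GCA, driving scores,
                      permutation significance
  sliding_window.py   windowed GCA along the severity ordering
  alps.py             DTI-ALPS index
  group_stats.py      ANOVA/ANCOVA, χ², FDR, correlations, ALPS regression
  pipeline.py, cli.py orchestration and the `qtm` command
```

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.
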