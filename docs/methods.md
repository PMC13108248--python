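# Methods

`coeruleus` implements an in vivo locus coeruleus (LC) integrity analysis:
neuromelanin-sensitive MRI quantification of LC relative intensity, per-subject
degeneration slopes, PET-derived global amyloid burden, longitudinal
mixed-effects models of LC and cognition, and voxelwise tau interaction
inference with TFCE permutation correction.  Because the cohort data such an
analysis is designed for are not redistributable, every stage is developed and
validated against a synthetic-data module with fully known ground truth.  This
note records the models, the parameters that matter, and the design choices
made where the underlying methodology leaves the implementation open.

## LC relative intensity (LC_RI)

The neuromelanin-sensitive turbo-spin-echo slab shows the LC as a small
hyperintense nucleus in the rostral pons.  Quantification proceeds in three
steps on a volume with left/right LC search-space masks and a large
pontomesencephalic reference mask already aligned to the image grid
(template registration is out of scope; masks are consumed in native space):

1. **Slicewise reference normalization.** Each axial slice is multiplied by
   `100 / mean(reference voxels in that slice)`, so the reference region
   averages exactly 100 in every slice.  This removes slicewise TSE shading
   and anchors all intensities to the reference; the operation is idempotent
   and makes the measure invariant to global intensity rescaling.  Slices
   without reference coverage cannot be normalized: they are excluded (set to
   zero, so they can never host candidate voxels), and if a search-space voxel
   lies on such a slice the session fails QC with the slice named.  A
   non-positive reference mean on a covered slice is a data error.
2. **Brightest-contiguous-voxel selection.** Within each search space the 10
   brightest mutually contiguous voxels are extracted.  "Contiguous" is not
   uniquely defined on a voxel grid; the default is 26-connectivity
   (face/edge/corner), because with anisotropic 0.7 x 0.7 x 1.8 mm voxels
   in-plane-only adjacency is too restrictive; 6 and 18 are available, and the
   same option also decides whether contiguity binds across slices.  Exact
   maximum-sum connected-k-subset selection is combinatorial, so selection is
   deterministic greedy region growing: seed at the search-space maximum, then
   repeatedly add the brightest adjacent voxel, breaking intensity ties by
   lexicographic voxel index.  By default growth restarts from each of the
   top-3 maxima and the region with the largest total is kept (`n_seeds=3`);
   single-seed growth can lodge on a locally bright spur and fall measurably
   below the exhaustive optimum, while the multi-seed variant matched
   brute-force enumeration on all seeded 4x4x1 test grids and remains fully
   deterministic.  `n_seeds=1` restores plain greedy.
3. **LC_RI.** The mean normalized intensity over each side's 10-voxel mask,
   averaged over left and right.  On a noiseless phantom with a planted
   contrast of 1.2 x reference, LC_RI is exactly 120.

Longitudinal QC compares the selected masks between sessions with per-side
Dice coefficients and centroid displacement in mm; pairs below a configurable
Dice threshold (default 0.5) are flagged for review.

## Degeneration slopes and trajectory models

The per-subject degeneration rate dLC_RI is the OLS slope of LC_RI on time.
Time is modelled in months since baseline MRI; slopes are reported per year
(x 12).  Subjects with fewer than two distinct time points are excluded with a
logged reason.

Three model families are exposed as `Model(...).fit() -> ModelResult`:

- `BaselineSlopeModel`: OLS of dLC_RI on baseline LC_RI, adjusting for age,
  sex and education.
- `LCTrajectoryModel`: `lc_ri ~ age_bl * time + sex + education + (1 | subject)`,
  optionally extended to `age_bl * time * abeta`.  Random intercept only — no
  random slopes — matching the written model structure exactly.
- `CognitionTrajectoryModel`:
  `score ~ time * bl_lc * abeta + time * dlc * abeta + age_bl + sex + education
  + (1 | subject)` per cognition domain (total, attention, immediate memory,
  delayed memory, language, visuospatial).  Both interaction families sit in a
  single fit so baseline LC and its rate of change control for one another.

**Standardization.** By default continuous predictors *and* the outcome are
z-scored before fitting and interaction columns are products of the
standardized mains; binary covariates (sex) are left as 0/1.  This is the
common convention for reporting standardized betas where the exact scheme is
not prescribed; `standardize_scale=False` gives raw-scale coefficients, and
the post-hoc `beta_raw * sd(x)/sd(y)` identity is verified in the tests for
the simple-regression case.

**Inference.** Mixed models are fitted by REML through statsmodels MixedLM.
Satterthwaite per-effect degrees of freedom are computed in-package: for the
random-intercept structure the marginal covariance is
`V_g = sigma^2 I + tau^2 11'` per subject, with closed-form inverse and
determinant, so the restricted likelihood, the contrast variance
`f(theta) = c'(X'V^-1 X)^-1 c`, and the observed information of the variance
parameters are all cheap; `df = 2 f^2 / (g' A g)` with `g` the gradient of
`f` and `A` the inverse observed REML information, both by central finite
differences on the log-variance scale (the quadratic form is invariant to
smooth reparameterization at the optimum).  Estimates, standard errors,
Satterthwaite df and p-values agree with lmerTest (R) on a frozen fixture to
at least 6, 4, and ~1 decimal places respectively.  When the information
matrix is not positive definite — typically a zero-boundary random-intercept
variance — the affected effects fall back to residual df and the result is
marked `df_method="residual"`.  Non-convergence of the backend is flagged on
the result, never raised.

## PET metrics

SUVR is mean target uptake over mean reference uptake.  Global amyloid burden
is the volume-weighted mean SUVR over the packaged roster of 20 neocortical
Desikan-Killiany regions: `SUVR_VW = sum(SUVR_i V_i) / sum(V_i)`.  The
summary is bounded by the regional extremes and invariant to region
reordering and to splitting a region into same-SUVR parts.  An optional
linear SUVR-to-centiloid mapping (slope/intercept supplied by the user —
tracer calibration is deliberately not baked in) supports binarization at a
positivity threshold of 30 cL; the boundary counts as positive (the open/closed
choice is not prescribed anywhere, so it is documented and configurable).

## Voxelwise tau inference

Per-subject tau maps are regressed voxelwise on
`bl_lc * abeta + dlc * abeta + age + sex + education + total GMV`
(intercept plus nine effect columns; continuous covariates z-scored,
interactions formed from the standardized mains).  Per-voxel OLS t-maps are
enhanced with TFCE, `TFCE(v) = sum_h e(h,v)^E h^H dh` with E = 0.5, H = 2.0,
integrated by the midpoint rule over 100 equal steps from 0 to the map
maximum (isolated-peak closed form reproduced to < 0.01%; `dh` and the step
count are configurable).  Cluster extent uses 26-connectivity.  A compiled
union-find sweep computes the same discrete integral as the straightforward
threshold-labelling loop (equivalence asserted in the tests); the loop remains
as a fallback.

Family-wise error is controlled by the max-TFCE permutation distribution,
default 5000 permutations (tests and the acceptance script use 200-500 to
keep desk-scale runtimes).  The permutation scheme is Freedman-Lane: the data
are residualized against the nuisance-only model, residuals are permuted, the
nuisance fit is added back, and the full model is refit — the standard choice
for GLM permutation with nuisance covariates; plain full-row permutation is
available for comparison.  `FWE-p = (1 + #{perm max >= observed}) / (1 + n_perm)`,
so the smallest attainable p is `1/(1+n_perm)` and p is monotone in observed
TFCE.  Positive and negative effects are two one-sided runs (the negative one
on the negated t-map) sharing the same permutations; each direction is
individually FWE-calibrated at its nominal level.  The analysis mask defaults
to all voxels and accepts an intersection mask.

## Synthetic data: what it emulates, and what it does not

`PhantomSpec` renders a 64 x 64 x 20 slab of 0.7 x 0.7 x 1.8 mm voxels: a
homogeneous reference box (~6300 mm^3), two ~640 mm^3 search-space boxes, and
a compact 12-voxel LC blob per side planted at `lc_true_intensity` (default
1.2, i.e. LC_RI 120) times the local reference level.  Per-slice
multiplicative drift (default 0.9-1.1) emulates TSE slab shading — chosen
multiplicative because slicewise normalization implies slicewise
multiplicative variation — and Gaussian scanner noise is added everywhere.
The grid is kept small so tests run in seconds; all geometry is configurable.

`CohortSpec` defaults encode the study conditions of a familial-risk aging
cohort: 199 subjects, 2-3 MRI sessions at 28.8 +/- 6.4-month intervals, age
68.3 +/- 5.2, baseline LC_RI 119.7 +/- 3.1 with an age gradient of -0.08
units/year of age, population decline -0.187 units/year, and ~7.5 annual
cognition visits per subject.  The observed slope spread of ~0.63 units/year
arises from a true between-subject slope SD of 0.2 combined with LC_RI
measurement noise of SD 1.0 at these intervals.  Global amyloid is a
two-component mixture (30% "elevated" at SUVR 1.60 +/- 0.20, the rest at
1.15 +/- 0.10) — the real-world distribution is not published, so these are
explicit placeholders.  Tau phantoms plant linear covariate effects (in SUVR
per SD of the z-scored term, sign configurable per region, mimicking the
occipital sign flip) inside designated boxes on a 16 x 16 x 8 grid; cognition
tables plant per-year fixed effects on time and its interactions with
baseline LC, dLC, amyloid and their three-way products, plus a subject random
intercept.  A `slope_bl_coupling` parameter plants a baseline-integrity ->
degeneration-rate dependence for recovery simulations.

Deliberately not emulated: MR physics and k-space artifacts, head motion,
registration error, PET counting statistics and partial-volume effects,
retrospective (negative-time) cognition visits, practice effects, dropout
that correlates with decline, and spatially correlated noise.  Passing tests
therefore demonstrate correctness of the estimators and calibration of the
inference under the stated generative model, not robustness to those
real-data complications.

## Numerical choices and degenerate inputs

- Intensity ties in voxel selection break by lexicographic index; all
  generators run from a single `numpy` Generator seed, so equal spec + seed
  reproduces outputs bitwise.
- Zero-variance columns are an error under standardization (a degenerate
  cohort, e.g. truly noiseless and effect-free, cannot be standardized).
- The random-intercept variance is floored at `1e-10 * sigma^2` before
  refinement so the log-scale optimizer stays finite on boundary fits.
- Satterthwaite df are capped at 10x the residual df to keep the finite-
  difference estimate from exploding when `g' A g` is tiny.
- The permutation engine treats the observed statistic as one member of its
  own null (the `+1` in numerator and denominator), guaranteeing valid p-values
  at any `n_perm`.

## Problem sizes

Simulation sizes are chosen so the full test suite runs on a laptop-class
single core: selection oracles enumerate 4x4x1 grids; phantom recovery uses
50 seeds; slope recovery 200 replicates of the n=199 cohort; mixed-model
type-I calibration 500 replicates of a 50-subject cohort with 3-6 visits;
FWE calibration 200 replicates of 30-subject 16x16x8 null stacks at 200
permutations, detection 50 runs at 500 permutations.  The acceptance script
reports the same quantities at comparable or slightly reduced replicate
counts.

## Known limitations

- The greedy selection rule is a documented stand-in for an unspecified
  "10 brightest contiguous" extraction; it is validated against brute force
  only on small grids.
- Satterthwaite df rely on finite-difference curvature of the REML surface;
  near-singular information matrices trigger the residual-df fallback rather
  than a warning-free wrong answer.
- Cognition visits are anchored at MRI baseline with non-negative times; the
  anchor is configurable in spirit (times are arbitrary in the model) but the
  generator does not produce retrospective visits.
- Real-data concerns — registration, motion, partial-volume correction,
  centiloid calibration — are explicitly outside this package's scope.
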