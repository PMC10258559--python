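# Methods

## The statistical model

`migvar` quantifies reproducibility of high-content cell-migration
features with a linear mixed-effects model containing a fixed intercept,
an optional two-level treatment fixed effect, and nested random
intercepts for laboratory, person, experiment, technical replicate and
cell. The within-cell, over-time residual is the innermost variance
component and is interpreted as temporal variability. All random
intercepts are centred Gaussians, independent across units and levels.
Estimation is maximum likelihood (not REML), matching the convention of
treating the reported components as plain ML point estimates; no
confidence intervals for variance components are produced.

Variability is categorised as *biological* (cell identity + temporal
residual) or *technical* (replicate + experiment + person + laboratory);
`decompose_variance` reports absolute and relative components per feature
and the technical share.

### Likelihood evaluation

The marginal covariance V = σ²ᵣI + Σₗ σ²ₗ ZₗZₗᵀ of nested one-hot designs
is hierarchically block-structured. The likelihood is computed exactly,
bottom-up: for each unit the sufficient statistics
(XᵀV⁻¹X, XᵀV⁻¹y, yᵀV⁻¹y, log|V|, and the projections XᵀV⁻¹1, yᵀV⁻¹1,
1ᵀV⁻¹1 onto the unit's all-ones vector) are updated by the rank-one
Woodbury identity when that unit's intercept variance is integrated out,
then summed into the parent. One pass from cells to laboratories costs
O(number of cells); fixed effects are profiled out by GLS at the root.
The cascade agrees with a dense-covariance evaluation to machine
precision and with `lme4`'s ML deviance to ~1e-5 on a cross-check dataset
(see `tests/test_lme4_crosscheck.py`).

### Optimisation and boundaries

Variances are optimised on the log scale (enforcing non-negativity) with
L-BFGS-B, `ftol` 1e-13, `gtol` 1e-8, at most 500 iterations; starting
values are nested method-of-moments estimates floored away from zero.
The fit is fully deterministic given the data. A component whose estimate
falls below 1e-5 of the response variance is pinned to exactly zero and
the remaining components are refitted; the pinned fit is kept only if the
log-likelihood is not meaningfully worse (2e-5 tolerance on −2logL). This
is how a component whose unconstrained optimum would be negative is
reported as exactly 0. A response lying exactly on the fixed-effect plane
(zero residual) is returned as a degenerate fit with all variances 0 and
infinite likelihood rather than an optimiser failure. Unbalanced data are
supported throughout via per-unit sufficient statistics.

### BLUPs

Random-intercept predictions come from Henderson's mixed-model equations,
assembled sparsely over all levels with positive variance and solved
directly; levels estimated at zero variance get BLUPs of exactly 0. The
intercept equation forces each level's BLUPs to sum to zero, so
corrections built from them preserve the grand mean. One accuracy
ceiling is worth knowing: a BLUP predicts a unit's deviation around the
*estimated* parent mean, so with m siblings per parent the correlation
between BLUPs and the true intercepts cannot exceed ≈ √(1−1/m) even with
unlimited data per unit. With triplet designs (m = 3) that ceiling is
≈ 0.82 at the technical levels; at the cell level (50 cells per
replicate) predictions are essentially unshrunken in this respect and
track the truth closely.

## Batch-effect removal

Each observation is corrected by subtracting the BLUPs of the technical
levels on its design path — laboratory, person, experiment, replicate —
from the feature value. Fixed effects are untouched: since only random
intercepts are subtracted, the baseline and the treatment effect remain
in the corrected values with no re-addition step. Cell-level and
temporal variation are retained as biological signal; subtracting the
observation-level residual as well would annihilate all within-condition
variation, which contradicts the purpose of the correction, so the
correction deliberately stops at the replicate level. The model used for
correction must be the *joint* fit over both conditions with the
treatment fixed effect — correcting a two-condition table with a model
lacking the effect is an error, because the random intercepts of a
single-arm fit would absorb part of the perturbation.

Because a BLUP absorbs both the unit's true intercept and the sampling
noise of its unit mean, corrected unit means are slightly
*under*-dispersed relative to the biological noise below them; a refit on
corrected data therefore drives the technical components to the zero
boundary rather than leaving an "unshrunk residue". In balanced designs
the condition-wise sums of replicate BLUPs cancel, so the raw treatment
contrast moves only at numerical precision.

The 3D variant applies the same mechanics to per-nucleus spheroid
migration distances with levels laboratory/experiment/replicate plus a
spheroid random level (retained), and the collagen density as condition.

## Cumulative variability

The per-subdataset statistic is the sample variance (n−1 denominator) of
the per-technical-replicate mean feature values. This choice — variance
of replicate means — is an interpretation: it captures the accumulating
technical spread among the design's atomic units while being insensitive
to the (much larger) within-replicate biological spread. Subdatasets are
enumerated exhaustively at each level: k ∈ {2,3} units sharing one
complete ancestry path, all lower levels complete, giving
(#parent paths) × C(n, k) subdatasets per (level, k). Curves are reported
as the full distribution plus the per-level mean. The randomised control
permutes the replicate means globally across design positions (preserving
within-replicate structure) before the same enumeration; a fixed seed
fixes the permutation. Curves are computed within a single condition.

## Feature extraction

The 15 segmentation-derived variables are cell area, perimeter, form
factor (4πA/P²), eccentricity, solidity, extent, major/minor axis length,
equivalent diameter, nucleus area, nucleus perimeter, nucleus form
factor, nucleus-to-cell area ratio, cell-centroid speed, and
nucleus–cell centroid offset; plus protrusion, retraction and short-lived
areas this makes the 18-variable inventory. The exact panel of morphology
measurements is a documented package choice of standard profiler
variables of cell and nucleus.

Numerical conventions: 8-connectivity for regions; perimeter by the
4-direction Crofton estimator, which is nearly unbiased on smooth shapes
(a naive boundary count overestimates a circle's perimeter by ~7% and
would distort the form factor); pixel-centre coordinates, origin
top-left, x rightward, y downward, scaled by the pixel size; form factor
clipped at 1 against discretisation overshoot on small regions.

Dynamic regions per cell and frame: protrusion = pixels present now,
absent in the previous frame; retraction = present now, absent in the
next; short-lived = absent in both neighbours (lifetime under one frame
interval, i.e. < 10 min on the 5-min schedule). Areas are per-frame
totals (regions are not individually tracked); the first/last frames have
undefined protrusion/retraction respectively, and a label present now but
in neither neighbour is flagged as a whole-cell appearance and excluded.
Short-lived area is a subset of both parents, so it can never exceed
either — a property the tests verify exactly against per-pixel set
arithmetic.

Tracking is greedy nearest-neighbour on nucleus centroids in frame
order: candidate links sorted by distance (ties by lower track id, then
label), one-to-one, never beyond the gate distance; an unmatched
detection opens a new track. This is a deterministic rendering of
"track by nucleus distance"; it is not a global-optimum tracker.

## Trajectory preparation

QC removes records whose cell area exceeds the Tukey fence
Q3 + 1.5·IQR of all cell areas (quantiles by linear interpolation
between order statistics) and records with nucleus area < 100 µm², then
drops duplicated trajectories (two tracks sharing ≥ 50% identical
centroid records — the higher id is removed) and merged trajectories
(distinct tracks colliding on identical centroid records — both removed).
The area rules are applied per record; the paper-style exclusion of
"static and rounded" cells by eye has no automated equivalent here and is
deliberately out of scope (a net-displacement heuristic can be emulated
by filtering on the ICS columns, but nothing is applied by default).
Strict idempotence of a Tukey filter is not guaranteed when the fence is
recomputed on filtered data; the fitted fence is therefore reported in
the QC report and can be passed back in, which makes the filter exactly
idempotent.

Smoothing is a centred rolling mean with window 9; at the ends the window
shrinks symmetrically to the largest odd size that fits (a truncate mode
that drops 4 frames per end is available). ICS is the Euclidean
displacement of the smoothed positions per interval divided by the frame
interval, in µm/min, assigned to the later frame — 73 frames on the
5-minute, 6-hour schedule give exactly 72 values per cell. µm/min (rather
than µm/interval) is a unit choice that affects scale only. Z-scoring
standardises each feature over all pooled observations to mean 0 and
sample SD 1 (zero-variance features are dropped with a warning); PCA runs
on the z-scored table with a deterministic sign convention (the
largest-magnitude loading of each component is positive). Pooling both
conditions is the default; restrict the table first for single-condition
analyses.

## 3D spheroid invasion

The core sphere is the unique sphere through four annotated surface
points, obtained from the pairwise-equidistance linear system; a
condition-number guard rejects (near-)coplanar annotations. Migration
distance is signed: d = ‖nucleus − centre‖ − radius, negative inside the
core (summaries can clamp at 0). Detection quality uses greedy
one-to-one matching by increasing distance within a configurable match
radius (default 5 µm, a typical nuclear-radius scale; no published value
exists for this choice): precision = TP/#segmented,
recall = TP/#annotated, with precision undefined (NaN) for an empty
segmentation. Border-touching segments are emulated by a bounding-box
margin filter on centroids. Greedy matching equals the optimal assignment
whenever annotations are separated by more than twice the match radius,
which holds for well-spread nuclei; the tests check this regime against
an optimal-assignment oracle.

## The synthetic-data generator

The generator emulates the multisite study design: 3 laboratories ×
3 persons × 3 experiments × 2 conditions × 3 technical replicates, ~50
cells per replicate, 72 time points at 5-minute intervals (the default
`DesignSpec`). Random intercepts are drawn independently per unit from
centred normals; the residual is white noise per time point — no temporal
autocorrelation, a deliberate simplification of real migration
time-series. Multi-feature tables are independent draws per feature (no
cross-feature correlation), sufficient for PCA plumbing but not a model
of real feature covariance. Mask movies are rasterised disks
(pixel-centre-in-shape) with scripted velocities and transient boundary
bumps, persistent labels, nuclei strictly inside cells, no overlap or
border contact; they are born segmented. Scenes for 3D are four
non-coplanar points placed exactly on a known core sphere and nuclei at
scripted signed radial offsets.

What passing tests therefore show: the estimator, the correction, the
curve enumeration and the geometry are correct *given* the hierarchical
Gaussian structure and clean segmentations. What they do not show:
robustness to segmentation errors, temporal autocorrelation, non-Gaussian
feature distributions, or cell division/collision — none of which the
generator produces.

## Problem sizes and tolerances

Simulation-based checks run the full design hierarchy scaled to 10 cells
× 24 time points (38,880 observations; ~1 s per fit), 20 seeds for
recovery/correction statistics and the cumulative-variability curve
(5 cells × 12 time points there); these sizes are the package's choice of
a desk-scale experiment that keeps all 162 replicate groups of the design.
Oracle equivalence uses 50 random datasets of ≤ 60 observations against
direct dense-covariance ML (|ΔlogL| ≤ 1e-4); mask differencing is checked
exactly on 100 random scripted movies; sphere recovery to 1e-9 relative.
Monte-Carlo assertions use 3 standard errors across seeds. The
lab-variance estimate deserves a caveat that no tolerance hides: with
three laboratories, single-study estimates of σ²_lab are extremely noisy
and ML-biased low by roughly a third; only the cross-seed mean is a
meaningful recovery check.

## Known limitations

- Crossed (non-nested) random effects, random slopes and non-Gaussian
  responses are out of scope; "cell" is strictly nested in replicate.
- ML is the default and the convention for all reported components, so
  they inherit ML's small-sample downward bias at the outer levels;
  `fit_nested_lme(..., reml=True)` maximises the restricted likelihood
  instead for sensitivity checks (it reproduces the classical ANOVA
  estimator exactly on balanced one-level data).
- The cumulative-variability statistic (variance of replicate means) is
  one defensible reading of a loosely specified procedure; alternatives
  (e.g. pooled observation variance) would scale the curve differently.
- The correction subtracts technical BLUPs only; no location-scale or
  empirical-Bayes-family alternatives are implemented or compared.
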