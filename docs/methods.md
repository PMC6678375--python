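# Methods

This note documents the models implemented in `canopyaroma`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about field data.

## Gap analysis and canopy architecture

The unit of analysis is a binary raster (`True` = foliage) obtained either
from an upward-looking photograph, where the sky is the background, or
from an aerial per-tree sub-image, where the inter-row is the background.
Both orientations are treated identically: the aerial sub-image is a
nadir view with the same gap-geometry semantics as a zenith view.

The raster is subdivided into an `m × n` grid (default 5 × 5). A cell
whose gap fraction reaches the big-gap threshold (default 0.75)
contributes all of its gap pixels as *large* gaps — gaps between crowns
rather than within them. From whole-mask tallies (`t_p` total pixels,
`t_g` gap, `l_g` large-gap):

    ff   = 1 − t_g / t_p           foliage projective cover
    fc   = 1 − l_g / t_p           crown cover
    Φ    = 1 − ff / fc             crown porosity
    LAI  = −fc · ln(Φ) / k         Beer's-law inversion
    Ω(0) = (1 − Φ) ln(1 − ff) / (ff · ln Φ)
    LAI_e = LAI · Ω(0)

These are the canonical cover-photography forms: they satisfy the
internal identities Φ = 1 − ff/fc and, when there are no large gaps
(fc = 1, so Φ = 1 − ff), Ω(0) reduces to exactly 1 — the
random-dispersion limit. The identity holds to the last floating-point
bit in this implementation because numerator and denominator evaluate the
same product, which the test suite asserts.

**Large-gap semantics.** The threshold rule is applied at cell level: a
cell at or above the threshold contributes *all* its gap pixels as large.
An alternative connected-component mode (a contiguous sky region is large
when it covers at least the threshold fraction of its cell) is available
via `AnalysisSettings(large_gap_mode="component")`; the cell rule is the
default because it is simpler, deterministic under subdivision, and the
two agree on the solid-block geometries that dominate between-crown gaps.

**Parameters.**

| parameter | default | units | rationale |
|---|---|---|---|
| grid `m × n` | 5 × 5 | – | standard cover-photography subdivision for ~1 MP images |
| big-gap threshold | 0.75 | fraction | between-crown sky dominates a cell at this level |
| `k` (light extinction) | 0.7 | – | cocoa-canopy value; 0.61 is the common broadleaf default and is accepted as a config scalar. Back-substituting the packaged per-tree table (LAI vs −fc·lnΦ) is more consistent with 0.61, so published per-tree values may reflect either constant — `k` is therefore never hard-coded |
| porosity floor ε | 1e−6 | fraction | keeps ln Φ finite for solid canopies |

**Degenerate conventions.** An all-sky mask returns the empty record
(ff = fc = 0, Φ = 1, LAI = LAI_e = 0, Ω = 1, `empty_flag`); Φ is floored
at ε before the logarithm; ff = 1 uses 1 − ε inside ln(1 − ff). Outputs
stay finite and flagged instead of erroring mid-pipeline. Remainder
pixels when the image size is not divisible by the grid attach to the
last row/column of cells, so no pixel is dropped.

## Segmentation

Upward images threshold the **blue channel** (sky and cloud are bright in
blue); pixels above the threshold are gap. Aerial tiles threshold the
**CIELab a\* channel** (green vegetation has negative a\*); pixels at or
below the threshold are foliage. The automatic threshold is Otsu's
criterion; a fixed level is accepted for reproducibility. On a constant
channel Otsu is undefined and the midpoint of the channel's physical
range (127.5 for blue, 0 for a\*) is used with a warning, which keeps the
polarity right for uniform sky, foliage or soil tiles.

When a whole block is analyzed (`analyze_plantation`), the automatic a\*
threshold is computed **once from the block's full histogram** and applied
to every tile. Per-tile Otsu fails on tiles that contain only inter-row
soil: with no second class present it splits sensor noise and invents
foliage, which would make empty planting positions undetectable. The
block histogram is strongly bimodal (canopy vs inter-row), so one global
threshold is both more robust and closer to how a practitioner would
segment the mosaic. `assess_tree_cell` keeps per-tile behaviour when
called directly.

## Plantation gridding and georeferencing

A block crop is partitioned into a fixed grid from the planting geometry:
rows of the grid run along planting rows with the tree spacing (2 m
default), columns across rows with the row spacing (5 m default);
`n = round(extent / spacing)` per axis, minimum 1 with a warning when the
block is smaller than one spacing. The tiling is exhaustive and
non-overlapping. No crown detection is attempted — the grid *is* the
planting plan.

A position whose crown cover falls below 0.1 is a **missing tree** and
carries a zeroed architecture. The comparison direction is configurable
(`missing_when_below=False` inverts it) because the opposite reading
exists in the field literature; "low cover ⇒ missing" is the default as
the only physically sensible direction.

Cell centres are georeferenced by bilinear interpolation of the block's
four corner coordinates at fractional grid positions
`((row + 0.5)/n_rows, (col + 0.5)/n_cols)`. For corners forming a
parallelogram this is the exact affine placement; for non-affine corner
sets it degrades gracefully. Grid origin is the first corner; the row
direction runs from corner 1 to corner 3.

## The canopy-to-aroma network

A 6 → H → 6 feedforward net with tan-sigmoid hidden units and linear
outputs, H ∈ {3, 5, 7, 10} in the trimming assessment. Inputs (LAI,
LAI_e, ff, fc, Φ, Ω) and targets (six GC peak areas) are min-max
normalized to [−1, 1] with specs fitted on training rows only; constant
columns map to 0 with a warning. The split is random, seed-reproducible,
with `n_test = round(0.15 · n)` (half-up), giving 147/26 on 173 samples.

Training minimizes `F(w) = β·E_D + α·E_W` (`E_D` sum of squared errors,
`E_W` sum of squared weights) by damped Gauss–Newton/Levenberg–Marquardt
steps on the analytic Jacobian. After each accepted step the
regularization hyperparameters are re-estimated by the evidence
framework: with `H = 2β JᵀJ + 2α I` and effective parameter count
`γ = N_w − 2α·tr(H⁻¹)`,

    α ← γ / (2 E_W),     β ← (N − γ) / (2 E_D).

α starts at 0 and β at 1 (pure error minimization until the first
evidence update). γ is clipped to [1, min(N_w, N)] and E_D, E_W are
floored at 1e−12 so noiseless datasets cannot divide by zero. The damping
factor μ starts at 0.005, multiplies by 10 on rejected steps (up to 1e10,
then the fit stops at a local minimum of F) and by 0.1 on accepted ones.
Stopping: gradient infinity-norm or relative objective decrease below
`tol` (1e−7), or `max_epochs` (1000). Weights initialize uniformly in
[−0.5, 0.5] scaled by 1/√fan-in from a seeded generator; three seeded
restarts are trained and the lowest final objective kept, so the whole
fit is deterministic for a fixed `random_state`.

**Scoring.** R and MSE are pooled over samples × 6 targets on the
normalized scale — a 173-sample set pools 1038 observations — because
that is the natural accounting for a multi-output fit report; per-stage
entries carry sample and observation counts. The outlier fraction is the
share of pooled points outside the 95 % prediction band of the
predicted-vs-observed regression line. Constant pooled vectors report
R = 0 with a `degenerate` flag.

**Architecture selection.** One net per candidate size; the winner has
the highest test R among candidates whose |train MSE − test MSE| stays
below the overfitting gap (0.05 normalized units; all candidates if none
qualify). Test-R ties within 1e−3 resolve toward the smallest network —
the parsimony tie-break.

**Prediction.** Stored normalization specs are applied, the forward pass
runs, outputs denormalize, and predictions clamp to the fixed map scale
[0, 60 × 10³] area units. Feature rows outside the training min/max
trigger an extrapolation warning but still predict.

## Spatial mapping

The empirical semivariogram uses 12 distance bins up to half the maximum
pairwise distance, weighted by pair counts, and is fitted by bounded
weighted least squares for a spherical (default), exponential or Gaussian
family (the latter two parameterized with the conventional factor 3 so
`range` is the practical range). Ordinary kriging solves the constrained
system per target point; the unit-sum weight constraint and the
exact-interpolation property at zero nugget are asserted numerically in
tests. Singular systems are retried with a jittered diagonal and a
warning. Rasters cover the points' bounding box padded by one cell at
0.5 m resolution (finer than the 2 m tree spacing — a rendering choice)
and are clamped to the variable's fixed scale (0–6 for LAI_e,
0–60 × 10³ for aromas).

Missing trees enter LAI_e layers as value 0 (an unplanted position has
zero canopy, and including it renders the gaps visibly) but are excluded
from aroma layers (no bean sample exists at an empty position); both
behaviours are arguments. Raster export is CSV and plain TIFF; scatter
layers export CSV; PNG rendering uses the variable's fixed colour scale.

## Field statistics

Per-tree summaries average the replicate images of each coded tree
(`B{block}C{number}{row}`); SD is the sample standard deviation, 0 for a
single image. Block summaries are **tree-weighted** by default (each tree
counts once), which is the weighting that reproduces the packaged
per-tree table's block aggregation; image-weighted pooling is available
because unbalanced replicate counts (6–9 images per tree) make the two
differ in the second decimal for some cells.

One note on the packaged table: its two cover columns are named
`canopy_cover` and `crown_cover` following the source table's printed
headers, but the porosity identity Φ = 1 − ff/fc shows the `canopy_cover`
column holds the foliage-projective-cover values (it is the smaller of
the two and 1 − col₁/col₂ matches the printed porosity). Downstream code
indexes these columns by name only.

ANOVA is one-way with images as replicates. Post-hoc comparisons use the
Tukey–Kramer studentized-range statistic with quantiles from the
numerically integrated range distribution (no table lookup), valid for
unequal group sizes. The compact letter display uses insert-and-absorb:
start from one column covering all groups, split on each significant
pair, absorb subset columns, and letter the surviving columns in input
order. Groups share a letter exactly when they are not significantly
different at α (default 0.05); with zero within-group variance everywhere
there is no error term and all groups share one letter, with a warning.

## Synthetic data: what it emulates, and what it does not

`gen_canopy_mask` draws masks whose gap fraction is `exp(−k·LAI)` — the
Beer's-law relation the analysis inverts. Random mode is an independent
Bernoulli field: crown cover is 1 and the clumping index ≈ 1, so recovery
of the true LAI tests the inversion in its own model. Clumped mode
concentrates the identical gap budget into discs anchored at distinct
analysis-grid cells (grown or trimmed pixel-by-pixel to hit the budget
exactly), producing large-gap cells and Ω(0) < 1 at the same total gap
fraction. Infeasible geometries (disc radius beyond half the image, more
discs than grid cells) raise.

`gen_plantation_scene` renders green crowns (ellipses with the π/4 area
correction, adjusted pixel-by-pixel to the requested cover exactly) on a
noisy brown inter-row, with chosen positions left empty, and returns the
matching block layout anchored at the study site's coordinates.

`gen_aroma_dataset` draws internally consistent feature vectors over the
observed field ranges (LAI 2.30–4.56, crown cover 0.775–0.994, porosity
0.056–0.188, clumping 0.723–0.986; ff and LAI_e derived from the
identities ff = fc(1 − Φ), LAI_e = LAI·Ω) and maps them through a fixed,
seeded 6 → 6 teacher (unit-row-norm random linear map, gain 1.2, tanh
squashing, rescaled to [0, 60 × 10³]) plus Gaussian noise. The default
noise SD of 10 × 10³ area units was chosen once so that the noiseless
teacher — the Bayes-optimal predictor — correlates with the noisy targets
at roughly R = 0.85–0.87, the accuracy regime reported for canopy-based
aroma models; tests require the trained network to come within 0.1 of
that oracle.

**Limits of synthetic validation.** Passing these tests shows the
algorithms are implemented correctly in their own generative models. It
does not show that field photographs segment as cleanly (sun glare,
clouds, weeds and neighbouring canopies are not simulated — unsuitable
images are excluded by a manual list, not a classifier), that real cocoa
canopies follow Beer's law with a single k, that real aroma chemistry is
a smooth function of six canopy features, or that a plantation's spatial
covariance matches a stationary variogram. No fisheye/hemispherical
projection model is included (zenith angle fixed at 0°), there is no
orthorectification, and kriging offers no universal/co-kriging variants.

## Problem sizes

Default test and acceptance runs use 400–1000 px square masks, 173-sample
aroma datasets, 4 × 4 to 6 × 8 plantation scenes and ≤ 200-point kriging
layers — sizes at which every Monte-Carlo tolerance in the suite is
comfortably stable and a full run completes in well under a minute of
compute per module.
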