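# Methods

## Problem and model

Child growth is monitored through height-for-age and weight-for-age
z-scores (HAZ, WAZ), which standardise a child's anthropometry against a
reference population.  To judge whether a change between two ages is
normal, one needs the correlation `r12` between z-scores at those ages:
the conditional standard deviation score

    Z_{2|1} = (Z2 - r12 * Z1) / sqrt(1 - r12^2)

is the standardised residual of the second score given the first under a
bivariate-normal working model.  It has mean 0 and variance 1 in the
reference population and corrects the naive difference `Z2 - Z1` for
regression to the mean: an extreme child is expected to rebound, and the
cSDS charges them for failing to.

No single study observes all age pairs.  `growthcorr` therefore builds a
single complete age-by-age correlation matrix from many heterogeneous
longitudinal studies in two stages:

1. **Elementwise meta-analysis.**  Each study's smooth correlation
   matrix is aligned to a master weekly age grid.  For every grid entry,
   the correlations of the studies covering that age pair are pooled by
   a univariate random-effects meta-analysis on the Fisher-z scale
   (`atanh`), with sampling variance `1/(n_ij - 3)` where `n_ij` counts
   children observed in both bins, between-study heterogeneity `tau^2`
   estimated per entry by DerSimonian–Laird, and inverse-variance
   weights `1/(sigma^2 + tau^2)`.  Entries no study covers stay missing.
2. **Surface smoothing.**  The incomplete, noisy Fisher-scale surface is
   smoothed with a symmetry-constrained bivariate P-spline; the fit is
   evaluated on every grid cell, filling the uncovered regions, then
   back-transformed and renormalised
   (`rho_ij / sqrt(rho_ii * rho_jj)`) to a complete, symmetric matrix
   with an exact unit diagonal.  The stage-1 confidence bounds are
   smoothed the same way; their difference is the uncertainty surface.

The split design makes updates incremental: a new study only requires
its own matrix plus a re-run of the cheap combine-and-smooth stages, and
the package verifies that this reproduces the from-scratch result
bitwise.

## Age grid

Ages are integer days with birth at day 0.  The default grid covers
0–6570 days (18 years) in 7-day bins with `bin = round(day/7)`
(ties-to-even), giving exactly 940 bins; `7*bin` is both the centre of
each bin's day range and its representative age.  The convention is the
only simple rounding under which the 0–6570-day range yields 940 bins.
Any bin width is supported; the analyses shipped here use a reduced
200-bin grid (33-day bins) to keep a full multi-study run on one desktop
core in about a minute.

## Study-level correlation matrices

A study's matrix is estimated functional-data style.  A penalized cubic
B-spline regression of z on age (35 basis functions, second-order
difference penalty, GCV-selected penalty) gives the study mean; for each
child all ordered pairs of *distinct* visits contribute residual
cross-products `e_i * e_j`.  Same-visit squares are kept out: they carry
the measurement-error nugget, which would otherwise attenuate every
correlation by `v/(v + sigma_noise^2)`.  The cross-products are averaged
within fine weekly age-pair cells and smoothed with a symmetric
tensor-product P-spline in age-day coordinates, with cell counts as
weights; the smooth surface is evaluated at the output grid's
representative ages and normalised to correlations.

Two resolution choices matter and were set after observing clear failure
modes of the alternatives:

- **Fine-resolution fitting.**  Aggregating products at the output-grid
  resolution places within-cell pairs (mean separation about a third of
  the cell width) at lag-0 coordinates, biasing the fitted variance low
  and inflating every correlation — about 20% at 33-day cells under an
  exponential truth with a 150-day range.  Weekly aggregation makes the
  bias negligible regardless of the output grid.
- **Span-scaled basis.**  The marginal basis size is
  `min(35, span_weeks/2)`: knots must resolve the near-diagonal apex of
  the covariance surface, whose width is the correlation range, not the
  output grid's bin width.

Entries informed by fewer than `n_min = 10` children (configurable), or
with smoothed variance below `1e-8`, are masked; off-diagonal entries
are clipped to ±0.999 (as everywhere in the pipeline, so `atanh` stays
finite); the diagonal is set exactly to 1.

A structural caveat: with only cross-visit products, the variance is
identified through smooth extrapolation of the surface to the diagonal.
Studies whose visit schedule contains no short gaps carry no information
about correlation at lags below their minimum gap, and their short-lag
correlations saturate toward 1.  This is a property of any nugget-free
covariance smoother, not of this implementation; the meta-analysis
tempers but cannot remove it, which is the main reason near-diagonal
pooled estimates sit slightly high.

## Stage-1 pooling

Pooling is vectorised over all grid entries at once.  Per entry, studies
present contribute `f = atanh(c)` with variance `1/(n_ij - 3)`
(entries with `n_ij <= 3` are treated as missing, not errors);
DerSimonian–Laird `tau^2 = max(0, (Q - (K-1))/C)` uses fixed-effect
weights; a single study passes through unchanged.  `tau^2` is estimated
per entry by default — elementwise calls to a standard meta-analysis
routine estimate it that way — with a shared-`tau^2` mode behind a flag.
95% normal-theory intervals `m ± 1.96 se` are back-transformed with
`tanh`, which preserves their ordering.  The per-entry study count is
recorded; it reproduces the familiar coverage heat-map of such pooled
designs (dense for infancy, a single long study for older ages, empty
young-age × old-age corners).

## Stage-2 smoothing

The smoother is a tensor-product cubic B-spline surface with
second-order difference penalties along both axes and the coefficient
matrix constrained to be symmetric by half-parameterisation (only the
upper triangle of the coefficient matrix is estimated), so the fitted
surface is symmetric by construction.  The default marginal basis is
`max(8, min(40, r/5))` functions on an `r`-bin grid.  Fitting uses the
observed off-diagonal cells only (the unit diagonal is removed first —
it is an artefact of the correlation scale, not data), with weights
equal to the inverse squared meta-analytic standard error, capped at
their 95th percentile so a few very dense cells cannot dominate; an
unweighted mode matching the homoscedastic working model is available.
Normal equations are accumulated in chunks, and both GCV and
cross-validation scores are computed from the accumulated blocks, so
memory and time stay modest even at the full 940-bin grid.

Two selection/normalisation choices deviate from the obvious defaults,
for cause:

- **Smoothing parameter by spatially blocked cross-validation.**  Plain
  GCV is nearly flat (within 1%) across four orders of magnitude of
  `lambda` here — cell errors are correlated and heteroscedastic — while
  the quality of extrapolation into never-observed regions varies
  drastically over the same range, and GCV's argmin systematically
  undersmooths it.  Stage 2's defining job is exactly that
  extrapolation, so `lambda` is chosen by tiling the grid into 12×12
  blocks, holding out each block together with its mirror (symmetric
  cells duplicate information and would leak), and scoring weighted
  prediction error on the held-out cells; the largest `lambda` within 5%
  of the best score is taken, a standard parsimony rule for flat CV
  curves.  The selected `lambda` is shared by the CI-bound surfaces.
  Plain GCV remains available (`lam="gcv"`), and the lower-level
  `symmetric_pspline_fit` defaults to it.
- **Normalisation diagonal by local extrapolation.**  The true
  correlation surface equals 1 on the diagonal by definition, but a
  40-function basis (knots every ~165 days on the default grid) rounds
  the near-diagonal apex and under-reads its own diagonal — by over 30%
  for truths with a 150-day correlation range, occasionally crossing
  zero at grid corners.  Dividing by that value corrupts the whole
  matrix.  The normaliser `rho_ii` is instead estimated per bin by a
  weighted quadratic extrapolation, in lag, of the observed Fisher
  values within 6 cells of the diagonal, clipped between the largest
  observed band value and `atanh(0.9995)`.  The published normalisation
  formula is applied unchanged; only the estimator of its denominator
  differs, and `finalize_correlation` without the override still uses
  the surface's own diagonal.

After normalisation the diagonal is set exactly to 1 and off-diagonal
entries clipped to ±0.999 (clips are logged).  Positive
semi-definiteness is *not* enforced by default — single `r` lookups for
cSDS only need entries in (−1, 1) — but a flag-gated projection to the
nearest correlation matrix (eigenvalue clipping, via statsmodels) is
provided.

## Synthetic data

The generator emulates the structure of the 16 pooled growth studies:
their published child counts, age windows, and visits-per-child
minima/medians/maxima (the one study whose window reaches past day 6570
is clamped to the grid ceiling).  Visit ages are uniform without
replacement inside the window; visit counts are drawn from a two-piece
uniform pinned at the published median.  Each child's latent trajectory
is sampled exactly (per-child Cholesky) from a zero-mean, unit-variance
Gaussian process with a configurable correlation family — exchangeable,
exponential `exp(-|s-t|/phi)`, or user-supplied — plus study-specific
i.i.d. measurement noise.  Measurement-error SDs are not published;
fixed study-specific values between 0.1 and 0.4 are assigned once.
Per-study RNG streams are derived by stable hashing of the study id, so
adding a study never perturbs the data of the others, and identical
configs are byte-identical.

What the generator does **not** emulate: protocol-driven visit
schedules (a jittered-schedule mode is a natural extension), dropout
that depends on growth, secular trends, age-varying process variance,
and any non-Gaussianity of real z-scores.  Passing the recovery tests
therefore shows the estimator chain is correct and well-calibrated under
a known smooth truth at realistic sparsity — not that real growth data
satisfy the model.

Note one identifiability fact exposed by the exchangeable family: a
truth that is discontinuous at the diagonal (constant correlation
`rho0 < 1` at all non-zero lags) cannot be distinguished, by any
estimator that excludes same-visit products, from a continuous truth
with variance equal to the off-diagonal limit.  The nugget-exclusion
property is therefore demonstrated with the mean-square continuous
exponential family, where it is well-posed; the exchangeable family is
validated at the generator level (empirical between-visit correlation).

## Problem sizes and numerical defaults

The shipped analyses run the full 16-study design (about 18,000
children, 200,000 observations) on a 200-bin grid (33-day bins), which
completes in roughly a minute on one core; the weekly 940-bin grid is
supported by the same chunked code paths.  End-to-end, the pipeline
recovers an exponential truth (`phi` = 150 days) with mean absolute
error below 0.07 on entries covered by three or more studies and below
0.15 on entries no study observed, across multiple generator seeds.
Other defaults: lambda ladder `10^-2 … 10^6` in half-decade steps;
conditioning ridge `1e-10` relative to the design scale (small enough to
keep null-space reproduction exact to `1e-6`); 95% CIs; reporting of
cSDS at 2 decimal places with full precision retained internally.
Consecutive same-bin observations in dynamic cSDS series are skipped
with a warning rather than dividing by zero at `r = 1`.

## Known limitations

- Near-diagonal pooled correlations are biased upward when studies lack
  short visit gaps (see above); entries at one or two bins' lag should
  be read with that in mind.
- The final matrix is not guaranteed PSD without the optional
  projection.
- Fisher variance `1/(n-3)` treats each study's smoothed correlation as
  a sample correlation from `n_ij` independent pairs; it ignores the
  smoothing already applied at the study level, so stage-1 standard
  errors are approximate.
- CI surfaces are smoothed independently of the point estimate; after
  renormalisation the bounds are not guaranteed to bracket it cell by
  cell (crossings are floored at zero width and logged).
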