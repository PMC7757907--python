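# Methods

This note documents the models implemented in `zonarisk`, the defaults and
why they were chosen, what the synthetic landscapes do and do not emulate,
and the numerical decisions that affect results.

## Occurrence processing

Records arrive georeferenced (WGS84 decimal degrees). Cleaning drops rows
with unparseable or out-of-range coordinates and logs them; deduplication
removes *exact* (lon, lat) repeats, keeping the first — near-duplicates are
deliberately left to the spatial filter, avoiding an undocumented fuzz
radius. Spatial thinning is a greedy single pass in file order: a record is
kept iff it lies at least `min_km` (default 10 km) from every previously
kept record, measured as great-circle (haversine) distance with Earth
radius 6371.0088 km. Greedy input-order thinning is deterministic and
reproducible; it does not attempt the (NP-hard) maximum retained set. The
retained set provably satisfies the pairwise minimum distance, and thinning
is idempotent. Every filter appends an `(n_in, n_kept, n_removed)` entry to
the set's provenance log, and the counts must reconcile.

## Collinearity pruning

Pairwise Pearson correlations are computed complete-case over cells valid
in *every* layer (optionally a seeded subsample via `max_cells`, for large
grids). Elimination follows the "find correlation" heuristic: while any
retained pair exceeds the cutoff (default |r| > 0.7), locate the worst
pair and drop the member with the larger mean absolute correlation against
all other retained layers; ties break on layer name. Each step removes one
layer, so termination is guaranteed, and the retained set never contains a
pair above the cutoff (asserted in tests by exhaustive scan). A constant
layer has undefined correlations; it is reported as NaN, warned about, and
treated as uncorrelated during elimination.

## The niche model

The model is a Gibbs density `q_λ(x) = exp(λ·f(x))/Z` over a finite point
universe: a uniform background sample of valid cells (default 10,000,
without replacement) plus the training presences. The objective is the
L1-penalized mean presence log-likelihood. Feature classes are linear,
quadratic, and forward/reverse hinges at 20 evenly spaced interior knots
per variable per direction (config-exposed; a modest count keeps desk runs
fast while leaving the response curves flexible); every feature lives in
[0, 1] after min–max scaling of each covariate over the training universe.
Prediction inputs outside the training range are clamped to the scaling
interval and logged.

Per-feature penalties are

    β_j = base(class) · r · s_j / √m,

with `r` the regularization multiplier (default 2), `m` the presence
count, `s_j` the feature's standard deviation over the presences (floored
at 0.05 so features absent from all presences stay penalized), and base
1.0 for linear/quadratic and 0.5 for hinge features. This is the
error-bound scaling used by maximum-entropy niche modelling software: a
coefficient moves only when a feature's presence mean differs from its
background expectation by more than roughly its standard error. Dropping
the `s_j` factor makes any class-level base that tames the hinge ladder
zero out *all* coefficients at small m, because per-feature gradients
scale with the feature's spread.

The optimizer is cyclic coordinate descent: per coordinate a Newton step
on the smooth part, soft-thresholded for the L1 term, then halved until
the penalized objective does not decrease (so the objective trace is
non-decreasing, asserted in tests). Convergence: objective improvement per
sweep below `tol` (1e-6) or `max_iter` (500) sweeps, in which case the
model is returned with a warning flag. Every accepted update's objective
improvement is credited to the variable owning the feature; normalized
credits are the percent-contribution scores (zero total gain yields
uniform contributions with a warning).

The logistic output is `p = e^H·q/(1 + e^H·q)` with `H` the entropy (nats)
of the fitted distribution over the universe, so the all-zero model
predicts exactly 0.5 and `p` is a monotone transform of the raw score
(AUC-invariant, asserted). AUC is the rank-sum (Mann–Whitney) statistic
with half credit for ties, computed as held-out test presences against the
model's own background sample; the conventional 75/25 split uses
`round(0.75·n)` training records from a seeded permutation. The
10th-percentile training-presence threshold (linear interpolation) is
computed and reported but not applied unless requested — masking is a
policy choice, not part of the model.

## Habitat overlay and classification

Min–max normalization `(x − min)/(max − min)` uses the raster's own
valid-cell extrema unless dataset-wide overrides are supplied; the host
raster is normalized with an explicit minimum of 0 ha (and optionally a
dataset-wide maximum) so tiles of a larger dataset normalize consistently.
A degenerate range (max = min) maps to all zeros with a warning. Overall
suitability is the equal-weight mean `S = (n(cs) + n(h))/2`; nodata in
either input propagates (oceans must not read as "unsuitable at 0").

The printed class bounds (≤ 0.15, 0.16–0.30, 0.31–0.60, ≥ 0.61) leave gaps
between rounded edges; the implementation closes them with half-open
intervals (−∞, 0.15], (0.15, 0.30], (0.30, 0.60], (0.60, 1], giving a
total, unambiguous partition. The same scheme classifies climatic and
overall suitability maps.

## Dispersal kernel

`D_max` (default 40.2 km, the recorded 25-mile flight capacity) is read as
the 3σ point of a normal displacement distribution: σ = D_max/3,
c1 = 1/(σ√2π) (the 1-D pdf height at the mean), c2 = 1/(2σ²). With
`paper_rounding` (default) c1 and c2 are rounded to the conventionally
printed 2 and 3 decimals (0.03, 0.003); the unrounded mode supports
sensitivity checks, and `unit_height` forces c1 = 1 for a pure decay
profile. Because the kernel is monotone decreasing, "the kernel of the
nearest source" equals the maximum over per-source kernels, so the
implementation evaluates `c1·exp(−c2·x²)` at the per-cell distance to the
nearest occurrence — order-independent and O(cells × sources). Distances
are haversine kilometres between cell centers and source points; σ is in
km, which fixes the units of x. The likelihood is bounded by c1, decays
monotonely with distance under uniform habitat, and at x = D_max retains
about 1.1% of its peak. One generation is the standard run; multi-
generation mode (off by default) reseeds cells whose likelihood reaches a
threshold and can only expand the front.

## Synthetic landscapes

The generator produces the inputs the pipeline assumes, with truth known:

* **Predictors** are sums of six low-frequency cosine surfaces with random
  frequencies (0.5–2.5 cycles per domain axis), amplitudes and phases,
  plus white noise (`noise_sd`, default 0.1), standardized and then scaled
  into °C (temperature-like layers, following the Bio1–Bio11 convention)
  or mm (precipitation-like). Collinear pairs are constructed as
  `z_j = r·z_i + √(1−r²)·e` with `e` empirically orthogonalized against
  `z_i`, so the realized Pearson correlation equals the target exactly.
* **Truth** is the logistic of an intercept plus linear–quadratic
  combination of the standardized predictors.
* **Presences** are distinct cell centers sampled with probability
  proportional to truth; **host availability** is a shifted, clipped,
  squared smooth field in hectares whose minimum is exactly 0; **climate
  scenarios** shift temperature layers additively and scale precipitation
  layers multiplicatively.

Identical scenarios (including the seed) are bit-identical.

Default study conditions: 100×100 cells of 0.05° (a ~550 km domain, so the
10-km thinning radius removes a realistic ~30–45% of records rather than
almost all of them), 12 predictors of which 8 informative and 4
high-collinearity duplicates (pair targets 0.88–0.95, as is typical of
bioclimatic summaries), 150 presences, and truth coefficients
(|η| sd ≈ 10, intercept −9.5) that carve a sharply bounded niche envelope
occupying roughly 5–8% of the landscape. Those conditions put the
generating process itself in the high-discrimination regime (the truth
surface separates presences from background at AUC ≈ 0.94–0.98), which is
the regime in which presence-background models of range-expanding
invasives are reported to operate; a fitted model then reaches held-out
AUC ≈ 0.92–0.97 and Spearman ρ ≈ 0.8–0.9 against the truth. A broad,
diffuse niche (prevalence ≳ 0.3) caps attainable AUC near 1 − prevalence/2
regardless of model quality, which is worth remembering when interpreting
published AUCs.

What the generator does **not** emulate: real bioclimatic covariance
structure (19 variables with block correlations), anisotropy and elevation
gradients, geocoding error and sampling bias in occurrence compilations
(presences here are unbiased given suitability), crop-map zero inflation
patterns, and any actual geography. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated
conditions, not performance on real data.

## Problem sizes and determinism

Test and acceptance runs use the default 100×100 grid, 150 presences and a
10,000-point background; a full fit takes a few seconds, the whole suite
well under a minute of model fitting. All stochastic steps (field phases,
presence sampling, background sampling, the 75/25 split) take explicit
seeds, and the file pipeline records them in a JSON manifest from which
any output can be regenerated bit-identically.

## Known limitations

* The fit is exact coordinate descent on a finite universe; very large
  backgrounds (≫10⁵) would need stochastic or clustered approximations.
* The AUC compares test presences against the training background, the
  common presence-only convention; it is not an absolute accuracy measure.
* Grids must be co-registered; only a trivial mismatch diagnosis is
  provided, not reprojection.
* The spread model is isotropic, barrier-free and single-kernel: no
  long-distance or human-mediated jumps, no wind advection, no temporal
  dynamics beyond the optional reseeding extension.
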