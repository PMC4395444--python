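# Methods

## Problem and model

`mycogeo` attributes a geographic origin to an environmental sample from
the presence/absence of its taxa. The model has two stages.

**Stage 1 — occurrence surfaces.** For each taxon j, the probability
p_j(t) that a sample at location t contains the taxon is estimated by
Nadaraya–Watson kernel smoothing of the binary observations Y_ij over a
grid 𝒯 of cell centers, with a Gaussian kernel on great-circle distance
(haversine, sphere radius 6371.0 km; no projection is ever applied). The
estimator is a convex combination of 0/1 observations, so every surface
value lies in [0, 1] by construction.

**Stage 2 — Bayes inversion.** A query profile is scored at every grid
cell by its Bernoulli log-likelihood under the fitted surfaces, assuming
taxa are independent given location (a naive-Bayes approximation). With a
flat prior over cells — the default; a per-cell log-prior can be supplied
— the posterior is the normalized likelihood. The point estimate is the
argmax cell (ties broken to the lowest cell index); the normalized
likelihood is the predictive pmf from which highest-density prediction
regions are cut.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `bandwidth_candidates` | 25 log-spaced, 10–3000 | km | GCV search grid per taxon, within-city to continental scales |
| `max_trace_ratio` | 0.5 | – | excludes near-interpolating smoothers from GCV selection |
| `clip_epsilon` | 0.03 | probability | floor/ceiling applied to surfaces inside the log-likelihood |
| `min_prevalence` | 1 | samples | taxa with fewer presences (or absences) get constant surfaces |
| grid `nx × ny` | 40 × 40 (CLI) | cells | granularity/cost trade-off of 𝒯 |
| levels | 0.5, 0.75, 0.9 | – | nominal coverage of prediction regions |
| `k` | 5 | folds | cross-validation protocol |

### Bandwidth selection and the degeneracy guard

GCV for a linear smoother penalizes the mean squared residual by
(1 − tr(W_ρ)/n)². As ρ → 0 the smoother approaches the identity, the
residual approaches zero, and the criterion becomes 0/0. With binary
responses this is not a removable nuisance: the numerator vanishes
*faster* than the penalty, so an unguarded minimization drifts to the
smallest bandwidth whose smoother is still technically invertible and
returns spike surfaces that memorize the training samples. The guard
therefore excludes candidates with tr(W_ρ)/n ≥ 0.5 — i.e. the fit must
keep at least half of its residual degrees of freedom. Empirically the
GCV curve has a well-defined interior minimum once the degenerate edge is
removed, and on synthetic single-bump taxa the selected bandwidth tracks
a dense-grid minimizer (tested). Ties are broken toward the larger
bandwidth: when scores are equal we prefer the smoother, lower-variance
surface.

The candidate grid bounds are deliberate: 10 km is below any cell size a
continental grid will use, 3000 km is effectively a constant surface, and
25 log-spaced points give ~26% spacing, finer than the GCV curve's
curvature warrants. Rare taxa (prevalence near 0 or n) fail the
`min_prevalence` filter and receive constant surfaces at their prevalence
fraction with a NaN bandwidth sentinel — they stay in the atlas so query
vectors never need re-indexing, and constant surfaces cancel out of the
argmax.

### Probability clipping

The product likelihood multiplies hundreds of per-taxon terms. An
unclipped surface value of 0 at a cell would veto that cell outright on
the strength of a single binary feature, and a tiny floor (say 1e−6)
still lets one taxon swing the field by ±13.8 nats. That is far more
evidence than a kernel estimate can carry: with n samples and bandwidth ρ
over a domain of area A, the effective local sample size behind a surface
value is roughly n_eff ≈ n·2πρ²/A — about 15 at the package's default
scales — so probabilities below ~1/(2·n_eff) ≈ 0.03 are not resolvable
from the data. The default ε = 0.03 caps each taxon's per-cell evidence
at ±3.5 nats, keeping improbable cells penalized but comparable.
Coverage calibration is insensitive to ε across [0.01, 0.05] (the
held-out threshold re-absorbs the scale); the clip mainly protects the
point estimate from overconfident spikes. For reference collections much
denser than the defaults a smaller ε is appropriate; it is exposed in
`FitConfig`.

### Regions, thresholds, coverage

`prediction_region(pmf, q)` accumulates cells in descending pmf order
until the cumulative mass first reaches q, then includes every cell tied
with the last value (stable ordering, ties to the lower cell index), so
the region is order-independent and slightly conservative; q = 0 gives
the empty set and zero-mass cells are never included. Because a discrete
pmf cannot hit Σf = q exactly, this smallest-exceeding set is the
standard HDR convention.

`calibrate_threshold` searches q on a 0.01-step grid refined to 0.001
around the solution; coverage is monotone non-decreasing in q, so this
equals an exhaustive 0.001-grid scan (tested against one). A sample
counts as covered when the grid cell nearest its true origin (great-circle
distance, ties to the lower index) lies in the region. Internally the
scan uses each sample's minimal covering mass — the cumulative pmf of
cells ranked strictly above its true cell — which is provably the same
membership test as rebuilding the region at every q.

The cross-validation protocol is nested: per fold, the atlas is fit on
an 80% subtraining split of the training data (floor rule on sizes),
thresholds are calibrated on the remaining 20%, and the *same*
subtraining atlas predicts the held-out test fold. Thresholds are
per-fold; nothing is pooled across folds except the final records. All
randomness flows from one master seed via independent per-fold seed
sequences.

## The synthetic generator

`make_world` draws m ground-truth occurrence fields over a lat/lon
bounding box (default 24–50°N, 125–67°W, a conventional continental-U.S.
extent): a fraction `endemic_fraction` (default 0.7) are Gaussian bumps
with centers uniform over the domain, range σ log-uniform in 100–600 km,
peak uniform in 0.3–0.9 and baseline uniform in 0–0.05; the rest are
spatially constant ("cosmopolitan") at a level drawn from the peak range.
An optional two-bump variant produces non-convex high-probability
regions, and sampling locations can be clustered around random "cities"
to reproduce sampling-intensity effects. Samples are independent
Bernoulli draws from the fields.

This reproduces the statistical shape that makes geolocation possible —
a mix of informative endemics and uninformative cosmopolitans, heavily
right-skewed taxon prevalence — and supplies an oracle: the same Bayes
inversion run on the *true* fields, a performance ceiling for any fitted
atlas. It does **not** emulate sequencing depth, detection error,
taxon co-occurrence, habitat covariates, or anisotropic ranges; passing
tests demonstrate the statistical machinery is correct and calibrated
under the model's own assumptions, not that any particular real survey
will achieve a given accuracy.

## Numerical choices

- Kernel weights that all underflow to zero (possible at extreme
  bandwidth/distance mismatches) fall back to a point mass on the nearest
  source and set a flag; inside GCV the self-weight exp(0) = 1 prevents
  this on the diagonal.
- The predictive pmf is computed as a max-subtracted softmax of the
  log-likelihood field; it is shift-invariant and never overflows.
- Surfaces are stored per taxon as dense length-N arrays; atlas
  persistence writes plain-text arrays with `%.17g`, which round-trips
  float64 bit-exactly (tested by comparing pmfs before and after).
- Quantiles use numpy's default inclusive linear interpolation.
- Grid cells are represented by their centers, ordered south→north then
  west→east; mask boundaries count as inside (shapely `covers`).
- Fitting is vectorized across taxa: W_ρ depends only on the sample
  layout, so each candidate bandwidth scores all taxa with one matrix
  product, and surfaces are computed grouped by selected bandwidth. Any
  execution order gives identical results.

## Problem sizes used in the shipped experiments

The calibration experiment (`scripts/acceptance.py` and the end-to-end
test) uses 10 replicate worlds with m = 300 taxa, n = 400 samples, a
40×40 grid and 5-fold CV — large enough that pooled coverage has
Monte-Carlo error ≈ 0.008–0.016 at the three levels, and the whole run
completes in seconds. Parameter-recovery checks use m = 40 taxa at
n ∈ {100, 400, 1600}. These sizes are the package's test defaults, not
limits; fitting scales as O(n²·candidates + N·n·m) time and O(max(n², N·n))
memory.

## Known limitations

- Taxa are treated as independent given location; correlated detection
  (shared habitat, sequencing batch) makes the likelihood overconfident.
  The calibrated regions absorb this on average but the point estimate
  does not.
- Prediction is restricted to grid cells; there is no off-grid
  refinement of ŝ, so error is floored near half a cell diagonal.
- The constant-surface fallback for rare taxa discards whatever weak
  signal singletons carry.
- Coverage is calibrated marginally (over samples), not conditionally:
  under-sampled regions can be under-covered while dense regions are
  over-covered, exactly as the stratified summaries expose.
- A uniform prior over *cells* is uniform over area only if cells have
  equal area; on a lat/lon grid spanning wide latitude ranges, northern
  cells are smaller — negligible at the default extent, but a per-cell
  log-prior can correct it.
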