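# Methods

This note documents the statistical model implemented in `cnm`, its
assumptions, the default parameters and why they were chosen, what the
synthetic data generator does and does not emulate, the numerical choices in
the solver, and known limitations.

## 1. Model

### 1.1 Penalized maximum entropy (MaxEnt)

Given `m` presence records and `N` background cells with feature vectors
`f(x) ∈ R^K`, the model is the Gibbs distribution over background cells

    q_λ(x) = exp(λ·f(x)) / Z_λ,

with `λ` minimizing the convex objective

    L(λ) = −(1/m) Σ_i λ·f(x_i) + log Z_λ + Σ_j β_j |λ_j|.

This is simultaneously (a) the maximum-entropy distribution subject to
relaxed moment constraints `|mean_presence f_j − E_q[f_j]| ≤ β_j` and (b) an
L1-penalized exponential-family MLE. The optimality (KKT) conditions are

    |mean_presence f_j − E_q[f_j]| ≤ β_j, with signed equality when λ_j ≠ 0.

The package tests this certificate directly after every fit.

**Features.** Continuous variables are min–max scaled to [0, 1] using the
background range. Feature classes: linear, quadratic, pairwise products, and
hinge features `max(0, (x − k)/(max − k))` with knots on an even grid (10 per
variable by default). With fewer than 80 presences only linear + quadratic
features are used — the standard sample-size heuristic that limits model
complexity when data are scarce. Constant features are dropped.

**Regularization.** `β_j = r · c_class · s_j / √m`, where `s_j` is the
feature's background standard deviation, `c_class` is a feature-class
constant (1.0; hinge 0.5), `m` the number of presences and `r` a global
multiplier (default 1.0). The `1/√m` scaling makes the penalty act like a
confidence-interval width on the presence means; a floor of 1e−6 keeps the
problem strictly regularized.

**Output scale.** Raw outputs sum to 1 over the background. The logistic
transform `p = e^H q r /(1 + e^H q r)` with `H` the entropy of `q` maps them
to [0, 1] such that a cell with typical presence-level suitability scores
about 0.5; an intercept-only model yields exactly 0.5 everywhere. Habitat
classes: unsuitable `p < 0.1`, moderate `0.1 ≤ p ≤ 0.5`, high `p > 0.5`.

### 1.2 Ensemble and evaluation

Each of `n_runs` (default 100) replicates draws a bootstrap training sample
(75 % of presences, with replacement); the out-of-bag records form the test
set. All replicates share one background sample (default 10 000 cells without
replacement; training presences are appended to the fitting background, the
standard presence-augmented background). Test AUC is the rank-based
Mann–Whitney statistic: the probability a random presence outranks a random
background point, with tie correction. The ensemble prediction is the
cellwise mean of converged replicates; non-converged fits are excluded and
logged.

Variable importance: (i) permutation contribution — drop in training AUC when
one variable's values are shuffled, normalized to sum to 100 %; (ii)
MaxEnt-style jackknife — training gain of the model with only / without each
variable versus the full model.

### 1.3 Occurrence processing

Records with unparsable or out-of-range coordinates are dropped and counted.
Records falling in urbanized cells can be removed (irrigation and horticulture
make urban presences unreliable climate signals). Spatial thinning treats two
records as duplicates when their circular buffers overlap — great-circle
(haversine, R = 6371 km) distance < 2 × radius (default radius 2.5 km) — and
keeps exactly one record per connected component of the overlap graph, chosen
by an RNG seeded from the sorted member ids so the result is independent of
row order.

### 1.4 Variable selection

Pairwise Spearman rank correlations are computed at the (retained) occurrence
points. Variables are pruned iteratively: retain the variable with the most
strong correlations (|ρ| > 0.60, ties alphabetical), drop its neighbours,
repeat. The retained set is an independent set of the threshold graph — no
retained pair is strongly correlated.

### 1.5 Scenario analysis, MESS, change test

The ensemble is projected onto each scenario's climate stack. MESS
(multivariate environmental similarity) scores each cell against the
reference climate (each replicate's training presences plus the shared
background): with `f` = percentage of reference values strictly below the
cell's value, the similarity is `(p−min)/range·100` if `f = 0`, `2f` if
`f ≤ 50`, `2(100−f)` if `50 < f < 100`, and `(max−p)/range·100` if
`f = 100`; a cell's MESS is the minimum over variables. Negative values mark
climates outside the reference range. Per-replicate MESS grids are averaged;
a cell is flagged novel when the mean is negative, and the percentage of
suitable (moderate + high) cells that are novel is reported.

The change test regresses future on current probability, `P_f = β0 + β1
P_c`, at `n` random jointly valid cells (default 10 000) and t-tests
β0 = 0 and β1 = 1 (identity line; df = n − 2, F(1, n−2) for overall fit).
A perfect linear fit makes the residual variance zero; the standard errors
are then undefined and the report flags `degenerate_se` instead of testing.

## 2. Synthetic data: what it does and does not emulate

`synthetic_data.make_world` builds a study system with a known answer:

- **Climate layers** — Gaussian-smoothed (σ = 5 cells, truncation 3σ,
  reflecting boundaries) standardized random fields, optionally mixed with a
  shared field to induce realistic cross-correlations between layers.
- **True niche** — logistic in the layers:
  `S(x) = 1/(1+exp(−(a + Σ b_v z_v(x))))`. The default
  (a = −9, b = +5 on `temp_range`, −4 on `prec_season`) makes a
  climate-limited specialist: suitable prevalence around 7–10 % of the
  landscape and an attainable presence–background AUC near 0.95, the regime
  in which MaxEnt niche models are typically applied to invasive species.
- **Occurrences** — cells drawn with probability proportional to `S`, with
  within-cell jitter; sampling is spatially unbiased.
- **Scenarios** — three future periods × four forcing levels built by adding
  fixed multiples of each layer's standard deviation (0.15–1.5 sd), a delta
  ladder monotone in forcing.
- **Zones and urban mask** — Voronoi partitions and random town disks for
  zonal summaries and occurrence filtering.

It does **not** emulate: observation/sampling bias (roadside clustering,
detection effort), spatial autocorrelation of occurrences beyond what the
smooth suitability surface induces, temporal dynamics or dispersal limits,
GCM structure (deltas are spatially uniform shifts, real GCM anomalies are
patterned), coastlines/elevation, or label noise in species identification.
Quantities that depend on those properties (e.g. realized spread rates) are
outside what this generator can validate.

## 3. Numerical choices

- **Solver** — monotone FISTA (accelerated proximal gradient) with
  backtracking line search and soft-thresholding for the L1 term. Stopping
  rule: maximum KKT violation ≤ `tol` (default 1e−5), cap `max_iter = 1500`.
  Non-converged fits are flagged, never silently used. The objective is
  convex, so the KKT certificate is a proof of (near-)optimality independent
  of the optimization path.
- **Overflow control** — `log Z` and Gibbs weights are computed with the
  max-subtraction (log-sum-exp) trick; the L1 term treats `β·|λ| = 0`
  whenever `λ = 0`, so infinite penalties denote frozen-at-zero features.
- **AUC** — computed from ranks (`scipy.stats.rankdata`, average ties), which
  is O(n log n) and exactly equals brute-force all-pairs counting.
- **MESS** — per-variable sorted reference + binary search (`searchsorted`,
  left side: ties count as "not below", i.e. percentiles use strict
  less-than), validated against a naive per-cell double loop.
- **Determinism** — every random draw derives from a master seed via
  SHA-256 of `"{seed}|{stage}|{index}"` reduced mod 2³¹, so stage seeds are
  stable across platforms and independent of execution order; pipeline
  reruns are byte-identical.
- **Rasters** — ESRI ASCII is written with shortest exact `repr` per value
  so text round-trips preserve float64 bit patterns; GeoTIFF I/O uses
  `tifffile` with GeoTIFF tags (pixel scale, tiepoint, nodata). Geographic
  coordinates only (WGS84 degrees); no reprojection is provided.

## 4. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| thinning radius | 2.5 km | one record per ~5 km climate neighbourhood; removes duplicate herbarium/GPS records |
| correlation threshold | 0.60 | conventional collinearity cut for Spearman \|ρ\| in niche modelling |
| feature auto-switch | 80 presences | standard MaxEnt sample-size heuristic |
| hinge knots | 10 | smooth response curves without exploding K |
| regularization multiplier | 1.0 | the standard default; raise for smoother models |
| ensemble runs | 100 | stable cellwise means and AUC standard errors |
| train fraction | 0.75 | bootstrap size; OOB set ≈ 25 % for testing |
| background size | 10 000 | standard MaxEnt background sample |
| class thresholds | 0.1 / 0.5 | conventional logistic-output cut points |
| change-test n | 10 000 | t-tests well into the asymptotic regime |
| solver tol / max_iter | 1e−5 / 1500 | KKT certificate well below the 1e−4 acceptance tolerance; cap bounds runtime |

## 5. Limitations

- Presence-background AUC is bounded below 1 even for a perfect model (its
  ceiling depends on species prevalence); it is comparable across runs on the
  same system, not across species or regions.
- The logistic output assumes a typical presence corresponds to p ≈ 0.5; it
  is a calibration convention, not a probability of occurrence.
- L1 selection among strongly correlated features is unstable by nature; the
  correlation pruning step mitigates but does not remove this, and per-run
  selected features may differ across bootstrap replicates. If the pruning
  step drops a variable that actually drives the niche in favour of a
  correlated proxy, ensemble discrimination degrades (observable on
  synthetic worlds where the truth is known).
- The change test's OLS assumes homoskedastic residuals; probabilities near
  0/1 violate this, so its p-values are descriptive, not exact.
- No multiple-testing correction is applied across the 12 scenario
  regressions.
- Climate-only model: no dispersal, biotic interactions, land use, or soil;
  projections are potential climatic habitat, not predicted occupancy.
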