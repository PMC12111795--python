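# Methods

This note documents the models, the synthetic data they are exercised
on, and the numerical and design choices a maintainer would want to know
about. Notation follows the README.

## Synthetic storage experiments

The generator emulates a constant-temperature/constant-humidity storage
trial: grain conditioned to a set of moisture contents is held at a set
of temperatures (chamber relative humidity pinned to the grain's
equilibrium value, tabulated for the 4 × 4 default grid, so moisture
stays constant), sampled every 30 days, with replicate measurements of
germination rate, fatty acid value and bulk density. The default design
is 4 moistures × 4 temperatures × 7 time nodes × 5 replicates = 560
records in long format.

Degradation follows deliberately simple closed forms so oracle tests can
evaluate trajectories directly:

* shared environment multiplier `r(T, M) = exp(α_T (T − 15) + α_M (M − 12.5))`
  with defaults `α_T = 0.12 /°C`, `α_M = 0.8 /%` — degradation
  accelerates exponentially with temperature and moisture;
* germination `g(t) = g₀ e^{−k_g r t}` clipped to [0, 100] (`g₀ = 98 %`,
  `k_g = 2.6·10⁻⁴ /day` at the mildest condition);
* fatty acid `f(t) = f₀ + k_f r t` (`f₀ = 8 mg KOH/100 g`, `k_f = 0.011`);
* bulk density `d(t) = d₀ − k_d r t` (`d₀ = 812 g/L`, `k_d = 0.012`).

Defaults were chosen once so that 180 days at the mildest condition
degrades quality barely (germination ≈ 93 %) and the harshest condition
substantially (germination ≈ 38 %, fatty acid ≈ 48), spanning the range
a grading system must resolve. Replicate noise is Gaussian per indicator
(sd 1.5 %, 0.8 mg/100 g, 2 g/L); missingness blanks exactly
`round(rate × cells)` uniformly chosen indicator cells (default rate
1.2 %).

What the generator does *not* emulate: mold/pest outbreaks, sudden
environment excursions, heteroscedastic or drifting measurement error,
assay-specific biases, and cross-indicator noise correlation. Passing
tests therefore demonstrate correctness of the machinery and sensible
behaviour on smooth monotone kinetics, not performance on real
warehouse data.

### Preprocessing

* **Standardization** — z-score with the *population* sd (divide by n),
  or a [0, 1] range transform; parameters stored for exact inversion.
* **Imputation** — each missing cell is the equal-weight average of a
  temporal estimate (linear interpolation, edge-slope extrapolation,
  along its own condition/replicate series) and a condition-space
  estimate (least-squares plane in temperature × moisture over same-time,
  same-replicate peers; mean fallback below 3 peers; temporal-only when
  no peer exists).
* **Outlier screen** — per (condition, time) replicate group, a record is
  removed when any indicator satisfies `|x − mean| / sd ≥ z` (population
  sd, default z = 3). Groups with < 2 replicates are skipped with a
  warning. The screen is a single pass; re-running can flag further
  records because group statistics change.

## Forecaster

Architecture as in the README. Choices that were genuinely open:

* **Loss and protocol** — MSE on standardized values; Adam, lr 1e-4,
  batch 32, 20 epochs, 3 GCN layers (the standard protocol adopted
  throughout); chronological 70/15/15 split over time-ordered windows,
  never shuffled across the boundary; correlation edges fitted only on
  records visible to training windows.
* **Adjacency** — fixed training-split correlations; signed weights are
  kept (germination vs fatty acid couple negatively) while degrees use
  absolute values so normalization stays well defined; zero-variance
  series (constant environment in a single-condition panel) get zero
  edges rather than aborting. An optional learnable additive adjacency
  refinement exists behind `learn_adjacency` and is off by default.
* **Gate input** — elementwise addition `H + S`; a concatenation variant
  sits behind `gate_concat` since both conventions appear in the wild.
* **Gate initialization** — gate weights and bias start at zero, so
  Γ = 0.5 exactly and the fused model begins as the ungated branch mean,
  learning deviations from it (the usual neutral start for gating
  modules; a randomly initialized gate begins life as a noise source).
* **Association node** — exactly one, pooled from the temperature and
  moisture tokens by per-variable single-layer attention plus
  attention-weighted mean; it joins the graph with unit edges to every
  variable node and its output row is dropped before fusion.
* **Head** — shared per-variable linear map D → horizon, mirroring the
  shared embedding so the model is permutation-equivariant in the
  variables.
* **Engine** — a ~300-line tape-based reverse-mode autodiff core over
  numpy (`graincast.autodiff`); at this model scale (N ≈ 6 tokens,
  D = 32) it trains the full benchmark in seconds on one CPU, and its
  gradients are finite-difference-checked in the test suite.
* Germination is clipped to [0, 100] only when reporting in original
  units, never inside the loss.

## Grader

* **Weights as feature scalings** — the decay weight multiplies row τ of
  `G_t` before flattening (it indexes time steps *within* the window),
  not the sample weights of the clustering objective. λ = 0 reproduces
  plain k-means on the unweighted window; λ → ∞ reduces the feature to
  the anchor row. Default λ = 0.5; P and F default to lookback − 1 and
  the forecast horizon.
* **Seeding** — first center: the point nearest the global mean (a
  deterministic, central anchor); each next center: the point with the
  greatest minimum distance to the chosen ones; the seed only breaks
  exact ties. With this seeding the whole fit is deterministic in the
  data.
* **Lloyd loop** — convergence at max center shift < 1e-6 or 300
  iterations; empty clusters are repaired by reseeding with the point
  farthest from its center (k must stay fixed — it is the number of
  grades); nearest-center ties go to the lower cluster index; the
  within-cluster sum of squares is recorded every iteration and asserted
  non-increasing.
* **Choosing k** — majority vote of silhouette-max, Davies–Bouldin-min
  and Dunn-max over the candidate range, silhouette breaking ties. On
  real degradation panels quality varies along a continuum, so small k
  often wins; the planted-structure benchmarks use separable Gaussian
  mixtures where the vote must recover the true count.
* **Grades** — clusters are ordered by descending mean germination at
  the anchor (grade 0 = best) and summarized by min/max of each
  indicator over members' anchor observations in original units, plus a
  member count per grade.

## Metrics

MSE, RMSE, MAE as printed everywhere; MAPE excludes zero-truth terms
(count logged) instead of epsilon-padding; SMAPE uses the 200 %/n
convention with 0/0 terms contributing 0; MSPE is defined here as the
mean squared relative error — conventions for it vary, so reports flag
it as implementation-defined. Validity indices use Euclidean distance
(the k-means-compatible choice); silhouette assigns 0 to
singleton-cluster points; all-singleton clusterings return Dunn = +∞
with a warning, and coincident centroids return Davies–Bouldin = +∞
with a warning rather than crashing.

## Benchmark problem sizes

The forecaster benchmark uses a noise-free 8 × 8 condition grid sampled
every 3 days over 180 days (3 904 records, ≈ 3.5 k windows): dense
enough that 20 epochs at lr 1e-4 supply on the order of 1.5 k optimizer
steps, which is what the fixed protocol needs to converge; medians are
taken over 5 seeds. Planted-structure benchmarks use 6-dimensional
Gaussian mixtures with centers ≥ 12 noise-sd apart (separable by
construction), 30 points per component, candidate k ∈ [2, 10]. The
end-to-end pipeline benchmark runs the full 560-record design.

## Known limitations

* The kinetics are smooth and monotone; model skill on them is an upper
  bound on skill for noisy, regime-switching real storage data.
* The forecaster extrapolates beyond the last observed time node when
  the grader asks for forecasts at late anchors; on synthetic kinetics
  this is benign, on real data it inherits the usual extrapolation risk.
* MAPE/MSPE on standardized values are unstable near zero-mean crossings
  and are reported for completeness, not recommended for model
  selection.
* The grade count is data-driven via the validity vote; it is not forced
  to any particular number of levels.
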