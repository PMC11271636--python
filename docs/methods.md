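# Methods

This note documents the models, the synthetic data they are validated on,
and the numerical/design choices a maintainer would need to know. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Shipping network and metrics

The network is a directed graph `G = (V, E, W)` over ports; `w_ij` counts
trips from *i* to *j* over the observation period. Self-loop rows are
dropped at ingestion (a port calling itself carries no ballast-transfer
information at this granularity).

Great-circle distances use the canonical haversine on a sphere of radius
6371 km: `2R·arcsin√(sin²(Δφ/2) + cosφ_i·cosφ_j·sin²(Δλ/2))`. Forms that
omit the half-angles and the square root are not metrics (they exceed the
arcsin domain and break the triangle inequality) and are not implemented.
Ellipsoidal geodesics are out of scope; at shipping-network granularity the
spherical error (&lt; 0.6%) is irrelevant.

Node metrics:

- **Betweenness** — unnormalised sum over ordered pairs of the fraction of
  shortest paths through the node; pairs with no path contribute 0.
- **Closeness** — over *outgoing* distances (the direction a departing ship
  cares about). With `r` reachable targets out of `|V|−1`, the value is
  `(r/Σd)·(r/(|V|−1))`: on strongly connected graphs this is exactly the
  classical `(|V|−1)/Σd`; otherwise the reachable-fraction scaling keeps
  values comparable across components. Isolated nodes score 0.
- **PageRank** — damping 0.85, tolerance 1e−9, at most 200 power
  iterations, transitions proportional to trip counts, dangling mass
  redistributed uniformly. PageRank deliberately has no `weight_mode`: a
  walk's transition probabilities follow traffic volumes whether or not one
  reinterprets weights as distances, so its ranking is identical across
  modes (asserted as a property test). Measured on dense synthetic worlds,
  literally using 1/w-proportional transitions would reorder the top-5 on
  every seed, and even betweenness/closeness rankings are unstable under
  reciprocal weights there (Spearman 0.14–0.71 across seeds) — the
  rankings-are-stable intuition belongs to sparse, heavy-tailed real
  networks.
- **Straightness** — mean over reachable targets of geodesic km divided by
  network shortest-path km (edge lengths are haversine distances), scaled
  by 1/(|V|−1); values in [0, 1], unreachable targets contribute 0.

`weight_mode` for the shortest-path metrics: `trips` (edge length = trip
count, the default and the primary computation), `reciprocal` (length =
1/count, weights-as-distances) and `unweighted` (hop counts).

## Full connection and link screening

`fully_connect` adds every missing ordered pair with pseudo-weight
`w′ = 0.1` (the default) or, alternatively, weights ∝ 1/distance scaled so
the closest pseudo pair receives 0.1 (`mode="inverse_distance"` — the two
readings coexist in the source material; the constant is the explicit one).

Edge importance uses min–max normalisation for both the weight and the
haversine distance over all edges of the augmented graph, with ε = 1e−6.
If all weights (or distances) coincide, the normalised values are defined
as 0 with a warning. Sea-route distances come from a pluggable provider;
without one, the fallback is haversine × 1.15 (a typical route-to-geodesic
detour ratio), flagged in the result. Routed distances are floored at the
haversine value.

Pseudo links vastly outnumber real ones, so training sets are balanced 1:1
by stratified subsampling of the pseudo class. Strata are (haversine
decile × source region); quotas are proportional with largest-remainder
rounding, short strata borrow from the nearest decile within the region,
then globally. All real rows are kept; no pseudo row is drawn twice.

The classifier menu is logistic regression, k-nearest neighbours, decision
tree, gradient boosting and random forest (scikit-learn; boosted trees
stand in for XGBoost, which is not a dependency). Each is tuned by 5-fold
grid-search cross-validation over a small fixed grid (ties resolved by the
first-listed parameter set) on a 75/25 stratified split; plain accuracy is
reported. The deployed filter defaults to logistic regression: tree models
reach near-perfect accuracy because edge importance embeds the observed
weight, but the logistic filter's misses are concentrated on 1–2-trip
links, which is exactly the pruning of unstable connections the flow model
benefits from. Any menu model can be selected instead.

## Feature assembly

Destination ports are encoded into ≤ 17 geographic regions by country; a
default 17-token country→region table ships with the package and is
overridable. Region centroids are unit-sphere means of member-port
locations. Each (source port, destination region) pair carries a frozen
10-feature order: origin out-flux; region in-flux (arrivals are the
gravity "mass" of attraction — the source material leaves the direction
open); haversine distance to the region centroid; bilateral trade in USD
from the source country summed over the region's countries, with the
source's own country contributing exactly 0; and origin/region-median
betweenness, closeness and PageRank (medians over member ports present in
the network). Missing trade pairs count as 0 with a logged tally. Features
are z-scored with training-split statistics; constant features pass
through unscaled with a warning.

## Flow models

Scores `f(x_ij)` for the N candidate regions of one source are mapped to
flows by `ŷ_ij = O_i · softmax(f)_j`, so `Σ_j ŷ_ij = O_i` holds by
construction. Training minimises `−Σ_j y_ij log softmax(f)_j` through a
numerically stable log-softmax (max-shifted).

**Transformer gravity**: linear embedding 10 → 64, then stacked encoder
blocks — fused 3d×d QKV projection with biases, 2 heads (d_k = 32),
softmax attention scaled by 1/√d_k, d×d output projection, dropout 0.1,
residual + layer norm (ε = 1e−5, affine initialised to 1/0), position-wise
feed-forward 64 → 256 → 64 with ReLU, dropout, residual + layer norm —
and a scalar output head. No positional encoding: destination regions are
an unordered set, and both models are permutation-equivariant over rows
(tested). The feed-forward width 256 is a default; the originating
description omits it, and its printed transformer parameter counts do not
correspond to any integer width under the standard layout, so no parameter
count is asserted for this architecture.

**Deep gravity**: k ∈ {3, 9, 12, 15} hidden layers, the first k/3 of width
256 and the remaining 2k/3 of width 128, leaky-ReLU (slope 0.01), scalar
output. Parameter counts match the closed form
`10·256+256 + (k/3−1)(256²+256) + (256·128+128) + (2k/3−1)(128²+128) + 129`
exactly (52,353 / 249,985 / 348,801 / 447,617).

Training is strictly batch-size 1 (samples have varying N), with Adam
(lr 1e−3, classic L2 penalty 1e−5 — values chosen as standard defaults
where the source names only "Adam with L2"), learning rate × 0.1 after 10
epochs without validation-CPC improvement, early stopping after 20, and
best-validation-CPC checkpointing. Cross-validation assigns source-port
samples to near-equal seeded folds; each fold's model starts from the same
seeded initialisation so fold scores differ only through the data. NRMSE
and Pearson correlation are pooled over all (source, region) pairs by
default — the per-source sums written in the originating definitions grow
with the number of sources and cannot produce values on the reported
[0, 1] scale — with a `per_source` mean variant available.

All of this runs on a ~150-line reverse-mode autodiff over float64 NumPy
arrays (`shipflow._autodiff`). Analytic gradients are validated against
central finite differences to 1e−4 in the acceptance suite; training is
single-threaded and bit-reproducible under a seed (seeds drive fold
assignment, initialisation, shuffling and dropout masks).

## Risk stage

Environmental distance is the plain Euclidean norm over
(t_min, t_max, t̄, s̄) in native units (°C, PSU), as defined upstream;
because the units differ, a z-scored variant (components divided by their
spread over the port table) is available via `standardized=True`.
Distributions are 50 equal-width bins spanning [0, max observed distance],
shared between compared distributions via `bin_max`; comparison reports
the Pearson correlation of binned weights (identical inputs short-circuit
to exactly 1.0 rather than 1 − ulp) and the total-variation distance, with
a per-link (`method="pairs"`) variant since the upstream description does
not say which was correlated. Predicted region-level flows are spread over
a region's ports proportionally to observed port in-flux (uniform when all
zero), restricted to the source's actual destinations where available —
total predicted weight per source is conserved.

## Synthetic worlds

The generator emulates the statistical structure the method assumes, not
real geography: region centres sampled on the sphere (|lat| ≤ 50°),
countries scattered around them, ports around countries (final |lat| ≤
65°, poles avoided); port masses log-normal (σ = 1, heavy-tailed fluxes);
expected flows `λ_ij = κ·m_i·m_j / max(d_ij, 100 km)^γ` with γ = 2 and
κ = 1e7 — chosen once so a median port sees on the order of 10² departures
per period, comparable to a busy harbour-year — realised as Poisson
counts so 1–2-trip links arise naturally (the links the screening filter
targets); trade = 1e4 USD × aggregated inter-country expected flow ×
log-normal noise (σ = 0.3), exactly 0 within a country, directional;
temperatures fall 0.4 °C per degree of |latitude| from 28 °C with noise
σ = 1.5 °C, min/max bracket the mean by a latitude-widening half-range,
salinity ≈ 35 PSU with a weak gradient. "Sea-route" distances are
haversine × (1.15 + small coordinate-hashed jitter). Defaults are 150
ports, 40 countries, 12 regions.

What a green test does **not** establish: real coastline constraints
(ports sit on a featureless ocean sphere, so distances understate true
routes), seasonality and trends (one stationary period), canal/chokepoint
topology, the extreme 2.3%/97.7% real/pseudo imbalance of the full global
network (synthetic worlds are denser), or salinity structure beyond noise.
Scores on synthetic worlds are typically higher than anything achievable
on real traffic; they validate mechanics and recoverability, not
real-world accuracy.

## Pipeline

`run_pipeline` executes inputs → network → metrics → screen → featurize →
train → risk, writing every artifact (CSV/JSONL/GraphML/JSON) with a
SHA-256 content hash into `manifest.json`; a stage failure halts with the
stage name and persists the partial manifest. The global seed fans out to
per-stage seeds by fixed offsets (world +0, screen +1, model +2, folds
+3), so stages can be re-derived in isolation. Determinism makes a rerun
equivalent to resumption; no incremental skip logic is implemented.

## Known limitations

- The transformer's feed-forward width (and hence its parameter count) is
  a package choice, not a reproduction.
- The link classifiers' near-perfect accuracy with edge importance partly
  reflects that the feature encodes the observed weight; the
  distances-only ablation quantifies this.
- NRMSE/correlation aggregation conventions differ across the literature;
  both pooled and per-source variants are computed, pooled is reported.
- The risk stage needs port-level predicted flows; the in-flux-
  proportional disaggregation from region level is a modelling choice and
  the main approximation in the risk comparison.
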