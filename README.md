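# shipflow

Gravity-informed forecasting of maritime origin–destination traffic, with a
ballast-water invasion-risk stage.

Global shipping moves non-indigenous species between harbours in ballast
water: a tank filled in one port and discharged in another transplants whole
communities of organisms. Anticipating *where ships will go* is therefore a
biosecurity question as much as a logistics one. `shipflow` implements a
complete pipeline for that problem, exercised end-to-end on seeded synthetic
shipping worlds (real global AIS-derived port-visit data is proprietary):

1. **Network construction** — a directed graph over ports with edge weights
   `w_ij = Σ_t T_ij(t)`, the number of trips observed from port *i* to *j*,
   plus betweenness, closeness, PageRank and straightness centralities.
2. **Link screening** — the network is fully connected with pseudo-edges of
   weight 0.1; classifiers trained on great-circle distance, sea-route
   distance and the *edge importance* `I_ij = ŵ_ij / (d̂_ij + ε)`
   (min–max-normalised flow over normalised distance) decide which
   origin–destination pairs are plausible.
3. **Flow allocation** — for each source port *i* with total outflow `O_i`
   and candidate destination regions `j = 1..N` (N ≤ 17), a model scores a
   10-feature vector per region (fluxes, distance to the region centroid,
   bilateral trade, centralities) and allocates

   `ŷ_ij = O_i · softmax(f(x_ij))_j`,

   trained with the cross-entropy `L = −Σ_j y_ij · log softmax(f(x_i))_j`.
   Two architectures are provided: **transformer gravity** (64-d embedding,
   stacked 2-head self-attention encoder blocks, no positional encoding —
   destinations are an unordered set) and the **deep gravity** MLP baseline
   (k hidden layers, widths 256→128 in a 1:2 ratio).
4. **Evaluation** — the Common Part of Commuters
   `CPC = 2 Σ_j min(ŷ_j, y_j) / (Σ_j ŷ_j + Σ_j y_j)` averaged over source
   ports, plus NRMSE and Pearson correlation, with 5-fold cross-validation.
5. **Risk assessment** — per-port environmental vectors
   `ν_i = ⟨t_min, t_max, t̄, s̄⟩` give a link the environmental distance
   `d_ij(env) = ‖ν_i − ν_j‖₂`; weighting by trips yields a distribution of
   shipping activity over invasion-risk levels, compared between observed
   and predicted flows.

The models are implemented in NumPy with a small in-repo reverse-mode
autodiff (`shipflow._autodiff`), so no deep-learning framework is required;
gradients are verified against finite differences in the test suite.

## Worked example

```bash
python examples/03_flow_forecasting.py
```

builds an 80-port synthetic gravity world, trains both models and prints:

```
80 source-port samples, up to 10 candidate regions each
transformer gravity (3 layers): validation CPC 0.864 (150,721 parameters, stopped epoch 29)
deep gravity (15 layers): validation CPC 0.850 (447,617 parameters, stopped epoch 29)
uniform allocation baseline: CPC 0.290
```

A CPC of 0.864 means that 86% of the predicted flow mass coincides with the
observed allocation of departures over destination regions — far above the
no-information uniform split, with the attention model matching the much
larger MLP. The other examples cover network metrics (`01`), link screening
(`02`, including the accuracy gap when the edge-importance feature is
removed), risk distributions (`04`) and the one-call pipeline (`05`), which
writes every artifact with a content hash into a manifest and is
bit-reproducible under its seed.

There is no command-line interface; the importable API plus these scripts
are the intended surface. `shipflow.run_pipeline(PipelineConfig(...))`
orchestrates all stages from a single YAML-serialisable configuration.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — generates a seeded
synthetic world, builds the network and metrics, screens links, trains the
transformer gravity model with cross-validation and evaluates the
ballast-water risk stage — printing the headline metrics and writing the
results file.
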