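# Methods

This note records the model, its assumptions, the defaults that matter, and
the design decisions taken where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

One measurement is a tuple *(d₁, d₂, r₁, r₂, c) → s*: two drugs (identified
by SMILES), their two assay concentrations (positive reals, assay units), a
cell line (identified by an expression vector), and a real-valued response.
The response scale is dataset-defined — percent growth in NCI-60-style
screens, Bliss-based synergy scores elsewhere — and the models treat it as
an opaque regression target; no internal rescaling is applied (an optional,
explicit preprocessing step is the place for dataset-level standardization).
Drug pairs are treated as **unordered**: (A, B) and (B, A) with swapped
doses denote the same physical experiment, so retrieval matches on the
canonical sorted pair (doses travel with their drug) and the global trainer
augments each sample with its swapped copy by default.

## Global model

- **Drug encoder** — character-level tokenization (vocabulary built from the
  training library; PAD and UNK reserved), embedding (PAD row pinned to
  zero), stacked same-padded 1-D convolutions with ReLU, max-pooling masked
  to the real token span (so trailing padding cannot affect the output), and
  a linear projection. Defaults: char dim 16, two conv layers (32 and 64
  filters, kernel 5), embedding dim 64, max length 128. One encoder is
  shared by both drugs.
- **Dose embedder** — fixed (non-learnable) sinusoidal features over
  log-spaced frequencies. Defaults: c = 16 frequencies on [0.1, 50], output
  dim 2c = 32. Raw concentrations are first mapped into [0, 1] by
  **log-min-max**: d' = (log r − log r_min)/(log r_max − log r_min) with the
  range fitted on the training doses (values outside are clipped). Embedding
  raw micromolar values would alias every frequency above ~1/|dose range|;
  with the transform, the slowest wave spans the range once and the fastest
  resolves ~1% dose differences. The `raw` mode returns the 1-D transformed
  dose itself — the "no dose embedding" ablation. Dose embeddings are not
  passed through further learnable layers.
- **Cell encoder** — exactly three affine layers with ReLU (final
  activation configurable), default widths 128 → 64 → 32. Expression length
  is data-driven (78 in the common highest-variance-gene convention).
- **Head** — MLP on the concatenation [drug1, drug2, dose1, dose2, cell],
  default hidden widths (128, 64), scalar output. Encoders and head are
  trained **jointly** end-to-end (the only reading consistent with a single
  MSE objective over the composed network).
- **Training** — Adam at learning rate 1e-3 (defaults constrained to the
  grid [1e-5, 1e-1]), batch 256, epoch cap 300, early stopping on a 10%
  random slice of the training data with patience 20, best-epoch weights
  restored. Pair-swap augmentation on by default. All initialization and
  shuffling flows from one `numpy` generator seeded by the config, so
  training logs are bit-reproducible.

## Local model

- **Retrieval.** Exact match on the canonical (pair, cell) key, excluding
  samples at exactly the query's dose pair. `k_min = 2` neighbors are
  required for the graph path: the two regimes described for the method are
  "more than one" and "fewer than one" retrieved sample, leaving k = 1
  undefined; a one-neighbor graph gives a semi-supervised learner nothing to
  work with, so k = 1 falls through to the fallbacks.
- **Fallback 1 (Bliss).** If monotherapy curves for both drugs exist in the
  query's cell line, the pseudo-surface g₁(r₁)·g₂(r₂) over the outer product
  of the two dose grids supplies pseudo-labeled neighbors. Multiplication
  requires growth fractions in [0, 1]; percent-growth inputs are divided by
  100 and clipped (clipping logged). Pseudo-samples enter the graph as
  labeled nodes; predictions made from them are mapped back to the data
  scale. The alternative reading — pseudo-curves guiding retrieval only —
  is available by composing the primitives directly.
- **Fallback 2 (feature similarity).** The K = 20 nearest training samples
  by cosine distance in joint-feature space (K configurable to {20, 50,
  100}), ties broken toward the lower training index.
- **Graph.** k retrieved nodes + the query (last). Node features are the
  frozen trained encoders' joint features — the encoders are reused, not
  retrained, which keeps per-query training cheap and deterministic. Each
  node selects its 4 nearest neighbors by Euclidean distance in
  (log r₁, log r₂) — log space matches the log-spaced grids of screening
  designs — with union symmetrization and a unit diagonal; knn is capped at
  n−1, so no node is ever isolated.
- **GCN.** Propagation H ← ReLU(Â H W + b) with Â = D^(−1/2) A D^(−1/2),
  two layers of width 32 by default, then a linear scalar read-out per node.
  One network is trained **per query** (the graph differs per query; nothing
  is amortized across queries), 200 epochs of Adam at 1e-3 (grid
  [1e-6, 1e-2]), loss on labeled nodes only. Labels are standardized per
  graph (trained on (t − μ)/σ of the labeled nodes, predictions mapped
  back), so the zero-initialized output starts at the labeled mean — this
  is what makes constant surfaces exactly recoverable and stabilizes
  interpolation generally. Many queries are trained in one vectorized
  batch when their graphs share a shape; per-element results are identical
  to training each query alone.
- **"Local without GCN" ablation** — identical retrieval, features and
  budget, but a per-node MLP (the graph coupling Â removed), trained on the
  labeled nodes and applied to the query. This follows the plain reading of
  an MLP applied to the retrieved dose-response samples.

## Aggregation

A small MLP (hidden (16, 16)) on [global, local, availability flag,
log(1+k)]; the two extra inputs let a single network modulate its trust in
the local path (they can be disabled with `extra_inputs: false`). Modes
`fixed-average` and `global-only` cover the ablations. **Contract:** for
every mode, a query without a local prediction returns the global
prediction bit-exactly — the fusion network is never consulted. The
aggregator is fitted on out-of-fold pairs: each training fold is split
90/10, the global model trains on the 90%, and the aggregator trains on
(global, local, truth) triples from the 10% — in-fold targets would let it
learn from overfit global predictions.

## Synthetic screens

The generator emulates a combination screen's structure, not its biology:

- **Monotherapy**: Hill curves g(r) = 1/(1 + (r/EC50)^h), EC50 log-uniform
  over the dose range (default grid: 5 log-spaced doses on [0.01, 1], the
  full 5×5 matrix design), slope uniform on [0.5, 3]. Responses are clipped
  to [0, 1] after noise.
- **Combination surfaces**: Bliss null g₁·g₂ plus a Gaussian bump
  A·exp(−(‖log r − μ‖²)/(2w²)) in log-dose space, A uniform on [−0.3, 0.3]
  (negative = antagonism), width 0.5–1.5 log-units, center on a grid point;
  plus i.i.d. Gaussian noise, default σ = 0.05 on the growth-fraction scale.
- **Expression**: per-cell latent factors (q = 4) times a random loading
  matrix plus noise (σ = 0.1), length 78 by default. The same factors shift
  each drug's log₁₀ EC50 (0.3 decades per latent unit), so expression is
  genuinely informative about sensitivity.
- **SMILES**: an embedded list of small valid molecules, extended by carbon
  chain growth; validity is asserted against a cheminformatics toolkit in
  the test suite.

What passing tests on these screens show — and what they do not: the
surfaces are smooth, the null is exactly Bliss, noise is homoscedastic
Gaussian, expression covariance is unstructured, and every pair×cell has a
complete matrix. Real screens violate all of these (plate effects,
heteroscedastic counts, missing wells, correlated expression), so results
here validate the machinery and its relative ordering of model variants,
not absolute performance on any real dataset.

## Evaluation

- **S1 (matrix completion)**: each matrix's 25 cells are partitioned across
  the 5 folds (20% per fold), monotherapy retained. Partitioning (rather
  than independent random draws) is what makes 5-fold CV well defined.
- **S2 / S3 (new combinations)**: whole drug pairs are partitioned across
  folds; S2 keeps monotherapy (enabling the Bliss fallback), S3 removes it
  (leaving feature-similarity retrieval only).
- **Transfer splits**: new-combo (pair×cell matrices), new-drug (train
  contains no sample touching a held-out drug), new-cell (whole cell lines).
- Monotherapy rows feed only the Bliss fallback by default; the global
  model's five-input interface takes combination rows only.
- Metric: Pearson correlation (guarded against constant inputs), averaged
  over folds. Every source of randomness fans out from one master seed into
  named sub-seeds (data, split, global, local, aggregator, inner) recorded
  in the report; a rerun with the same master seed reproduces the report
  exactly.

## Problem sizes and defaults used in the standard benchmark

`presets.synthetic_benchmark_config`: 12 drugs × 6 cell lines × 5×5 grids
(9 900 combination rows), σ = 0.05, S1 split with one of the five folds
evaluated, five seeds. The encoder widths in this preset (drug embedding
16, cell embedding 8, c = 8 dose frequencies, GCN hidden 16, 150 epochs per
query graph) are deliberately leaner than the package defaults: a 12-drug
synthetic screen supports — and needs — far less capacity than a production
screen, and the lean preset keeps a five-seed run in the minutes range on
one CPU.

## Numerical choices and degenerate inputs

- All arithmetic is float64 numpy; the autodiff core implements exactly the
  ops the models need, with gradients unit-tested against finite
  differences.
- k-NN ties break toward the lower node index (stable argsort); dose-match
  exclusion uses a 1e-9 relative tolerance.
- A single-dose training set degenerates the log-min-max fit; the range is
  widened to one decade.
- Retrieval with an empty result, graphs below `k_min`, and aggregator
  training without any available local prediction all resolve to typed
  "unavailable" outcomes that degenerate to the global model, never to
  exceptions.
- Non-finite training losses abort with a diagnostic rather than
  propagating NaNs.

## Known limitations

- Per-query GCN training makes batch prediction O(queries); the vectorized
  batch trainer mitigates but does not remove this.
- The feature-similarity fallback retrieves samples of *other* pairs; their
  labels are only as transferable as the joint feature space is faithful.
- The generator's Bliss-plus-bump surfaces cannot represent dose-dependent
  antagonism-to-synergy reversals along a single axis.
- SMILES handling is character-level; no canonicalization or chemistry-aware
  augmentation is attempted.
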