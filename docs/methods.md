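# Methods

## Problem setting

Acute-toxicity data across species form a multi-task tabular regression
problem: each *toxicity endpoint* — a (species, administration route,
toxicity type) triple such as "mouse / oral / LD50" — is one task
Dᵢ = (Xᵢ, yᵢ) with its own compounds, a continuous toxicity label, and a
sample size anywhere from tens to tens of thousands of rows. Features are
high-dimensional, sparse molecular fingerprints (1024-bit Avalon/Morgan,
1024-bin AtomPair counts). The goal is to maximize the unweighted mean test
performance P_avg = (1/T) Σᵢ Pᵢ over all T endpoints, which forces a
trade-off between large tasks (plenty of signal on their own) and small
tasks (which only improve through knowledge borrowed from related tasks).

## The cascade-forest regressor

The base learner is a cascade forest: an adaptive stack of layers, each an
ensemble of U forest units (default 2 random forests + 2 extremely
randomized trees, 100 trees per unit, sklearn estimators with their default
tree parameters). Layer 1 trains on the raw d features. Each layer's
per-unit prediction vector (length U) is concatenated to the **original**
feature block as the next layer's input, so layers after the first see
d + U columns.

Two details are deliberate choices where the general recipe leaves room:

* **Out-of-fold augmentation during training.** The augmentation passed to
  the next layer is built from k-fold (default k=3) out-of-fold
  predictions, the deep-forest convention; feeding in-sample predictions
  forward would let the stack memorize the training labels. At prediction
  time the stored units — refit on the full layer input — produce the
  augmentation instead.
* **Internal-CV-gated depth.** A layer's score is the R² of the
  unit-averaged OOF prediction against the training labels. A candidate
  layer is retained only if it beats the best retained score by more than
  `growth_tolerance` (1e-4); otherwise it is discarded and growth stops.
  `max_layers` (20) is a hard guard. For a constant target the R² ratio is
  undefined; a perfect OOF fit scores 1 and anything else −∞, so such
  degenerate fits stop at depth 1. With the `neg_mse` metric the score is
  the negative OOF mean squared error.

The final prediction is the arithmetic mean of the last layer's U unit
outputs. Feature importance is the mean of the final layer's per-unit
impurity importances, truncated to the first d columns (augmentation
columns dropped) and renormalized to sum to 1; if all mass sits on
augmentation columns the truncated vector degenerates to uniform.

## Knowledge transfer

Three mechanisms wrap the base learner into a multi-task framework:

1. **Data aggregation.** The train+valid rows of all endpoints are pooled
   (a multiset over measurements — compounds appearing in several endpoints
   stay as separate rows) and a cascade is fitted on the pool. Its first
   layer, refit on the full pool, is the *source model*: U forest units
   operating on raw width-d features.
2. **Feature enhancement by layer transfer.** Every sample of every
   endpoint — train, valid *and* test, since the downstream models consume
   d+U columns — is widened by the source model's U-dimensional prediction
   vector. Rows that trained the source receive the layer-1 *out-of-fold*
   predictions by default (`source_oof=True`): forest in-sample predictions
   track the training labels closely, so in-sample enhancement smuggles
   near-memorized labels into the training rows while test rows get honest
   predictions — downstream cascades then over-trust the enhancement
   columns and test generalization degrades, and spurious neighbor
   acceptance follows for the same reason. The in-sample variant
   (`source_oof=False`) mirrors the enhancement equation most literally and
   remains available. Test rows always receive direct predictions.
3. **Greedy sample transfer guided by covariance distance.** Each
   endpoint's feature block is summarized by its sample covariance matrix
   CM(X) (denominator n−1; the full d×d matrix including the variance
   diagonal — the distance's mean runs over all d² entries, a declared
   convention since rank orders are insensitive to dropping the diagonal).
   The task distance is mean|CM(Xₐ) − CM(X_b)|, computed on **raw**
   train+valid features so similarity reflects the chemistry rather than
   source-model outputs. For endpoint i, candidate neighbors are visited in
   ascending distance (ties by ascending endpoint id). Starting from a
   baseline cascade on the endpoint's own enhanced train rows, each step
   refits on the pool plus the candidate's train+valid rows and is accepted
   only if R² on the endpoint's **own validation rows** strictly improves
   (ties reject). The search halts at the first rejection (`patience`
   raises the number of consecutive rejections tolerated). Finally the
   model is retrained on the accepted pool plus the endpoint's own
   validation rows; test rows never enter any pool, and a leakage audit
   verifies this on every fit.

Endpoints with fewer than `min_valid_rows` (5) validation rows skip the
greedy stage — a validation score on a handful of rows is too noisy to gate
data acquisition — and keep the baseline.

Greedy scoring uses mean(y_valid) as the R² reference so step scores are
comparable across steps; final evaluation uses the endpoint's own
train+valid label mean as the reference (the training-mean convention for
ȳ). `evaluate` reports per-endpoint R²/RMSE on test rows and their
unweighted means.

## Determinism

One top-level seed fans out through `derive_seed(seed, *tokens)` (a blake2b
hash of the token path, < 2³¹): the source model, each endpoint's greedy
step s, the final refit, fold assignments and every forest unit all receive
distinct derived seeds. Re-running any fit with the same data and seed is
bit-reproducible, including the greedy acceptance sequence.

## Evaluation harness

`repeated_cv` reproduces the repeated k-fold protocol (default 10×5): per
run, each endpoint's rows are partitioned into k folds under a run-specific
derived seed; each fold serves once as test while the remainder is re-split
3:1 into train:valid, reconstructing the 60/20/20 geometry inside the fold.
How the original 60/20/20 narrative composes with k-fold reporting is
under-determined; the 3:1 re-split is this package's declared convention.
Endpoints smaller than k are skipped with a warning.

## Multi-view modeling and interpretation

A `ViewSet` aligns several feature representations of the same compounds
(identical endpoints, labels, splits). Two strategies are implemented:
feature concatenation (one wide collection, d = Σ dᵥ) and the consensus
ensemble — an unweighted mean of independently trained per-view framework
predictions (no weights: averaging is the declared combiner). For
association analysis, endpoints are pooled by species (`species_merge`),
one framework model is fitted per species-endpoint, and the raw-feature
importance vectors are compared by pairwise Euclidean distance; truncation
to the raw feature space keeps vectors commensurable across endpoints whose
cascades grew to different depths.

## Synthetic data: what it emulates and what it does not

`generate_collection` draws fingerprint-like multi-task collections: tasks
are assigned round-robin to `n_clusters` clusters; each cluster has a
column-activation profile π_c concentrated on a cluster-specific block of
columns (in-block Bernoulli rates ~ U(0.5, 1.5)·p·K, floor rate 0.02
elsewhere, so the overall 1-bit density stays near `feature_sparsity` p and
covariance distance can separate clusters) and a sparse coefficient vector
β_c supported on ~8 in-block columns. Task t in cluster c draws
X ~ Bernoulli(π_c) and y = X·(ρ·β_c + (1−ρ)·β_t)/s + N(0, σ²), where s
scales the noiseless signal to unit standard deviation so σ is a
noise-to-signal level. The cluster structure deliberately lives in **both**
the feature distribution (detectable by covariance distance) and the
response (so accepted neighbors genuinely help) — the premise the sample
transfer mechanism relies on.

Defaults: ρ = 0.9 (strongly related tasks), p = 0.2, σ = 0.3 (attainable
R² ≈ 0.9), task sizes of a few hundred rows with one small task where a
test calls for it. The generator does not emulate real chemistry: no
SMILES, no hashed-bit collision structure, no heavy-tailed label
distributions, and cluster membership is exactly block-structured. Passing
tests therefore demonstrate the mechanics and direction of the transfer
effects, not performance levels on real fingerprint data.

## Problem sizes used in tests and the acceptance script

Cascade behaviour is exercised at n = 500, d = 20 (growth law) and smaller;
framework-level experiments use T = 2–6 endpoints of 50–200 rows,
d = 30–50, with reduced cascades (15–20 trees per unit, depth ≤ 2,
3-fold CV) — small enough that a full multi-seed comparison runs on one
CPU in minutes while preserving every structural property of the full-size
configuration. These sizes are the package's own desk-scale choices; the
defaults (100 trees, depth ≤ 20) remain the production configuration.

## Known limitations

* The greedy search is strictly sequential per endpoint; a parallel
  implementation must reproduce the serial acceptance sequence under the
  same seeds.
* Covariance distance only sees second moments of the feature columns;
  related tasks with dissimilar feature distributions are invisible to it
  (task clustering over samples is an acknowledged alternative, out of
  scope here).
* Enhancement uses the source model's plain outputs; richer augmentation
  vectors (e.g. Shapley-based) are out of scope.
* `r_squared` raises on zero-variance references rather than returning a
  sentinel; callers with constant validation labels must handle this.
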