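# Methods

## The classification model

scassign annotates single cells by running one **binary linear
classifier per cell type** (one-vs-rest) and organising those
classifiers in a **parent/child forest**. Each classifier bundles five
pieces of information: the cell-type name, the trained linear model, the
ordered gene (feature) list it consumes, a probability threshold, and an
optional parent type.

For a cell with standardized feature vector *z* the decision value is

    f(z) = w · z + b

fitted as a soft-margin linear SVM (hinge loss, L2 penalty,
regularization strength 1/C). The decision value is mapped to a
calibrated probability with Platt's sigmoid

    p(f) = 1 / (1 + exp(A·f + B))

where (A, B) minimize the negative log likelihood of the training
decision values against Platt's smoothed targets
t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2). A cell is *accepted* by a
classifier when p ≥ threshold (default 0.5; adjustable later without
retraining, because only the comparison changes).

Hierarchical application: root classifiers score every cell; a child
classifier scores only cells accepted by its parent. Per cell, the
final candidate set keeps the deepest accepted type along each path (an
accepted subtype replaces its accepted lineage label). No candidate at
all yields **"unknown"** — this is the rejection option that keeps
populations absent from the reference from being forced into a label.
Multiple candidates from different branches yield an ambiguous,
slash-joined assignment; `best_guess` picks the candidate with the
highest probability (lexicographic tie-break).

## Training pipeline

For each cell type, in parents-first order:

1. **Lineage restriction** (children only): keep cells whose *label*
   belongs to the parent lineage. Labels, not the parent model's
   predictions, define the restriction, so a child's fit is reproducible
   and independent of parent quality.
2. **Normalization** (raw counts only): scale each cell to 10,000 total
   counts, then log1p. Zeros stay zeros, so sparsity is preserved.
3. **Feature extraction**: densify only the requested gene columns.
   Genes absent from the matrix become zero columns with a warning.
4. **Constant-feature drop**: features with zero variance on the
   training cells are dropped (z-scoring is undefined for them), with a
   warning.
5. **Standardization**: per-feature z-scoring; the means and standard
   deviations are stored in the model and re-applied at prediction time.
6. **Class balancing**: the one-vs-rest negative class usually dwarfs
   the positive class, so by default the majority class is randomly
   downsampled (seeded) to the minority size before fitting.
7. **SVM fit** on the balanced subset (libsvm via scikit-learn,
   tol 1e-6 — the default 1e-3 leaves the solution visibly short of the
   QP optimum on small problems).
8. **Calibration** on the decision values of *all* lineage-restricted
   training cells, not only the balanced subset. The majority-class
   cells unseen by the margin fit anchor the sigmoid where the classes
   actually mix; calibrating on the balanced subset alone produced
   systematically optimistic probabilities for borderline negatives and
   noticeably worse rejection of held-out populations.

A type's positive class includes its descendants' labels (a plasma cell
is also a B cell), so parent models learn the whole lineage.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `cost_c` | 1.0 | SVM soft-margin cost C (regularization 1/C) |
| `balance` | `downsample` | seeded majority-class downsampling before the fit |
| `min_cells_per_class` | 10 | refuse to train below this per-class count |
| `threshold` | 0.5 | per-classifier acceptance probability |
| `scale_total` | 10⁴ | library-size normalization target |

Only the linear kernel is supported: in this regime (marker panels of
tens of genes, hundreds of training cells) linear decision functions
are the appropriate model class, and the config field reserves room for
future kernels.

### Feature sets

Classifiers consume explicit gene lists. The bundled helper for
simulated data (`training_hierarchy`) gives every classifier the
**union of all reference types' marker lists**. A one-vs-rest model
benefits from negative evidence — strong expression of another type's
markers argues against the type at hand — and per-type own-marker
panels roughly doubled the per-classifier error rate in the reference
scenario. Per-type panels remain available (`shared_panel=False`), and
users supply whatever lists they like through the API and CLI.

## Evaluation

* **Accuracy** is computed over all cells. A cell whose true type is in
  the reference is correct under *strict* scoring iff the assignment is
  exactly that single type; under *intermediate-accepted* scoring an
  ambiguous set containing the truth, or a single ancestor of the truth,
  also counts. A cell whose true type is absent from the reference is
  correct — in both variants — iff it was rejected as "unknown". A flag
  excludes out-of-reference cells from the denominator instead.
* **Sensitivity** of type t: the same correctness rule restricted to
  cells with truth t. **Specificity** of type t: fraction of non-t
  cells whose assignment set does not assert t (an ambiguous call naming
  t still asserts t). Means are unweighted across reference types
  present in the truth.
* **Unknown-population detection rate**: among cells whose truth is not
  in the reference, the fraction assigned "unknown"; undefined (None)
  when no such cells exist.
* **ROC / threshold tuning**: curves are computed over the unique
  predicted probabilities with the acceptance rule p ≥ threshold, area
  by trapezoid; `tune_threshold` supports the Youden point (max
  tpr − fpr, ties to the lowest threshold) and a target-sensitivity
  objective (largest threshold still reaching the target).

## The synthetic-data generator

`simulate_dataset` draws counts from a negative binomial with mean
s_c · μ₀ · F and variance μ + μ²/r, where μ₀ = 0.5 is the baseline
mean, r = 2 the dispersion, s_c a per-cell log-normal library factor
(σ = 0.3, mean 1), and F the planted fold change (default 4) when the
gene is a marker of the cell's type *or of an ancestor* — descendants
inherit ancestor markers, so a parent classifier has signal covering
all its children. Sibling marker sets must be disjoint. Everything is
determined by a single seed.

The reference scenario (`default_spec`) has three well-separated root
populations, one subtype of the first (with its own 30 markers on top
of the inherited ones), and one additional root population that is
simulated but held out of training — ground truth for the rejection
metrics. 500 cells per type, 30 markers per type, 1,000 genes.

What the generator does *not* emulate: batch effects, doublets,
ambient RNA, dropout beyond the NB's own zeros, and correlated gene
modules. Passing tests therefore demonstrate that the machinery is
correct and well calibrated under a clean overdispersed-count model,
not that any particular real tissue will reach the same accuracy.

## Reference benchmark and problem sizes

`scassign.pipeline.run_benchmark` is the canonical end-to-end run:
simulate the reference scenario, split cells 50/50 stratified by label,
train on one half, classify the other, and score both variants. All
randomness derives from one seed (simulation seed, split seed + 1,
balancing seed + 2). At the defaults this yields strict accuracy
≈ 0.95–0.97 and unknown-detection ≈ 0.93–0.98 depending on seed, and
accuracy degrades sharply as the planted fold change drops through
4 → 2 → 1.3 — the synthetic analogue of discrete versus closely related
populations. The difficulty sweep uses five seeds per fold change; the
sparse-contract check classifies a 50,000-cell, 500-gene matrix with a
database trained on a separate 150-cell-per-type draw.

## Numerical choices and degenerate inputs

* Platt calibration runs Newton's method with a backtracking line
  search and a 1e-12 Hessian ridge; the oracle cross-check (coarse grid
  plus simplex refinement) agrees to 1e-4.
* Probabilities are clipped to the open interval (0, 1) at float
  resolution, so downstream log-odds never see exactly 0 or 1.
* Threshold comparison is ≥: a probability exactly at threshold passes.
* Ambiguous assignment strings are lexicographically sorted and joined
  with "/"; names containing "/" are rejected when added to a database.
* Not-evaluated child probabilities are NaN in memory and "NA" in the
  predictions CSV — deliberately distinct from a low probability.
* All-zero cells make normalization fail loudly (they cannot be
  scaled); all-constant feature panels fail training.
* `remove_classifier` re-roots orphaned children onto the removed
  node's parent — the least destructive default; subtree deletion is
  repeated leaf removal.
* Database archives (`.ctdb`) are zip files with a JSON manifest and
  one `.npy` member per numeric array, so floats round-trip
  bit-exactly while names, parents and thresholds stay inspectable
  with standard tools.

## Known limitations

* Only linear kernels; no hyperparameter search — C is taken as given.
* Gene matching is exact string equality; no alias resolution.
* One classifier per type means probabilities are calibrated per type,
  not jointly; probabilities across types need not sum to one.
* The strict/accepted scoring dichotomy treats any ambiguous set as
  wrong under strict scoring even when it contains the truth.
* Training restricts child classifiers by labels; datasets whose labels
  disagree with the parent classifier's behaviour will propagate that
  disagreement to the child's training set.
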