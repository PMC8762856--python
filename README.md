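# scassign

Hierarchical, probability-calibrated cell-type classification for
single-cell RNA-seq — with a rejection option for populations missing
from the reference.

## The problem

Annotating cell types is a central step in scRNA-seq analysis. Most
automatic classifiers are good at assigning the types they were trained
on, but many fail in two practical ways: they force a label onto cells
whose true type is *absent* from the reference, and they densify the
expression matrix and fall over on large datasets. scassign addresses
both, for analysts who want reusable, shareable classifiers rather than
a reference dataset bolted to every run.

## The model

One binary linear SVM per cell type (one-vs-rest), with decision values
mapped to probabilities by Platt scaling:

    f(z) = w · z + b          p(f) = 1 / (1 + exp(A·f + B))

Classifiers carry five pieces of information — cell type, model,
feature (gene) list, probability threshold, parent — and live in a
**classifier database** whose parent links form a forest. Root
classifiers score every cell; a child (say, plasma cells under B cells)
scores only cells its parent accepted. Per cell, the deepest accepted
type on each branch survives; several surviving branches give an
ambiguous call ("A/B"), and no surviving classifier gives **"unknown"**.
Thresholds can be changed at any time without retraining. Prediction
densifies only each classifier's feature columns, never the full
cells × genes matrix.

A seeded negative-binomial simulator with planted hierarchical marker
structure (and a held-out population for rejection tests) makes the
whole framework testable offline; see `docs/methods.md` for the model
and its limits.

## Worked example

```python
import scassign as sa

# simulate the reference scenario: 3 root types, 1 subtype, 1 type
# held out of training, 500 cells each, 30 markers per type
spec = sa.default_spec(seed=1)
matrix, labels = sa.simulate_dataset(spec)
(train_m, train_y), (test_m, test_y) = sa.split_train_test(matrix, labels, 0.5, seed=2)

hierarchy, features = sa.training_hierarchy(spec)   # {'TypeA_sub': 'TypeA', ...}
db = sa.train_database(train_m, train_y, hierarchy, features,
                       sa.TrainingConfig(seed=3))
sa.save_database(db, "models.ctdb")

preds = sa.classify_cells(db, test_m)
report = sa.score_predictions(test_y, preds, set(db.entries), hierarchy,
                              variant="strict")
print(f"strict accuracy     {report.accuracy:.3f}")
print(f"mean sensitivity    {report.mean_sensitivity:.3f}")
print(f"unknown detection   {report.unknown_detection_rate:.3f}")
```

Output:

```
strict accuracy     0.954
mean sensitivity    0.960
unknown detection   0.932
```

95% of held-out cells get their exact planted label; 93% of the cells
whose type was never trained are correctly left "unknown" instead of
being forced into a label. `preds.probabilities` holds the per-type
probability for every cell (NaN where a parent's gate was closed), and
`preds.assignment` the final call, e.g. `TypeA_sub`, `TypeB/TypeC`, or
`unknown`.

The same pipeline is available from the shell:

```sh
scassign simulate --seed 1 --out data/
scassign train --input data/ --labels data/labels.csv \
         --hierarchy hierarchy.json --out models.ctdb
scassign classify --input data/ --db models.ctdb --out predictions.csv \
         --threshold "TypeA=0.3"
scassign evaluate --predictions predictions.csv --truth data/labels.csv \
         --db models.ctdb --out-dir metrics/
scassign db list models.ctdb
```

Expression input is a 10x-style MTX directory (`matrix.mtx`,
`features.tsv`, `barcodes.tsv`, gzipped variants accepted) or a
CSV/TSV, either orientation. Raw counts are library-size normalized to
10,000 and log1p-transformed; pass `--no-normalize` for pre-normalized
input.

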