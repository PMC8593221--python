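# siamcell

Few-shot Siamese metric learning for single-cell RNA-seq: learn a cell–cell
distance from raw counts and use it to transfer cell-type annotations across
platforms, batches and species, and to flag cell types missing from the
reference.

## The problem

Annotating scRNA-seq data usually means clustering and manual marker
inspection, repeated for every new dataset. Classifier-based transfer needs
many labeled cells per type — rarely available for rare types or transient
states. siamcell instead learns a *distance*: a twin network trained on as
few as 30 cells per type maps expression vectors into a low-dimensional
embedding in which Euclidean distance reflects whether two cells are the
same type. Because the metric, not a fixed label set, is what is learned,
new reference types can be added without retraining, and queries that match
nothing in the reference can be detected.

## The model

Two identical fully connected subnetworks share one weight set *W* (default
input → 512 → 512 → 32, rectified-linear hidden units, dropout 0.5 after
each hidden layer during training). Each cell's counts are scaled by the
cell's maximum count, so inputs lie in [0, 1] and are library-size
invariant. For a pair (X₁, X₂) the distance layer computes

    D_W(X₁, X₂) = ‖f(X₁) − f(X₂)‖₂

and training minimizes the contrastive loss (Y = 1 for a same-type pair,
margin m = 1):

    L(Y, D_W) = Y · ½ D_W² + (1 − Y) · ½ max(0, m − D_W)²

with RMSprop, checkpointing every epoch and keeping the epoch with the best
validation *Siamese accuracy* (fraction of pairs where D_W < 0.5 agrees
with Y = 1).

At inference a query cell is compared to 20 reference cells per type; the
type with the smallest mean distance is assigned. A query is flagged
**novel** when its best match does not stand out: with per-type mean
distances c₁…c_k, best c_min and remaining values R,

    z = (mean(R) − c_min) / sd(R),    novel ⇔ z < 2.

k-NN label transfer (k = 3) and k-NN graph construction over the embedding
are also provided, as is cross-species annotation: query genes are
translated through an ortholog map and genes without an ortholog are
zero-filled. The benchmark module contrasts the learned metric with
Euclidean/cosine distance on top-variable genes via the signal-to-noise
ratio between the two closest reference types, SNR = |μ₁−μ₂| / |σ₁+σ₂|.

## Worked example

Everything below runs on the built-in synthetic generator (negative-binomial
counts, type-specific marker programs, log-normal library sizes); no
download is needed. The `novel_type` scenario trains on six immune-like
types and queries with a seventh ("Endo") the model never saw:

```bash
$ siamcell simulate --scenario novel_type --outdir demo/sim --seed 7
scenario novel_type: train 360 cells x 300 genes (6 types), query 210 cells (7 types)
  truth novel_types = ['Endo']

$ siamcell train --counts demo/sim/train --labels demo/sim/train_labels.tsv \
    --outdir demo/run --seed 7 --epochs 50
trained 50 epochs on 6 types; best epoch 43 (val accuracy 0.974); bundle written to demo/run/bundle

$ siamcell annotate --bundle demo/run/bundle --counts demo/sim/query --out demo/annotation.tsv
annotated 210 cells -> demo/annotation.tsv
  Mono: 47
  B: 38
  DC: 33
  NK: 33
  RBC: 31
  T: 28
  flagged novel: 35
```

`val accuracy 0.974` is the best-epoch fraction of validation pairs whose
embedding distance falls on the correct side of 0.5. The annotation table
has one row per query cell with the assigned type, its mean distance,
the novelty z-score and the novel flag:

```
cell_id	assigned_type	mean_distance	novelty_z	novel
q0	B	0.1889947830256689	13.25399300850042	False
q1	B	0.03629447554104953	21.260115532599283	False
```

Every query cell receives the closest type label (the 30 "Endo" cells are
necessarily assigned *some* known label — here mostly Mono); the novelty
filter is what marks unmatched cells, and most of the 35 flagged cells are
the held-out type. `siamcell benchmark` writes the SNR comparison table,
and the same workflow is available as library functions
(`simulate_counts`, `sample_reference`, `make_pairs`, `train`,
`annotate_cells`, `knn_annotate`, `compare_metrics`, …).

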