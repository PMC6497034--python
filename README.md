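# umikit

Pipeline statistics for UMI-count single-cell RNA-seq data, built for
studies that profile heterogeneous blood cell populations (for example
umbilical cord blood) across multiple 10x libraries and need the bespoke
computations around the standard toolkits to be reproducible and tested:

- **Quality filtration** — the per-dataset *detected gene* definition (UMI
  ≥ 1 in ≥ 30 cells), removal of cells by detected-gene number and
  mitochondrial fraction, flagging of hemoglobin-high (nucleated red blood
  cell) clusters, and the stricter 2.5% mitochondrial cutoff applied to
  trajectory cells.
- **Batch-mixing evaluation** — the kNN *alignment score* of an embedding.
  With batches subsampled to equal size, x̄ the mean number of same-batch
  cells among each cell's k nearest neighbors, and N batches:

      score = 1 − (x̄ − k/N) / (k − k/N),  clamped to [0, 1]

  so fully segregated batches score 0 and perfectly mixed batches score 1.
  Includes a k-sweep and multi-embedding comparison on a shared subsample.
- **Marker detection and annotation** — cluster-vs-rest two-sided Wilcoxon
  rank-sum tests with Seurat-style gates (`min.pct = 0.25`, log-fold-change
  ≥ 0.25), exact under ties for small groups; doublet-cluster flagging by
  marker-set sharing with two larger clusters; Pearson-correlation
  annotation against bulk reference profiles.
- **Pseudotime statistics** — Spearman concordance of two orderings with a
  1,000-shuffle permutation null (empirical and Student-t p-values), and
  monotone-trend tests of per-cell quantities against pseudotime.
- **Signature-set statistics** — m-way Venn decomposition, a size-matched
  random-pool permutation test of the full intersection, and gene–gene
  Pearson co-expression modules by hierarchical clustering.
- **Synthetic cohorts** — a seeded generator of negative-binomial UMI
  counts over discrete cell types and batches, with a hemoglobin-high
  subpopulation, doublets, a maturation trajectory with gene waves and
  declining library size, and signature sets with planted shared cores —
  all with complete ground truth, so every statistic above can be validated
  against planted structure.

## Worked example

```python
from umikit import (SimConfig, generate_cohort, generate_embedding,
                    compare_methods, lognormalize, flag_hemoglobin_clusters)

cfg = SimConfig(n_batches=4, cells_per_batch=250, n_genes=600,
                n_cell_types=4, seed=1)
matrix, truth = generate_cohort(cfg)

corrected = generate_embedding(truth, batch_shift=0.0, seed=1)
uncorrected = generate_embedding(truth, batch_shift=5.0, seed=1)
print(compare_methods({"corrected": corrected, "uncorrected": uncorrected},
                      k=100, seed=1).to_string(index=False))

norm = lognormalize(matrix).to_frame()
print(flag_hemoglobin_clusters(norm, truth.cells["cell_type"],
                               truth.gene_sets["hb_genes"]))
```

prints

```
     method   score  x_bar   k  n_sampled_per_batch
  corrected 1.00000 24.990 100                  250
uncorrected 0.63388 52.459 100                  250
['HB_HIGH']
```

With no batch shift each cell's 100 nearest neighbors contain ~25
same-batch cells — exactly the k/N = 25 expected under random mixing of 4
equal batches — so the corrected embedding scores 1. The shifted embedding
averages 52 same-batch neighbors and scores 0.63. The hemoglobin screen
flags exactly the planted hemoglobin-high cluster.

Every step is also available from the shell:

```sh
umikit run-all --out run --seed 1        # full synthetic pipeline
umikit integrate-eval --embedding emb.tsv --k-sweep 100,500,1000 \
    --seed 1 --out scores.json
```

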