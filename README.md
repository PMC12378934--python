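# scin — contrastive integration of two single-cell omics modalities

Single-cell multi-omics assays measure the same biology through different
feature spaces: gene expression (scRNA-seq), chromatin accessibility
(scATAC-seq), surface proteins (ADT).  Integrating two such modalities means
mapping their cells into one shared latent space where the same cell — or at
least the same cell type — lands in the same place regardless of which
technology measured it.  `scin` does this with CLIP-style contrastive
learning, for both **paired** data (both modalities measured in the same
cells, e.g. SHARE-seq or CITE-seq) and **unpaired** data (disjoint cells
linked only by cell-type labels).

## The model

Two modality-specific encoders
`Linear(p → 256) → BatchNorm → ReLU → Linear(256 → 128)` map preprocessed
cells onto the unit sphere (row-wise L2 normalization).  A mini-batch takes
one cell per cell type from each modality; the M×M matrix of cosine
similarities S has matched (paired) or same-type (unpaired) positives on the
diagonal and different-type negatives elsewhere.  Per anchor *i*:

    L(i) = −½ ln[ exp(s_ii) / Σ_j exp(s_ij) ]  −  ½ ln[ exp(s_ii) / Σ_j exp(s_ji) ]

summed over anchors; up to 150 epochs of Adam with early stopping (patience
10, min delta 1e-4).  Preprocessing (total-count normalization → log1p →
scaling → PCA) is fitted on training cells only and applied frozen to
held-out cells, so evaluation is leakage-free by construction.  Integration
quality is scored by five metrics: Recall@k, cell type@k, cell-type
accuracy (1-NN), median rank, and normalized average silhouette width of the
joint embedding.  See `docs/methods.md` for the full account.

## Worked example

```python
from scin import (SCINModel, TrainConfig, PreprocessConfig, SplitSpec,
                  make_split, evaluate_embeddings)
from scin.synthetic import SyntheticSpec, generate_paired

spec = SyntheticSpec(n_cells=600, n_types=5, p=80, q=80, separation=6.0, seed=1)
dataset, _ = generate_paired(spec)
train_idx, test_idx = make_split(dataset.n_cells, SplitSpec(seed=1))
train, test = dataset.subset(train_idx), dataset.subset(test_idx)

model = SCINModel(train, preprocess=PreprocessConfig(
    normalize=False, log1p=False, scale=True, n_pcs=50))
results = model.fit(TrainConfig(seed=1))
print(results.summary())

emb1, emb2 = results.embed(test)
report = evaluate_embeddings(emb1, emb2)
print(f"cell type accuracy:     {report.cell_type_accuracy:.3f}")
print(f"Recall@10:              {report.recall_at_k[10]:.3f}")
print(f"normalized ASW:         {report.asw_normalized:.3f}")
print(f"normalized median rank: {report.median_rank_normalized:.4f}")
```

Output:

```
Contrastive integration results
===============================
mode:            paired
modalities:      mod1 / mod2
training cells:  420 / 420
latent dim:      128
epochs run:      105 (early stop)
initial loss:    5.315397
final loss:      3.818572
cell type accuracy:     0.983
Recall@10:              0.439
normalized ASW:         0.934
normalized median rank: 0.0722
```

Reading the numbers: 98.3% of held-out cells find a same-type cell as their
nearest cross-modal neighbor; 43.9% find their *exact* matched cell among
their 10 nearest of 180 candidates (chance would be 10/180 ≈ 5.6%);
normalized ASW 0.934 means the joint embedding clusters cleanly by cell
type; and the matched cell's typical distance rank is in the best 7% of all
candidates.

The same pipeline runs from the shell — `scin generate-synthetic`,
`scin simulate-unpaired`, `scin train`, `scin evaluate`,
`scin run-replicates` (the 10-split protocol), `scin plot-tsne` — on h5ad
inputs with a `cell_type` observation column.

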