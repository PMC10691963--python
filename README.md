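# schiclink

Imputation of single-cell Hi-C (scHi-C) contact maps by enclosing-subgraph
link prediction, with learned cell embeddings for clustering and downstream
3D-genome analyses (A/B compartments, TAD-boundary insulation scores).

## Who this is for

scHi-C measures genome folding one cell at a time, but each cell's contact
matrix is extremely sparse: most zeros are unobserved contacts, not absent
ones. Anyone analysing scHi-C — calling compartments or domain boundaries
per cell, or clustering cells by 3D structure — needs those missing contacts
imputed first. `schiclink` provides that imputation as a fit/results
workflow plus a CLI, together with a synthetic-data generator with planted
ground truth so every step can be validated without external downloads.

## Model

Each cell *i* is a graph `G_i` over genomic bins; an observed contact is an
edge. For a candidate pair `(u, v)` the model predicts

```
ŷ(i,u,v) = σ( ReLU( (C_i | h_u | h_v) W₁ + b₁ ) W₂ + b₂ )
```

where

* `C_i = W₂ᶜ max(0, W₁ᶜ B_i + b₁ᶜ) + b₂ᶜ` is the **cell embedding** (two-layer
  MLP on PCA-reduced flattened contact maps `B_i`);
* `h_u, h_v` are final node states of a **subgraph transformer** run on the
  k-hop enclosing subgraph of `(u, v)`: node states start as bin embedding +
  degree embedding, `h⁰ = x_bin + z_deg`, and each layer applies multi-head
  attention whose logits carry an additive bias derived from the subgraph
  adjacency `D`,

  ```
  E   = tanh( ReLU(D W₁ᵉ + b₁ᵉ) W₂ᵉ + b₂ᵉ )
  Aᵢⱼ = (hᵢ W_Q)(hⱼ W_K)ᵀ / √d_h + Eᵢⱼ
  ```

  followed by a residual FFN block (pre-LayerNorm throughout).

Training minimizes binary cross-entropy over observed edges (positives) and
distance-banded sampled non-edges (negatives) with Adam (lr 1e-3, β₁ 0.9,
β₂ 0.999, weight decay 1e-5); the subgraph encoder can optionally be
pretrained with graph contrastive learning whose augmentations spare the
candidate pair. The network is implemented in NumPy with hand-written
gradients (finite-difference-verified in the test suite), so there is no
deep-learning-framework dependency.

See `docs/methods.md` for the full method description and design choices.

## Worked example

```python
import schiclink as sk

# 40 synthetic cells, 2 planted types, one 150-bin chromosome, 3000 reads/cell
cfg = sk.two_type_config(n_cells=40, n_bins=150, reads_per_cell=3000, seed=0)
graphset, truth_maps = sk.simulate_graphset(cfg)

model = sk.ContactImputer(graphset)
result = model.fit(train_config=sk.TrainConfig(seed=0), seed=0)
print(result.summary())

ari = sk.kmeans_ari(result.cell_embeddings(), graphset.labels, seed=0)
print(f"cell-type clustering ARI: {ari:.3f}")
```

prints (about 11 minutes on one CPU core):

```
Single-cell Hi-C contact imputation (subgraph transformer)
==============================================================
Cells:     40    Genome bins:    150    Resolution: 1000000 bp
Variant: full       k-hop: 1   d=32 heads=4 layers=2
Parameters: 43889
--------------------------------------------------------------
Train samples:   247188    Test samples:    22800
Epochs run:    30    Final train loss: 0.2284
Best validation AUPR: 0.7555
--------------------------------------------------------------
Held-out AUC:  0.9191
Held-out AUPR: 0.7492   (positive prevalence 0.2000)
==============================================================
cell-type clustering ARI: 1.000
```

Held-out AUPR 0.75 against a 0.20 positive prevalence means the model
recovers removed contacts far above chance (the Bayes-optimal scorer on this
generator reaches ~0.88; pure genomic distance ~0.84), and the learned cell
embeddings separate the two planted cell types perfectly.  The ablations
confirm both encoders matter: the cell-encoder-only variant reaches AUPR
0.715 and the subgraph-encoder-only variant 0.737 on the same split.

The same pipeline from the shell:

```bash
schiclink simulate --n-cells 40 --n-bins 150 --reads-per-cell 3000 --seed 0 --out-dir runs/sim
schiclink train    --graphset runs/sim/graphset.h5 --seed 0 --out-dir runs/fit
schiclink evaluate --graphset runs/sim/graphset.h5 \
                   --checkpoint runs/fit/checkpoints/model.npz \
                   --seed 0 --out-dir runs/eval
schiclink insulation --graphset runs/sim/graphset.h5 --chrom chr1 --window 5 \
                   --out-dir runs/ins
```

Real data enters through `schiclink preprocess` (tab-separated contact
pairs + a UCSC chrom.sizes file + a resolution) or through per-cell Matrix
Market files with a manifest.

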