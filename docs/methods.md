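# Methods

## Problem and model

Single-cell Hi-C (scHi-C) yields one contact map per cell over fixed genomic
bins, with well under a few percent of bin pairs observed; most zeros are
missing observations, not absent contacts. `schiclink` treats each cell's
per-chromosome map as a graph (bins = vertices, observed contacts = weighted
edges) and casts imputation as link prediction: for a candidate bin pair
(u, v) in cell i, predict the probability that the pair truly interacts.

The score combines two encoders feeding one decoder:

* **Cell encoder.** Each cell's per-chromosome upper triangles are flattened,
  concatenated genome-wide, reduced by PCA to `B_i` and passed through a
  two-layer ReLU MLP to the cell embedding `C_i`.  This carries the global
  context — density, type, cycle state — shared by all of the cell's edges.
* **Subgraph encoder.** The k-hop enclosing subgraph of (u, v) — every node
  within graph distance k of u or of v on the *masked* graph, plus u and v
  themselves — is encoded by a small transformer.  Node states are
  initialized as `h^0 = x_bin + z_deg` (learned genome-wide bin embeddings
  plus degree-centrality embeddings, both standard-normal at init).  The
  subgraph adjacency D is mapped row-wise by a two-layer MLP to an additive
  attention bias `E = tanh(relu(D W1 + b1) W2 + b2)`, added to every head's
  pre-softmax logits; attention is otherwise fully connected within the
  subgraph, so message passing is not limited to observed edges.  Layers are
  pre-LayerNorm multi-head attention and FFN blocks with residuals.
* **Decoder.** A two-layer MLP with sigmoid head on `(C_i | h_u^L | h_v^L)`,
  trained with binary cross-entropy against observed-vs-sampled-negative
  labels, optimized by Adam (beta1 = 0.9, beta2 = 0.999, lr = 1e-3, weight
  decay = 1e-5).

The candidate edge itself is always deleted from D before encoding —
otherwise train positives would read off their own label.  The cell
embeddings `C_i` double as a clustering representation; imputed maps feed the
compartment and insulation analyses below.

### Choices the equations leave open

* The attention update cites standard multi-head attention, which includes a
  value projection and an output projection; both are used even though only
  Q and K appear explicitly in the bias-modified logit formula.
* The logit scaling `1/sqrt(d)` is taken per head (`d_h = d / H`), the usual
  multi-head convention.
* The bias MLP acts on **rows** of the padded adjacency (input and output
  width `N_max`).  This makes E position-aware: subgraph nodes are sorted by
  genomic position, so row identity is informative.  The price is that the
  encoder with bias enabled is not permutation-equivariant; with the bias
  disabled equivariance is exact and is tested.
* E is shared across layers and heads, following the single unindexed E in
  the update rule.
* Degree embeddings index the raw within-subgraph degree (computed after
  candidate-edge masking), clipped at `d_max`.
* FFN width is `4d`; the loss clamps predictions at 1e-7 when computed from
  probabilities, and training uses the logit formulation, which needs no
  clamp.

### Default sizes

`d = 32, d_c = 32, H = 4 heads, L = 2 layers, N_max = 32, D_max = 32, k = 1,
dropout = 0.1, p = min(100, m-1)`.  One 256-sample batch (forward + backward)
costs ~0.24 s single-threaded at these sizes; doubling `d` and `N_max`
multiplies that by ~35, which is outside desk-scale CPU budgets.  `k = 1` is
the depth at which enclosing subgraphs already carry most of the local
signal; on dense synthetic cells a 1-hop neighborhood regularly exceeds
`N_max` and is down-sampled uniformly (u, v always kept).

## Sampling protocol

Per cell and chromosome, 10% of observed off-diagonal edges are removed and
become test positives; the remaining 90% are train positives.  Negatives are
drawn uniformly from never-observed pairs, 4x the test positives and 5x the
train positives, disjoint from each other and from all positives.  Negative
candidates are restricted to the genomic-distance band covered by the cell's
observed contacts; unconstrained negatives would be separable by distance
alone.  Test negatives take strict priority at their full 4x ratio (they
define the evaluation), and on dense graphs whose non-edge pool cannot also
cover 5x train negatives, the train negatives are capped at the remaining
pool with a warning; an error is raised only when even the test negatives
cannot be drawn.  Chromosomes with fewer than 10 edges are skipped.

Subgraph extraction always operates on the masked graph (test positives
deleted), so no test information reaches training or encoding.

## Training

Optional contrastive pretraining of the subgraph encoder precedes supervised
training: two views per subgraph (node dropping and edge perturbation at
ratio rho = 0.2, both sparing u, v and the candidate edge), mean-over-nodes
readout, projection head, NT-Xent loss at temperature tau = 0.5.  Pretraining
is off by default and capped at 50k subgraphs.

Supervised training visits a fresh uniform subsample of
`samples_per_epoch = 6000` train samples per epoch (30 epochs, batch 256) —
full passes over hundreds of thousands of samples are unnecessary at these
problem sizes and would be slow on one CPU.  A fixed 5% validation slice
(capped at 3000 samples) is carved from the train split for per-epoch AUPR
monitoring; the best-validation parameters are returned.  The test split is
never touched during fitting.  One user seed fans out to independent streams
for the split, initialization, pretraining, epoch subsampling, subgraph
capping and dropout, making runs bit-reproducible.

The network is implemented directly in NumPy (float64) with hand-written
backward passes and a manual Adam; all gradients are verified against
central finite differences in the test suite.

## Cell features

PCA scores of raw contact counts have scales of tens to hundreds and would
saturate the encoder at initialization, so the score matrix is divided by
one global factor (the leading component's standard deviation).
Per-component whitening is deliberately avoided: it erases the variance
ordering, and the separation between cell populations lives in the leading
components.

The number of components kept defaults to `p = min(32, max(2, m // 5))` — a
handful of leading components per expected population.  Taking nearly `m - 1`
components is counterproductive at desk scale: the trailing components are
pure sampling noise, and carrying them into the encoder drowns the population
axes, degrades the learned cell embeddings, and wastes the decoder's cell
pathway.  Users with many cells or many expected populations should raise
``p`` explicitly.

## Downstream structure analyses

* **Pseudo-bulk**: elementwise sum of per-cell maps (raw or imputed).
* **Distance normalization**: each entry divided by the mean contact level
  at its genomic distance (zeros included; with several chromosomes the
  per-distance means are pooled by entry count).  Entries at distances with
  zero expected level are undefined and excluded pairwise downstream.
* **Compartment Pearson map**: correlation between rows of the normalized
  map, pairwise-complete over defined entries; constant rows give 0 with the
  diagonal fixed at 1.  A/B compartments appear as a checkerboard of the
  sign structure.
* **Insulation score**: `s(x) = (contacts crossing x between the w-bin
  flanks) / (all contacts in the (2w+1)-bin square centered on x)`, with the
  row/column through x excluded from the numerator, the full square (both
  triangles plus diagonal) in the denominator, and NaN within w bins of the
  edge.  A constant map gives exactly `w^2/(2w+1)^2`.  Because the central
  row/column is excluded, a sharp domain edge yields a two-bin tie of exact
  zeros — boundary positions are therefore only defined to within one bin.
  Boundary calling takes local minima below a score quantile (default 0.1)
  with a minimum separation of 3 bins.

## Clustering metrics

Discrete types: seeded K-means (20 restarts) on the cell embeddings, scored
by the adjusted Rand index.  Cyclic states: cells are projected to 2D by
PCA and assigned an angle about the centroid; for each phase a one-vs-rest
AUC is computed with score equal to the negative circular distance from the
phase's circular-mean angle, and the metric is the mean over phases.  This
is rotation- and reflection-invariant by construction, 1.0 when phases
occupy contiguous arcs in cycle order, and ~0.5 for random labels.  Because
the phase centers are estimated from the same data, the null has a small
upward O(1/sqrt(n)) bias — negligible at population sizes (hundreds of
cells) but visible below ~50 cells per phase.

## Synthetic data: what it emulates, and what it does not

The generator builds an explicit per-cell contact-probability surface —
power-law distance decay `(|i-j|+1)^(-alpha)` times planted cell-type blocks,
an A/B checkerboard, and TAD blocks — normalizes it, and draws a fixed
number of reads per cell with replacement (multinomial), mirroring how the
imaging-derived conversion samples 200 reads per cell from an inverse
spatial-distance map.  The surface is returned alongside the sample so
imputation can be scored against ground truth.

Defaults for the benchmark study: 40 cells, one 150-bin chromosome at 1 Mb,
3000 reads per cell, alpha = 1.5 (between the fractal-globule exponent -1
and the equilibrium-globule -3/2; at these read depths this gives ~10%
map density, the attainable floor toward real scHi-C sparsity at the pinned
read count).  The two benchmark cell types differ by on-diagonal contact
domains (width 25 bins, contrast 8) shifted by half a width — type-specific
domain architecture — so a pair at a given distance can be enriched in one
type and depleted in the other.  Under these conditions the Bayes-optimal
scorer (true probability as score) reaches test AUPR ~0.88 and a pure
genomic-distance scorer ~0.84: planted structure, not distance alone,
separates the remainder.

Not emulated: ligation noise, duplicate reads, trans contacts, polymer
3D structure, coverage biases.  Passing tests on this generator shows the
pipeline recovers planted structure from realistic sparsity under a known
model; it does not certify performance on real assay artifacts.

## Known limitations

* Pure-NumPy training is practical up to tens of thousands of edge samples
  per epoch on one core; real multi-chromosome datasets need patience or
  more cores (BLAS threading helps the large matmuls).
* The bias MLP ties the model to the `N_max` it was trained with.
* Boundary calls inherit the one-bin ambiguity of the insulation definition.
* ARI/circular-ROC quality depends on the PCA features actually separating
  populations; with very few cells the PCA rank bound (m-1 components)
  limits what the cell encoder can see.
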