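# Methods

## The model

`plm` treats a single cell as an unordered "sentence" of genes. Each
expressed gene contributes one token; the token embedding is the elementwise
sum of a gene-identity embedding and an expression-level embedding,

    Token_ij = E_id(g_j) + E_expr(bin(x_ij)),

with no positional term, so the encoder is permutation-invariant over the
sentence by construction (and tested to be). Expression levels enter through
per-cell quantile bins: zeros take the reserved bin 0, and the nonzero
values of a cell are ranked (average ranks on ties) and mapped to
ceil(r * (n_bins - 1)) with r the normalized rank. Binning is therefore
invariant to any strictly monotone per-cell transform and independent of
sequencing depth; the default alphabet is 51 bins including the zero bin.

The encoder is a standard pre-norm transformer: multi-head self-attention
plus a position-wise feed-forward network in each layer, layer
normalization, residual connections, a final layer norm. The architecture
defaults are six layers and eight attention heads. Hidden width (256),
feed-forward width (4x), dropout (0) and CLS pooling are package choices
surfaced in `ModelConfig`; mean pooling is available as an alternative.
Padding keys receive an additive -1e9 before the softmax, so every
attention row is a probability distribution over the real tokens of the
sentence and padding receives exactly zero mass.

Two heads sit on the encoder: a two-layer perceptron that regresses the
(normalized) expression bin at each position, and a linear classifier over
cell types applied to the pooled cell embedding.

Everything differentiable is implemented on a compact tape-based
reverse-mode autodiff engine over NumPy arrays (`plm._autograd`), with
gradients verified against central finite differences in the test suite.
Training uses Adam. Computation is float32 and deterministic given the
configured seed on a single thread.

## Sequential pretraining

Stage 1 (masked-value modeling): 15% of the expression values of each
sentence — exactly round(0.15 * n_maskable) positions, never the CLS token,
chosen uniformly without replacement — are replaced by a MASK sentinel in
the value channel only; gene identities are never corrupted. The model
regresses the hidden bins under mean-squared error. Regression operates on
the normalized bin scale bin/(n_bins - 1); the output layer of the
regression head starts small with its bias at 0.5 (the mean normalized
bin), so optimization starts at the no-context baseline rather than
spending its step budget traversing the output scale.

Stage 2 (annotation): a classifier head is attached and the encoder +
head are trained jointly (freezing the encoder is a flag) under
cross-entropy on the cell-type labels, warm-started from the stage-1
parameters. A stratified 90/10 held-out split, derived from the stage seed,
is scored every run.

Training defaults follow the published recipe: batch size 64 and Adam at
learning rate 1e-4, no scheduler, no weight decay. Exact-count masking
makes the 15% figure testable exactly rather than in expectation.

Fine-tuning is stage-2 training on a small labeled corpus; new labels grow
the classifier head with the old class columns preserved at initialization.
Cross-species transfer re-initializes the gene-identity table for the new
vocabulary and retains the encoder, the value-bin table (bins are
species-agnostic by construction), and both heads.

## Desk-scale study conditions

The package is exercised end to end on synthetic corpora; the calibration
corpus used throughout the tests is 2,000 cells x 500 genes, 4 cell types
with 20 disjoint markers each at 5-fold enrichment, 2 batches with
log-normal per-gene batch scaling (sd 0.3), one planted 25-gene
co-regulated module at rho = 0.8, seed 7. Calibration training runs use a
2-layer, 4-head, 64-dimensional encoder on the top 200
highly-variable genes with sentences truncated at 128 tokens, 5 epochs of
masked-value pretraining and 20 epochs of annotation training; these sizes
keep a full two-stage run in the low minutes on one CPU core while leaving
the learning signals (masked MSE below the no-context baseline; held-out
annotation accuracy above 0.9) comfortably measurable.

## Synthetic corpus generator

Per cell i and gene j the latent log-rate is

    log mu_ij = log base_j + 1[j marker of type(i)] log(fold)
                + batch(b(i), j) + module term,

with gene base abundances log-normal (rescaled so the expected library size
is `library_size_mean`, default 2,000 counts per cell — about 4 counts per
gene over 500 genes, the per-gene depth a highly-variable-gene slice of a
typical droplet experiment carries), batch effects log-normal per
(batch, gene), and counts negative-binomial (gamma-Poisson) with shared
dispersion theta = 1. Each planted module adds
tau * (sqrt(rho) z_i + sqrt(1 - rho) eta_ij) - tau^2/2 to its genes'
log-rates, where z_i is a shared per-cell factor: module genes' latent
log-rates correlate at exactly rho, and z_i is exposed as ground truth so
analyses can condition on module-active cells. tau defaults to 1.0, a
strong but realistic co-activation swing for stress-response-like modules.

What the generator does not emulate: dropout beyond negative-binomial
zeros, continuous trajectories, ambient contamination, doublets, and
cross-type marker sharing. Passing tests on these corpora therefore
demonstrate that the machinery works and learns planted structure at desk
scale, not that it reproduces any real-atlas accuracy figure.

## Downstream analyses

**Zero-shot annotation** runs the pretrained classifier on new cells with
no update; genes absent from the model vocabulary are dropped before
encoding. Confusion matrices report reference x predicted counts, and a
user-supplied label-merge map recomputes accuracy after collapsing
subtypes (e.g. protoxylem + metaxylem onto xylem).

**Integration benchmark**: cell embeddings are clustered by modularity
community detection (Leiden refinement via `leidenalg`,
RBConfiguration objective, seeded) on a symmetric Euclidean kNN graph
(k = 15) over a resolution grid (default 0.1-1.5 in steps of 0.1). Each
partition is scored against the reference cell types with ARI and NMI
(arithmetic-mean normalization); the silhouette of the reference types over
the embedding completes the triple. Per-resolution curves and per-metric
maxima are reported.

**Attention networks**: for one cell, the head-averaged attention of the
final encoder layer (or the mean over all layers — the aggregation is
recorded in the matrix provenance) has its CLS row/column removed, is
symmetrized as (A + A^T)/2, and is min-max normalized to [0, 1] over the
off-diagonal (a constant matrix maps to zeros, and the normalization is
invariant to positive rescaling). Hub genes are those with the largest
total normalized attention; networks expand breadth-first from the hubs,
attaching each frontier gene's k strongest partners per level (defaults
k = 5, depth 2; the reduced direct-interaction view re-expands with k = 2,
depth 1 and is a subgraph of the full network by construction). Ties break
score-descending then gene-id ascending, so networks are deterministic.

For population-level structure recovery the package also provides a
masked-query readout (`grn.masked_pair_attention`): the training-time
corruption is re-applied and only the attention rows of value-masked
positions are accumulated, because masked-value training shapes attention
precisely where a value must be reconstructed from partners. Pair scores
are averaged per (query gene, key gene), symmetrized and min-max
normalized.

**The planted-module attention-recovery study** (`plm.studies`) measures
whether pretraining leaves a planted co-regulated module detectable in
attention. Four choices define the protocol, each with a mechanistic
rationale:

1. *Heavier corruption during pretraining* (half the values masked instead
   of the 15% default). With 15% masking a small model can reconstruct
   bins from the visible majority of the sentence through value-vector
   mixing and never needs partner-directed attention weights; heavy
   corruption makes partner attention the only reliable signal. The
   package's training default is unchanged — this is the study's probe
   setting.
2. *Masked-query readout* (above), at the same heavy rate.
3. *Module-active cells only* (top quartile of the true per-cell
   co-activation factor, which the generator exposes). Attention is
   largely keyed on expression level, so module pairs stand out only in
   cells where the module is jointly high — consistent with reading
   networks from an individual cell chosen for the process of interest.
4. *Best single head* rather than the head average. Heads specialize;
   averaging a module-tracking head with bin-magnitude heads dilutes the
   signal. The study scans all layer/head combinations and reports the
   strongest, as interpretability practice does.

The statistic is the Mann-Whitney rank-AUC of within-module pairs versus
all other pairs of the symmetrized mean attention matrix, per seed, with
the corpus regenerated and the model retrained from scratch each seed.

**Gene programs** are communities (same Leiden machinery) in a kNN graph
over the learned gene-identity embedding rows; the program count is
emergent from the resolution, not fixed. Program activity per cell type is
the mean over member genes of the across-type z-score of the type-mean
log-normalized expression; genes constant across types contribute zero.

## Numerical choices and degenerate inputs

- Ranking ties inside a cell use average ranks; HVG ties and all
  neighbor/hub ties break lexicographically — declared so results are
  bit-reproducible.
- Cells with zero total counts are rejected at normalization; all-zero
  rows cannot be encoded as sentences and raise.
- A constant attention matrix normalizes to all zeros rather than NaN.
- NMI of a constant labeling is 0 (1 only when both partitions are the
  trivial single cluster); singleton clusters contribute 0 to the
  silhouette.
- Checkpoints store parameters, the full model config and a hash of the
  vocabulary; loading against a different vocabulary is refused.

## Known limitations

- The desk-scale corpora and encoders are orders of magnitude smaller than
  a real pretraining atlas; absolute accuracies here say nothing about
  atlas-scale performance.
- Attention-derived networks are read from attention weights only; value
  vectors also carry gene information, so attention maps are a partial
  view of the mechanism, and module recovery from attention is measurably
  harder than module recovery from embeddings or expression.
- The generator's negative-binomial noise with a single shared dispersion
  is a simplification; real data show gene-specific dispersion.
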