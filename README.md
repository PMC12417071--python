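# plm — a plant single-cell language model toolkit

`plm` is a desk-scale, fully-tested implementation of a transformer
"foundation model" workflow for plant single-cell RNA-seq: cells are
tokenized into sentences of (gene, binned expression) pairs, an encoder is
pretrained sequentially — masked-value reconstruction first, then
supervised cell-type classification — and the trained model drives
zero-shot annotation, batch-integration benchmarking, attention-derived
gene networks, and gene-program discovery. It is aimed at computational
biologists who want the full mechanism of such models on their desk:
every stage runs in minutes on one CPU against a synthetic corpus with
known ground truth, with no downloads and no GPU.

## The model

A cell with expression vector x becomes a sentence of its nonzero genes.
Each gene j contributes a token embedded as

    Token_ij = E_id(g_j) + E_expr(bin(x_ij))

where bin(·) maps the cell's nonzero values to per-cell quantile ranks
(51 bins by default, bin 0 reserved for zeros). A pre-norm transformer
encoder — six layers, eight attention heads by default — contextualizes the
tokens; there is no positional term, so a cell is an unordered gene set.
Pretraining stage 1 masks 15% of the expression values per sentence and
regresses them (MSE); stage 2 trains a classifier head (cross-entropy) on
cell-type labels, warm-started from stage 1. Defaults: batch size 64, Adam
at learning rate 1e-4. The transformer and its training loop are built on
a small NumPy reverse-mode autodiff engine included in the package;
gradients are finite-difference-checked in the test suite.

Downstream, the pooled CLS state is the cell embedding (clustering, ARI /
NMI / silhouette integration benchmark over a Louvain-style resolution
sweep), per-cell attention maps become gene-gene relatedness matrices
(min-max normalized to [0, 1], hub genes, top-k / depth-limited network
expansion), and communities in the learned gene-embedding table are
reported as gene programs with per-type activity scores.

## Worked example

```python
from plm.io import BinConfig, bin_expression, build_vocabulary, normalize_log, select_hvgs
from plm.model import ModelConfig
from plm.synthetic import calibration_config, generate_corpus, split
from plm.train import TrainConfig, pretrain_mlm, pretrain_annotation, evaluate_masked_mse
from plm.annotate import zero_shot_annotate, confusion

train, test = split(generate_corpus(calibration_config(seed=7)),
                    (0.9, 0.1), stratify_by="batch", seed=7)
binned = bin_expression(select_hvgs(normalize_log(train.matrix), 200), BinConfig(51))
held = bin_expression(normalize_log(test.matrix).subset_genes(binned.gene_ids), BinConfig(51))
vocab = build_vocabulary(binned.gene_ids)

mc = ModelConfig(n_gene_tokens=vocab.n_tokens, n_value_bins=51,
                 n_layers=2, n_heads=4, d_model=64, d_ff=128, max_len=128)
state1, rep1 = pretrain_mlm(binned, vocab, TrainConfig(stage="mlm", epochs=5, seed=7),
                            model_config=mc)
print(evaluate_masked_mse(state1, held, vocab, seed=7))
state2, rep2 = pretrain_annotation(binned, vocab,
                                   TrainConfig(stage="annotate", epochs=20, seed=7),
                                   init=state1)
print(rep2.metrics["holdout_accuracy"])
print(confusion(zero_shot_annotate(state2, held, vocab)).accuracy())
```

Output (one CPU, ~3 minutes):

```
{'model_mse': 0.0714..., 'baseline_mse': 0.0752..., 'n_masked': 3125.0}
0.9555...
0.95
```

The first line says 5 epochs of masked-value pretraining predict held-out
masked bins better than the constant mean-bin baseline on the same
positions (MSE 0.071 vs 0.075, normalized-bin scale); the second is
held-out annotation accuracy after stage 2; the third is zero-shot
accuracy on the untouched 10% split — the four synthetic cell types are
well separated, so a correctly working pipeline should sit well above 0.9.

The same flow is available from the shell:

```bash
plm synth --seed 7 --out data/
plm preprocess --input data/ --n-hvg 200 --out corpus.h5 --vocab-out vocab.json
plm pretrain-mlm --corpus corpus.h5 --vocab vocab.json --checkpoint s1.npz \
    --n-layers 2 --n-heads 4 --d-model 64 --max-len 128 --epochs 5 --seed 7
plm pretrain-annot --corpus corpus.h5 --vocab vocab.json --init s1.npz \
    --checkpoint s2.npz --epochs 20 --seed 7
plm annotate --checkpoint s2.npz --corpus corpus.h5 --vocab vocab.json --out labels.tsv
plm grn --checkpoint s2.npz --corpus corpus.h5 --vocab vocab.json \
    --hubs auto:2 --k 5 --depth 2 --out net.graphml
plm pipeline --seed 7 --out run/   # everything above in one command
```

See `docs/methods.md` for the model, the synthetic-corpus generative
process, all numerical conventions, and known limitations.

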