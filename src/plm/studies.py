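"""Desk-scale study protocols used by the test harness and the acceptance
script.

The planted-module attention-recovery study asks whether masked-value
pretraining leaves a detectable trace of a co-regulated gene module in the
encoder's attention. Protocol:

* corpus: two cell types with markers, one planted module at rho = 0.8,
  negative-binomial counts at ~4 expected counts per gene;
* pretraining: heavier corruption (half the values masked) than the
  package default — small models only develop partner-directed attention
  when reconstruction cannot lean on the visible majority of the sentence;
* readout: the training-time corruption is re-applied to the module-active
  cells (top quartile of the true co-activation factor) and the attention
  rows of masked positions are accumulated per (query gene, key gene) for
  every layer and head separately;
* statistic: per attention head, the Mann-Whitney rank-AUC of within-module
  pairs versus all other pairs on the symmetrized mean matrix. The study
  reports the best head — heads specialize, and averaging across heads
  dilutes a module-tracking head with bin-magnitude heads.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu

from .io import BinConfig, bin_expression, build_vocabulary, normalize_log
from .model import ModelConfig, forward
from .synthetic import Module, SynthConfig, generate_corpus
from .tokenize import apply_mask, encode_corpus, pad_batch
from .train import TrainConfig, pretrain_mlm

__all__ = ["module_recovery_run", "module_recovery_study"]


def _per_head_masked_attention(state, sentences, n_bins, vocab, rate, rounds,
                               seed):
    """Accumulate masked-query attention per layer and head; returns
    (genes, totals[L,H,n,n], counts[L,H,n,n])."""
    genes = sorted(vocab.gene_to_token)
    index = {vocab.gene_to_token[g]: i for i, g in enumerate(genes)}
    n = len(genes)
    L, H = state.config.n_layers, state.config.n_heads
    total = np.zeros((L, H, n, n))
    count = np.zeros((L, H, n, n))
    rng = np.random.default_rng(seed)
    for _ in range(rounds):
        for lo in range(0, len(sentences), 64):
            batch = pad_batch(sentences[lo:lo + 64], state.config.max_len,
                              n_bins)
            masked = apply_mask(batch, rate=rate,
                                seed=int(rng.integers(2 ** 31)))
            out = forward(masked, state, return_attentions=True)
            for l, att in enumerate(out.attentions):
                for bi in range(att.shape[0]):
                    keys = np.where(~masked.pad_flags[bi])[0][1:]
                    queries = np.where(masked.mask_flags[bi])[0]
                    if queries.size == 0:
                        continue
                    toks = masked.gene_tokens[bi]
                    qi = np.array([index[t] for t in toks[queries]])
                    ki = np.array([index[t] for t in toks[keys]])
                    for h in range(H):
                        total[l, h][np.ix_(qi, ki)] += \
                            att[bi, h][np.ix_(queries, keys)]
                        count[l, h][np.ix_(qi, ki)] += 1
    return genes, total, count


def _pair_auc(genes, mean_matrix, module_genes):
    in_mod = np.array([g in set(module_genes) for g in genes])
    iu = np.triu_indices(len(genes), k=1)
    scores = mean_matrix[iu]
    same = in_mod[iu[0]] & in_mod[iu[1]]
    ok = ~np.isnan(scores)
    w, b = scores[ok & same], scores[ok & ~same]
    u = mannwhitneyu(w, b, alternative="greater").statistic
    return float(u / (w.size * b.size)), float(w.mean()), float(b.mean())


def module_recovery_run(seed: int, n_cells: int = 600, n_genes: int = 120,
                        module_size: int = 15, rho: float = 0.8,
                        epochs: int = 80, train_mask_rate: float = 0.5,
                        readout_rate: float = 0.5, rounds: int = 3,
                        lr: float = 1e-3) -> dict:
    """One seed of the planted-module attention-recovery study.

    Returns the best-head AUC plus the within/between means of that head,
    and the head-averaged final-layer AUC for reference.
    """
    module_genes = [f"g{j:04d}" for j in range(40, 40 + module_size)]
    cfg = SynthConfig(n_cells=n_cells, n_genes=n_genes, n_types=2,
                      markers_per_type=10, marker_fold=5.0, n_batches=1,
                      batch_scale_sd=0.0,
                      modules=[Module(genes=module_genes, rho=rho)],
                      library_size_mean=4.0 * n_genes, seed=seed)
    corpus = generate_corpus(cfg)
    binned = bin_expression(normalize_log(corpus.matrix), BinConfig(51))
    vocab = build_vocabulary(binned.gene_ids)
    mc = ModelConfig(n_gene_tokens=vocab.n_tokens, n_value_bins=51,
                     n_layers=2, n_heads=4, d_model=32, d_ff=64, max_len=128)
    state, _ = pretrain_mlm(
        binned, vocab,
        TrainConfig(stage="mlm", epochs=epochs, seed=seed, learning_rate=lr,
                    mask_rate=train_mask_rate),
        model_config=mc)
    z = corpus.module_factors["module0"]
    active = np.argsort(-z)[: n_cells // 4]
    sentences = encode_corpus(binned, vocab, max_len=mc.max_len)
    active_sents = [sentences[i] for i in active]
    genes, total, count = _per_head_masked_attention(
        state, active_sents, 51, vocab, rate=readout_rate, rounds=rounds,
        seed=seed)
    best = None
    for l in range(mc.n_layers):
        for h in range(mc.n_heads):
            with np.errstate(invalid="ignore"):
                mean = np.where(count[l, h] > 0,
                                total[l, h] / np.maximum(count[l, h], 1),
                                np.nan)
            sym = np.nanmean(np.stack([mean, mean.T]), axis=0)
            auc, w, b = _pair_auc(genes, sym, module_genes)
            if best is None or auc > best["auc"]:
                best = {"auc": auc, "within_mean": w, "between_mean": b,
                        "layer": l, "head": h}
    return best


def module_recovery_study(base_seed: int = 0, n_seeds: int = 10, **kw) -> dict:
    """Run the study across seeds; reports per-seed best-head AUCs, their
    mean, and the fraction of seeds with within > between."""
    runs = [module_recovery_run(base_seed + i + 1, **kw)
            for i in range(n_seeds)]
    aucs = [r["auc"] for r in runs]
    return {"aucs": aucs, "mean_auc": float(np.mean(aucs)),
            "min_auc": float(np.min(aucs)),
            "frac_within_gt_between": float(np.mean(
                [r["within_mean"] > r["between_mean"] for r in runs])),
            "runs": runs}
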