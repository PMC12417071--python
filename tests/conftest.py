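"""Shared fixtures: the calibration corpus and the two-stage trained models.

The calibration corpus (2,000 cells, 500 genes, 4 types with 20 five-fold
markers each, 2 batches, one 25-gene rho=0.8 module, seed 7) is the single
synthetic study condition every training-dependent test refers to. Training
fixtures are session-scoped because pretraining, while desk-scale, dominates
suite runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from plm.io import BinConfig, bin_expression, build_vocabulary, normalize_log, select_hvgs
from plm.model import ModelConfig
from plm.synthetic import calibration_config, generate_corpus, split
from plm.train import TrainConfig, pretrain_annotation, pretrain_mlm

N_HVG = 200
N_BINS = 51

# desk-scale encoder used for all calibration training runs
SMALL_MODEL = dict(n_layers=2, n_heads=4, d_model=64, d_ff=128, max_len=128)
MLM_EPOCHS = 5
ANNOT_EPOCHS = 20


@pytest.fixture(scope="session")
def calibration():
    """(train corpus, held-out corpus) split 90/10 stratified by batch."""
    corpus = generate_corpus(calibration_config(seed=7))
    return split(corpus, (0.9, 0.1), stratify_by="batch", seed=7)


@pytest.fixture(scope="session")
def calibration_binned(calibration):
    """Binned train/test matrices on the train-set HVGs, plus the vocabulary."""
    train_c, test_c = calibration
    train_m = select_hvgs(normalize_log(train_c.matrix), N_HVG)
    train_b = bin_expression(train_m, BinConfig(N_BINS))
    test_m = normalize_log(test_c.matrix).subset_genes(train_b.gene_ids)
    test_b = bin_expression(test_m, BinConfig(N_BINS))
    vocab = build_vocabulary(train_b.gene_ids)
    return train_b, test_b, vocab


@pytest.fixture(scope="session")
def model_config(calibration_binned):
    _, _, vocab = calibration_binned
    return ModelConfig(n_gene_tokens=vocab.n_tokens, n_value_bins=N_BINS,
                       **SMALL_MODEL)


@pytest.fixture(scope="session")
def stage1(calibration_binned, model_config):
    """Masked-value pretraining on the calibration corpus (5 epochs)."""
    train_b, _, vocab = calibration_binned
    cfg = TrainConfig(stage="mlm", epochs=MLM_EPOCHS, seed=7)
    return pretrain_mlm(train_b, vocab, cfg, model_config=model_config)


@pytest.fixture(scope="session")
def stage2(calibration_binned, stage1):
    """Annotation pretraining warm-started from the stage-1 encoder."""
    train_b, _, vocab = calibration_binned
    state1, _ = stage1
    cfg = TrainConfig(stage="annotate", epochs=ANNOT_EPOCHS, seed=7)
    return pretrain_annotation(train_b, vocab, cfg, init=state1)


@pytest.fixture(scope="session")
def stage2_cold(calibration_binned, model_config):
    """Annotation training from a random encoder (no stage-1 warm start),
    otherwise identical — the comparison arm for the sequential strategy."""
    from plm.model import init_model

    train_b, _, vocab = calibration_binned
    fresh = init_model(model_config, seed=7, vocab=vocab)
    cfg = TrainConfig(stage="annotate", epochs=ANNOT_EPOCHS, seed=7)
    return pretrain_annotation(train_b, vocab, cfg, init=fresh)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
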