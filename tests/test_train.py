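"""Losses, the two pretraining stages, fine-tuning, and species transfer."""

import numpy as np
import pytest
from scipy.special import softmax

from plm.io import BinConfig, bin_expression, build_vocabulary, normalize_log
from plm.model import ModelConfig, init_model
from plm.synthetic import SynthConfig, generate_corpus
from plm.train import (TrainConfig, cross_entropy_loss,
                       fine_tune, mse_masked_loss, pretrain_annotation,
                       pretrain_mlm, transfer_species)
from plm.tokenize import encode_corpus

TINY_MODEL = dict(n_layers=1, n_heads=2, d_model=32, d_ff=64, max_len=96)


def _tiny_corpus(seed=0, n_cells=200, n_types=2, n_genes=60):
    cfg = SynthConfig(n_cells=n_cells, n_genes=n_genes, n_types=n_types,
                      markers_per_type=8, marker_fold=5.0, n_batches=1,
                      batch_scale_sd=0.0, library_size_mean=240.0, seed=seed)
    c = generate_corpus(cfg)
    b = bin_expression(normalize_log(c.matrix), BinConfig(21))
    return b, build_vocabulary(b.gene_ids)


def _tiny_model_config(vocab, n_bins=21):
    return ModelConfig(n_gene_tokens=vocab.n_tokens, n_value_bins=n_bins,
                       **TINY_MODEL)


class TestLosses:
    def test_mse_identity_is_zero(self):
        assert mse_masked_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_mse_hand_computed(self):
        assert mse_masked_loss([0.0, 2.0], [1.0, 2.0]) == pytest.approx(0.5)

    def test_mse_permutation_invariant(self, rng):
        p = rng.normal(size=20)
        t = rng.normal(size=20)
        perm = rng.permutation(20)
        assert mse_masked_loss(p, t) == pytest.approx(
            mse_masked_loss(p[perm], t[perm]))

    def test_mse_empty_rejected(self):
        with pytest.raises(ValueError):
            mse_masked_loss([], [])

    def test_cross_entropy_uniform_is_log_c(self):
        logits = np.zeros((6, 4))
        assert cross_entropy_loss(logits, np.zeros(6, dtype=int)) == \
            pytest.approx(np.log(4))

    def test_cross_entropy_confident_correct_approaches_zero(self):
        logits = np.full((3, 4), -50.0)
        logits[np.arange(3), [0, 1, 2]] = 50.0
        assert cross_entropy_loss(logits, np.array([0, 1, 2])) < 1e-6

    def test_cross_entropy_matches_brute_force_softmax(self, rng):
        logits = rng.normal(size=(5, 3))
        labels = rng.integers(0, 3, size=5)
        probs = softmax(logits, axis=1)
        expected = -np.mean([np.log(probs[i, labels[i]]) for i in range(5)])
        assert cross_entropy_loss(logits, labels) == pytest.approx(expected)

    def test_cross_entropy_label_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="class range"):
            cross_entropy_loss(np.zeros((2, 3)), np.array([0, 3]))


class TestPretrainMLM:
    def test_zero_epochs_is_noop(self):
        b, vocab = _tiny_corpus()
        init = init_model(_tiny_model_config(vocab), seed=0, vocab=vocab)
        before = {k: v.data.copy() for k, v in init.params.items()}
        state, report = pretrain_mlm(b, vocab, TrainConfig(epochs=0, seed=0),
                                     init=init)
        assert report.epoch_losses == []
        for k in before:
            np.testing.assert_array_equal(state.params[k].data, before[k])

    def test_same_seed_identical_trajectories(self):
        b, vocab = _tiny_corpus()
        mc = _tiny_model_config(vocab)
        cfg = TrainConfig(stage="mlm", epochs=2, seed=5)
        _, r1 = pretrain_mlm(b, vocab, cfg, model_config=mc)
        _, r2 = pretrain_mlm(b, vocab, cfg, model_config=mc)
        assert r1.epoch_losses == r2.epoch_losses

    def test_training_log_is_json_lines(self, tmp_path):
        b, vocab = _tiny_corpus()
        log = str(tmp_path / "log.jsonl")
        cfg = TrainConfig(stage="mlm", epochs=1, seed=0, log_path=log)
        _, report = pretrain_mlm(b, vocab, cfg,
                                 model_config=_tiny_model_config(vocab))
        import json
        lines = [json.loads(l) for l in open(log)]
        assert len(lines) == report.steps
        assert {"stage", "step", "epoch", "loss", "lr"} <= set(lines[0])


class TestPretrainAnnotation:
    def test_shuffled_labels_give_chance_accuracy(self):
        b, vocab = _tiny_corpus(seed=3, n_cells=240, n_types=4)
        rng = np.random.default_rng(0)
        b.cell_type = list(rng.permutation(b.cell_type))
        init = init_model(_tiny_model_config(vocab), seed=0, vocab=vocab)
        state, report = pretrain_annotation(
            b, vocab, TrainConfig(stage="annotate", epochs=3, seed=0), init=init)
        # permutation null: held-out accuracy near 1/K
        assert report.metrics["holdout_accuracy"] < 0.55

    def test_missing_labels_rejected(self):
        b, vocab = _tiny_corpus()
        b.cell_type = None
        init = init_model(_tiny_model_config(vocab), seed=0, vocab=vocab)
        with pytest.raises(ValueError, match="no cell_type"):
            pretrain_annotation(b, vocab, TrainConfig(stage="annotate",
                                                      epochs=1), init=init)

    def test_single_class_rejected(self):
        b, vocab = _tiny_corpus()
        b.cell_type = ["same"] * len(b.cell_ids)
        init = init_model(_tiny_model_config(vocab), seed=0, vocab=vocab)
        with pytest.raises(ValueError, match="at least two"):
            pretrain_annotation(b, vocab, TrainConfig(stage="annotate",
                                                      epochs=1), init=init)


class TestFineTune:
    def test_accuracy_not_below_zero_shot_on_same_data(self, calibration_binned,
                                                       stage2):
        train_b, _, vocab = calibration_binned
        state2, _ = stage2
        cfg = TrainConfig(stage="finetune", epochs=1, seed=3)
        _, report = fine_tune(state2, train_b, vocab, cfg)
        assert report.metrics["holdout_accuracy"] >= \
            report.metrics["holdout_accuracy_before"] - 0.02

    def test_new_label_grows_head_preserving_old_logits(self):
        b, vocab = _tiny_corpus(seed=4, n_types=2)
        init = init_model(_tiny_model_config(vocab), seed=0, vocab=vocab)
        state, _ = pretrain_annotation(
            b, vocab, TrainConfig(stage="annotate", epochs=1, seed=0), init=init)
        old_W = state.params["cls_W"].data.copy()
        b2, _ = _tiny_corpus(seed=5, n_types=3)
        state2, _ = fine_tune(state, b2, vocab,
                              TrainConfig(stage="finetune", epochs=0, seed=0))
        assert state2.config.n_classes == 3
        for j, lab in enumerate(state.classifier_labels):
            jj = state2.classifier_labels.index(lab)
            np.testing.assert_array_equal(state2.params["cls_W"].data[:, jj],
                                          old_W[:, j])

    def test_disjoint_vocabulary_rejected(self):
        b, vocab = _tiny_corpus()
        init = init_model(_tiny_model_config(vocab), seed=0, vocab=vocab)
        other = build_vocabulary(["other1", "other2"])
        b.gene_ids = [f"x{j}" for j in range(len(b.gene_ids))]
        with pytest.raises(ValueError, match="disjoint"):
            fine_tune(init, b, other, TrainConfig(stage="finetune", epochs=1))


class TestTransfer:
    def test_encoder_retained_bit_identical(self):
        b, vocab = _tiny_corpus()
        init = init_model(_tiny_model_config(vocab), seed=0, vocab=vocab)
        new_vocab = build_vocabulary([f"z{j}" for j in range(40)])
        moved = transfer_species(init, new_vocab, seed=1)
        for k, v in init.params.items():
            if k == "E_id":
                continue
            np.testing.assert_array_equal(moved.params[k].data, v.data)
        assert moved.params["E_id"].data.shape[0] == new_vocab.n_tokens

    def test_forward_runs_on_new_species_batch(self):
        b, vocab = _tiny_corpus()
        init = init_model(_tiny_model_config(vocab), seed=0, vocab=vocab)
        b2, vocab2 = _tiny_corpus(seed=9, n_genes=40)
        moved = transfer_species(init, vocab2, seed=1)
        from plm.model import forward
        from plm.tokenize import pad_batch
        sents = encode_corpus(b2, vocab2, max_len=96)[:8]
        out = forward(pad_batch(sents, 96, 21), moved)
        assert np.isfinite(out.token_states.data).all()

    def test_transfer_warm_start_beats_from_scratch(self):
        """A model pretrained on species A, transferred to species B sharing
        the generative structure, trains to lower masked loss than a fresh
        model under the identical schedule."""
        bA, vocabA = _tiny_corpus(seed=11, n_cells=300)
        mc = _tiny_model_config(vocabA)
        stA, _ = pretrain_mlm(bA, vocabA, TrainConfig(stage="mlm", epochs=4,
                                                      seed=11), model_config=mc)
        # species B: same generative law, different seed and gene names
        cfg = SynthConfig(n_cells=200, n_genes=60, n_types=2, markers_per_type=8,
                          marker_fold=5.0, n_batches=1, batch_scale_sd=0.0,
                          library_size_mean=240.0, seed=12)
        cB = generate_corpus(cfg)
        cB.matrix.gene_ids = [f"sp2_{g}" for g in cB.matrix.gene_ids]
        bB = bin_expression(normalize_log(cB.matrix), BinConfig(21))
        vocabB = build_vocabulary(bB.gene_ids)
        warm = transfer_species(stA, vocabB, seed=13)
        tc = TrainConfig(stage="mlm", epochs=2, seed=14)
        _, warm_rep = pretrain_mlm(bB, vocabB, tc, init=warm)
        mcB = _tiny_model_config(vocabB)
        fresh = init_model(mcB, seed=13, vocab=vocabB)
        _, fresh_rep = pretrain_mlm(bB, vocabB, tc, init=fresh)
        assert warm_rep.final_loss < fresh_rep.final_loss


class TestCalibrationRuns:
    def test_mlm_loss_trajectory_monotone_in_epoch_median(self, stage1):
        """At the published learning rate the calibration loss trajectory
        declines epoch over epoch."""
        _, report = stage1
        losses = report.epoch_losses
        assert all(losses[i + 1] <= losses[i] * 1.02
                   for i in range(len(losses) - 1))
        assert losses[-1] < losses[0]

    def test_stage2_records_holdout_accuracy(self, stage2):
        _, report = stage2
        assert 0.0 <= report.metrics["holdout_accuracy"] <= 1.0
        assert len(report.epoch_losses) == 20
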