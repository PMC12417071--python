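"""Encoder forward semantics: summed embeddings, attention masking,
pooling, heads, checkpointing."""

import numpy as np
import pytest

from plm._autograd import Tensor
from plm.io import build_vocabulary
from plm.model import (ModelConfig, classify, embed_tokens, forward,
                       init_model, load_checkpoint, predict_masked_values,
                       save_checkpoint, cell_embedding)
from plm.tokenize import Batch, value_sentinels


def _tiny_batch(n_bins=5, lengths=(4, 6), n_genes=12, seed=0):
    rng = np.random.default_rng(seed)
    width = max(lengths)
    sent = value_sentinels(n_bins)
    genes = np.zeros((len(lengths), width), dtype=np.int64)
    vals = np.full((len(lengths), width), sent["pad"], dtype=np.int64)
    pad = np.ones((len(lengths), width), dtype=bool)
    for i, ln in enumerate(lengths):
        genes[i, 0] = 1  # CLS
        genes[i, 1:ln] = rng.choice(np.arange(3, 3 + n_genes), size=ln - 1,
                                    replace=False)
        vals[i, 0] = sent["cls"]
        vals[i, 1:ln] = rng.integers(1, n_bins, size=ln - 1)
        pad[i, :ln] = False
    return Batch(gene_tokens=genes, value_bins_in=vals, pad_flags=pad,
                 mask_flags=np.zeros_like(pad), value_targets=np.empty(0),
                 n_bins=n_bins)


@pytest.fixture()
def tiny_state():
    cfg = ModelConfig(n_gene_tokens=16, n_value_bins=5, n_layers=2, n_heads=2,
                      d_model=16, d_ff=32, n_classes=5, max_len=8)
    return init_model(cfg, seed=0)


class TestEmbedTokens:
    def test_sum_of_hand_set_tables(self):
        cfg = ModelConfig(n_gene_tokens=4, n_value_bins=3, n_layers=1,
                          n_heads=1, d_model=2, d_ff=4, max_len=4)
        state = init_model(cfg, seed=0)
        E_id = np.zeros((4, 2), dtype=np.float32)
        E_id[2] = (1.0, 0.0)
        E_expr = np.zeros((6, 2), dtype=np.float32)
        E_expr[1] = (0.0, 2.0)
        state.params["E_id"] = Tensor(E_id, requires_grad=True)
        state.params["E_expr"] = Tensor(E_expr, requires_grad=True)
        out = embed_tokens(np.array([[2]]), np.array([[1]]), state)
        np.testing.assert_allclose(out.data[0, 0], [1.0, 2.0])

    def test_zero_tables_give_zero_embeddings(self, tiny_state):
        tiny_state.params["E_id"].data[:] = 0
        tiny_state.params["E_expr"].data[:] = 0
        batch = _tiny_batch()
        out = embed_tokens(batch.gene_tokens, batch.value_bins_in, tiny_state)
        assert np.abs(out.data).max() == 0

    def test_channels_are_distinct(self):
        """Reading a value id through the gene table differs from reading it
        through the value table unless the tables coincide (toy brute force)."""
        cfg = ModelConfig(n_gene_tokens=2, n_value_bins=2, n_layers=1,
                          n_heads=1, d_model=2, d_ff=4, max_len=4)
        state = init_model(cfg, seed=1)
        a = embed_tokens(np.array([[0]]), np.array([[1]]), state).data
        b = embed_tokens(np.array([[1]]), np.array([[0]]), state).data
        assert not np.allclose(a, b)

    def test_out_of_range_token_rejected(self, tiny_state):
        with pytest.raises(ValueError, match="out of embedding-table range"):
            embed_tokens(np.array([[99]]), np.array([[1]]), tiny_state)


class TestForward:
    def test_attention_rows_sum_to_one_and_pad_gets_zero(self, tiny_state):
        batch = _tiny_batch(lengths=(4, 6))
        out = forward(batch, tiny_state, return_attentions=True)
        for A in out.attentions:
            np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-5)
            # row 0 has padding at positions 4,5
            assert A[0, :, :, 4:].max() == 0.0

    def test_default_config_six_layers_eight_heads(self):
        cfg = ModelConfig(n_gene_tokens=32, n_value_bins=5)
        assert cfg.n_layers == 6
        assert cfg.n_heads == 8
        state = init_model(cfg, seed=0)
        batch = _tiny_batch(lengths=(5,), n_genes=20)
        out = forward(batch, state, return_attentions=True)
        assert len(out.attentions) == 6
        assert all(a.shape[1] == 8 for a in out.attentions)
        assert all(a.shape[2] == a.shape[3] == 5 for a in out.attentions)

    def test_single_head_attention_matches_manual_linear_algebra(self):
        """1-layer 1-head d_model=2 with hand-set projections reproduces
        softmax(QK^T/sqrt(d_k)) computed independently in plain numpy."""
        cfg = ModelConfig(n_gene_tokens=6, n_value_bins=3, n_layers=1,
                          n_heads=1, d_model=2, d_ff=4, max_len=4)
        state = init_model(cfg, seed=3)
        rng = np.random.default_rng(7)
        Wq = rng.normal(size=(2, 2)).astype(np.float32)
        Wk = rng.normal(size=(2, 2)).astype(np.float32)
        state.params["Wq0"] = Tensor(Wq, requires_grad=True)
        state.params["Wk0"] = Tensor(Wk, requires_grad=True)
        state.params["bq0"].data[:] = 0
        state.params["bk0"].data[:] = 0
        sent = value_sentinels(3)
        batch = Batch(gene_tokens=np.array([[1, 3, 4]]),
                      value_bins_in=np.array([[sent["cls"], 2, 1]]),
                      pad_flags=np.zeros((1, 3), dtype=bool),
                      mask_flags=np.zeros((1, 3), dtype=bool),
                      value_targets=np.empty(0), n_bins=3)
        out = forward(batch, state, return_attentions=True)

        # independent oracle: embeddings -> layer norm -> Q,K -> softmax
        emb = (state.params["E_id"].data[batch.gene_tokens[0]]
               + state.params["E_expr"].data[batch.value_bins_in[0]])
        mu = emb.mean(axis=-1, keepdims=True)
        sd = np.sqrt(((emb - mu) ** 2).mean(axis=-1, keepdims=True) + 1e-5)
        h = (emb - mu) / sd  # ln gamma=1, beta=0 at init
        scores = (h @ Wq) @ (h @ Wk).T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        expected = e / e.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(out.attentions[0][0, 0], expected, atol=1e-5)

    def test_duplicate_cells_get_identical_outputs(self, tiny_state):
        batch = _tiny_batch(lengths=(5, 5), seed=4)
        batch.gene_tokens[1] = batch.gene_tokens[0]
        batch.value_bins_in[1] = batch.value_bins_in[0]
        out = forward(batch, tiny_state)
        np.testing.assert_array_equal(out.cell_embedding_t.data[0],
                                      out.cell_embedding_t.data[1])

    def test_cell_embedding_invariant_to_sentence_permutation(self, tiny_state):
        """No positional encoding: permuting the non-CLS tokens leaves the
        pooled embedding unchanged."""
        batch = _tiny_batch(lengths=(6,), seed=5)
        perm = np.concatenate([[0], 1 + np.random.default_rng(1).permutation(5)])
        shuffled = Batch(gene_tokens=batch.gene_tokens[:, perm],
                         value_bins_in=batch.value_bins_in[:, perm],
                         pad_flags=batch.pad_flags[:, perm],
                         mask_flags=batch.mask_flags[:, perm],
                         value_targets=batch.value_targets, n_bins=batch.n_bins)
        a = cell_embedding(forward(batch, tiny_state))
        b = cell_embedding(forward(shuffled, tiny_state))
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_value_table_frozen_at_zero_leaves_gene_only_function(self, tiny_state):
        """Ablation hook: with E_expr all zero, changing bins cannot change
        the output."""
        tiny_state.params["E_expr"].data[:] = 0
        batch = _tiny_batch(lengths=(5,), seed=6)
        other = Batch(gene_tokens=batch.gene_tokens,
                      value_bins_in=(batch.value_bins_in + 1) % 4,
                      pad_flags=batch.pad_flags, mask_flags=batch.mask_flags,
                      value_targets=batch.value_targets, n_bins=batch.n_bins)
        a = forward(batch, tiny_state).token_states.data
        b = forward(other, tiny_state).token_states.data
        np.testing.assert_array_equal(a, b)


class TestHeads:
    def test_masked_value_predictions_shape_and_order(self, tiny_state):
        batch = _tiny_batch(lengths=(5, 6), seed=7)
        batch.mask_flags[0, 2] = True
        batch.mask_flags[1, 3] = True
        out = forward(batch, tiny_state)
        preds = predict_masked_values(out, batch.mask_flags, tiny_state)
        assert preds.shape == (2,)
        scale = tiny_state.config.n_value_bins - 1
        np.testing.assert_allclose(
            preds, out.masked_value_pred.data[batch.mask_flags] * scale)

    def test_no_masked_positions_rejected(self, tiny_state):
        batch = _tiny_batch()
        out = forward(batch, tiny_state)
        with pytest.raises(ValueError, match="no masked positions"):
            predict_masked_values(out, batch.mask_flags, tiny_state)

    def test_predictions_finite_for_untrained_model(self, tiny_state):
        batch = _tiny_batch(lengths=(6, 6), seed=8)
        out = forward(batch, tiny_state)
        assert np.isfinite(out.masked_value_pred.data).all()

    def test_classifier_logits_shape_and_softmax(self, tiny_state):
        batch = _tiny_batch(lengths=(4, 5))
        out = forward(batch, tiny_state)
        logits = classify(out, tiny_state)
        assert logits.shape == (2, 5)
        from scipy.special import softmax
        np.testing.assert_allclose(softmax(logits, axis=1).sum(axis=1), 1.0,
                                   rtol=1e-6)

    def test_classifier_is_hand_computable_affine_map(self, tiny_state):
        rng = np.random.default_rng(9)
        W = rng.normal(size=(16, 5)).astype(np.float32)
        b = rng.normal(size=5).astype(np.float32)
        tiny_state.params["cls_W"] = Tensor(W, requires_grad=True)
        tiny_state.params["cls_b"] = Tensor(b, requires_grad=True)
        batch = _tiny_batch(lengths=(5,))
        out = forward(batch, tiny_state)
        np.testing.assert_allclose(classify(out, tiny_state),
                                   out.cell_embedding_t.data @ W + b, atol=1e-5)

    def test_missing_classifier_head_rejected(self):
        cfg = ModelConfig(n_gene_tokens=16, n_value_bins=5, n_layers=1,
                          n_heads=1, d_model=8, d_ff=8, n_classes=0, max_len=8)
        state = init_model(cfg, seed=0)
        out = forward(_tiny_batch(), state)
        with pytest.raises(ValueError, match="no classifier head"):
            classify(out, state)


class TestCheckpoint:
    def test_forward_bit_identical_after_save_load(self, tiny_state, tmp_path):
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(tiny_state, path)
        back = load_checkpoint(path)
        batch = _tiny_batch(lengths=(5, 6), seed=10)
        a = forward(batch, tiny_state)
        b = forward(batch, back)
        np.testing.assert_array_equal(a.token_states.data, b.token_states.data)
        np.testing.assert_array_equal(a.class_logits.data, b.class_logits.data)

    def test_vocabulary_mismatch_refused(self, tmp_path):
        vocab = build_vocabulary(["gA", "gB"])
        cfg = ModelConfig(n_gene_tokens=vocab.n_tokens, n_value_bins=5,
                          n_layers=1, n_heads=1, d_model=8, d_ff=8, max_len=8)
        state = init_model(cfg, seed=0, vocab=vocab)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(state, path)
        other = build_vocabulary(["gA", "gC"])
        with pytest.raises(ValueError, match="vocabulary hash"):
            load_checkpoint(path, vocab=other)

    def test_corrupted_checkpoint_reported(self, tmp_path):
        path = tmp_path / "ckpt.npz"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(ValueError, match="corrupted or unreadable"):
            load_checkpoint(str(path))
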