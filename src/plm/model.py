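"""The differentiable core: summed token embedding, pre-norm transformer
encoder, masked-value regression head, and cell-type classification head.

A token is the elementwise sum of a gene-identity embedding and an
expression-bin embedding; no positional term is added, so a cell sentence is
an unordered gene set and the encoder output is invariant to within-sentence
permutation. The default architecture is six layers with eight attention
heads; hidden width, feed-forward width and dropout are desk-scale defaults
surfaced in :class:`ModelConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from ._autograd import Tensor, embedding
from .io import GeneVocabulary
from .tokenize import Batch

__all__ = ["ModelConfig", "ModelState", "ForwardOutput", "init_model",
           "embed_tokens", "forward", "cell_embedding", "predict_masked_values",
           "classify", "save_checkpoint", "load_checkpoint"]

_NEG = np.float32(-1e9)  # additive key mask; exp(-1e9) underflows to exactly 0
_N_VALUE_SENTINELS = 3   # pad / cls / mask ids appended to the bin table


@dataclass
class ModelConfig:
    n_gene_tokens: int
    n_value_bins: int = 51
    n_layers: int = 6
    n_heads: int = 8
    d_model: int = 256
    d_ff: int | None = None
    n_classes: int = 0
    dropout: float = 0.0
    max_len: int = 512
    pooling: str = "cls"  # or "mean" over non-PAD token states

    def __post_init__(self):
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("n_gene_tokens", "n_value_bins", "n_layers", "n_heads",
                     "d_model", "d_ff", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pooling not in ("cls", "mean"):
            raise ValueError("pooling must be 'cls' or 'mean'")


@dataclass
class ModelState:
    """Learned parameters plus the config that shaped them.

    `params` maps names to autograd Tensors; `vocab_hash` pins the gene
    vocabulary the gene-embedding table was built for.
    """

    config: ModelConfig
    params: dict[str, Tensor]
    vocab_hash: str = ""
    classifier_labels: list[str] = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def copy(self) -> "ModelState":
        import copy as _copy

        new_params = {k: Tensor(v.data.copy(), requires_grad=True, name=k)
                      for k, v in self.params.items()}
        return ModelState(config=_copy.deepcopy(self.config), params=new_params,
                          vocab_hash=self.vocab_hash,
                          classifier_labels=list(self.classifier_labels))


@dataclass
class ForwardOutput:
    token_states: Tensor          # (B, L, d_model)
    cell_embedding_t: Tensor      # (B, d_model)
    masked_value_pred: Tensor     # (B, L) scalar regression per position
    class_logits: Tensor | None   # (B, n_classes) when classifier enabled
    attentions: list[np.ndarray] | None  # per layer, (B, n_heads, L, L)
    batch: Batch


def _param(rng: np.random.Generator, shape, std: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    std = float(np.sqrt(2.0 / (fan_in + fan_out)))
    return Tensor(rng.normal(0.0, std, size=(fan_in, fan_out)), requires_grad=True)


def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    std = float(np.sqrt(2.0 / fan_in))
    return Tensor(rng.normal(0.0, std, size=(fan_in, fan_out)), requires_grad=True)


def init_model(config: ModelConfig, seed: int = 0, vocab: GeneVocabulary | None = None,
               classifier_labels: list[str] | None = None) -> ModelState:
    rng = np.random.default_rng(seed)
    d, ff = config.d_model, config.d_ff
    p: dict[str, Tensor] = {
        "E_id": _param(rng, (config.n_gene_tokens, d)),
        "E_expr": _param(rng, (config.n_value_bins + _N_VALUE_SENTINELS, d)),
    }
    for l in range(config.n_layers):
        p[f"ln1_g{l}"] = Tensor(np.ones(d), requires_grad=True)
        p[f"ln1_b{l}"] = Tensor(np.zeros(d), requires_grad=True)
        for w in ("q", "k", "v", "o"):
            p[f"W{w}{l}"] = _glorot(rng, d, d)
            p[f"b{w}{l}"] = Tensor(np.zeros(d), requires_grad=True)
        p[f"ln2_g{l}"] = Tensor(np.ones(d), requires_grad=True)
        p[f"ln2_b{l}"] = Tensor(np.zeros(d), requires_grad=True)
        p[f"W1_{l}"] = _he(rng, d, ff)  # He for the ReLU layer
        p[f"b1_{l}"] = Tensor(np.zeros(ff), requires_grad=True)
        p[f"W2_{l}"] = _glorot(rng, ff, d)
        p[f"b2_{l}"] = Tensor(np.zeros(d), requires_grad=True)
    p["lnf_g"] = Tensor(np.ones(d), requires_grad=True)
    p["lnf_b"] = Tensor(np.zeros(d), requires_grad=True)
    # masked-value head: 2-layer perceptron emitting one scalar per position.
    # Output layer starts small with its bias at the mid-scale 0.5, the mean
    # of the normalized bin targets, so regression starts at the no-context
    # baseline and improves from there.
    p["mlm_W1"] = _he(rng, d, d)
    p["mlm_b1"] = Tensor(np.zeros(d), requires_grad=True)
    p["mlm_W2"] = _param(rng, (d, 1))
    p["mlm_b2"] = Tensor(np.full(1, 0.5), requires_grad=True)
    if config.n_classes > 0:
        p["cls_W"] = _glorot(rng, d, config.n_classes)
        p["cls_b"] = Tensor(np.zeros(config.n_classes), requires_grad=True)
    return ModelState(config=config, params=p,
                      vocab_hash=vocab.content_hash() if vocab else "",
                      classifier_labels=list(classifier_labels or []))


def embed_tokens(gene_tokens: np.ndarray, value_bins: np.ndarray,
                 state: ModelState) -> Tensor:
    """Summed token embedding: E_id[gene] + E_expr[bin], no scaling."""
    cfg = state.config
    gene_tokens = np.asarray(gene_tokens)
    value_bins = np.asarray(value_bins)
    if gene_tokens.max(initial=0) >= cfg.n_gene_tokens or gene_tokens.min(initial=0) < 0:
        raise ValueError("gene token id out of embedding-table range")
    if value_bins.max(initial=0) >= cfg.n_value_bins + _N_VALUE_SENTINELS:
        raise ValueError("value bin id out of embedding-table range")
    return embedding(state.params["E_id"], gene_tokens) + \
        embedding(state.params["E_expr"], value_bins)


def forward(batch: Batch, state: ModelState, return_attentions: bool = False,
            train: bool = False, rng: np.random.Generator | None = None) -> ForwardOutput:
    """Run the encoder. Deterministic when `train` is False (no dropout).

    PAD keys receive an additive -1e9 before softmax, so attention rows over
    valid keys sum to 1 and padding gets exactly zero mass.
    """
    cfg = state.config
    p = state.params
    B, L = batch.gene_tokens.shape
    if L > cfg.max_len:
        raise ValueError(f"batch length {L} exceeds max_len {cfg.max_len}")
    drop = cfg.dropout if train else 0.0
    if drop > 0 and rng is None:
        rng = np.random.default_rng(0)

    x = embed_tokens(batch.gene_tokens, batch.value_bins_in, state)
    key_mask = np.where(batch.pad_flags, _NEG, np.float32(0.0))[:, None, None, :]
    H, dh = cfg.n_heads, cfg.d_model // cfg.n_heads
    scale = np.float32(1.0 / np.sqrt(dh))
    attns: list[np.ndarray] | None = [] if return_attentions else None

    for l in range(cfg.n_layers):
        h = x.layer_norm(p[f"ln1_g{l}"], p[f"ln1_b{l}"])
        q = (h @ p[f"Wq{l}"] + p[f"bq{l}"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        k = (h @ p[f"Wk{l}"] + p[f"bk{l}"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        v = (h @ p[f"Wv{l}"] + p[f"bv{l}"]).reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = scores.softmax(additive_mask=key_mask)
        if attns is not None:
            attns.append(attn.data.copy())
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, cfg.d_model)
        proj = ctx @ p[f"Wo{l}"] + p[f"bo{l}"]
        if drop > 0:
            proj = proj.dropout(drop, rng)
        x = x + proj
        h2 = x.layer_norm(p[f"ln2_g{l}"], p[f"ln2_b{l}"])
        ffn = (h2 @ p[f"W1_{l}"] + p[f"b1_{l}"]).relu() @ p[f"W2_{l}"] + p[f"b2_{l}"]
        if drop > 0:
            ffn = ffn.dropout(drop, rng)
        x = x + ffn

    x = x.layer_norm(p["lnf_g"], p["lnf_b"])

    if cfg.pooling == "cls":
        cell = x[:, 0, :]
    else:
        valid = (~batch.pad_flags).astype(np.float32)[:, :, None]
        inv_len = (1.0 / valid.sum(axis=1)).astype(np.float32)
        cell = (x * Tensor(valid)).sum(axis=1) * Tensor(inv_len)

    mlm = ((x @ p["mlm_W1"] + p["mlm_b1"]).relu() @ p["mlm_W2"] + p["mlm_b2"])
    mlm = mlm.reshape(B, L)

    logits = None
    if cfg.n_classes > 0 and "cls_W" in p:
        logits = cell @ p["cls_W"] + p["cls_b"]

    return ForwardOutput(token_states=x, cell_embedding_t=cell,
                         masked_value_pred=mlm, class_logits=logits,
                         attentions=attns, batch=batch)


def cell_embedding(out: ForwardOutput) -> np.ndarray:
    """Pooled per-cell embedding (CLS token state under the default policy)."""
    return out.cell_embedding_t.data.copy()


def predict_masked_values(out: ForwardOutput, mask_flags: np.ndarray,
                          state: ModelState) -> np.ndarray:
    """Predicted bin values at masked positions, row-major flag scan order.

    The head regresses the bin value on the normalized scale bin/(n_bins-1);
    predictions are rescaled to bin units here.
    """
    mask_flags = np.asarray(mask_flags, dtype=bool)
    if not mask_flags.any():
        raise ValueError("no masked positions")
    scale = state.config.n_value_bins - 1
    return out.masked_value_pred.data[mask_flags].copy() * scale


def classify(out: ForwardOutput, state: ModelState) -> np.ndarray:
    if out.class_logits is None:
        raise ValueError("model has no classifier head")
    return out.class_logits.data.copy()


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(state: ModelState, path: str) -> None:
    meta = {"config": asdict(state.config), "vocab_hash": state.vocab_hash,
            "classifier_labels": state.classifier_labels}
    arrays = {f"param::{k}": v.data for k, v in state.params.items()}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str, vocab: GeneVocabulary | None = None) -> ModelState:
    """Load a checkpoint; refuses to load against a mismatched vocabulary."""
    try:
        with np.load(path) as fh:
            meta = json.loads(bytes(fh["__meta__"].tobytes()).decode())
            params = {k.split("::", 1)[1]: Tensor(fh[k], requires_grad=True)
                      for k in fh.files if k.startswith("param::")}
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupted or unreadable checkpoint {path!r}: {exc}") from exc
    config = ModelConfig(**meta["config"])
    if vocab is not None and meta["vocab_hash"] and \
            vocab.content_hash() != meta["vocab_hash"]:
        raise ValueError("checkpoint vocabulary hash does not match supplied vocabulary")
    return ModelState(config=config, params=params, vocab_hash=meta["vocab_hash"],
                      classifier_labels=list(meta.get("classifier_labels", [])))
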