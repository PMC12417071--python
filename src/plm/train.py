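"""Sequential pretraining: masked-value reconstruction, then cell-type
annotation, plus fine-tuning and cross-species vocabulary transfer.

Stage 1 masks 15% of the expression values per sentence and regresses the
hidden bin values under an MSE objective. Stage 2 initializes from the
stage-1 encoder and trains a classifier head under cross-entropy, jointly
with the encoder by default. Defaults follow the published recipe: batch
size 64, Adam at learning rate 1e-4. All randomness flows from
``TrainConfig.seed`` so runs reproduce end to end on one thread.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._autograd import Adam, Tensor, cross_entropy_with_logits
from .io import BinnedMatrix, GeneVocabulary
from .model import ModelConfig, ModelState, forward, init_model
from .tokenize import CellSentence, apply_mask, encode_corpus, pad_batch

__all__ = ["TrainConfig", "StageReport", "mse_masked_loss", "cross_entropy_loss",
           "pretrain_mlm", "pretrain_annotation", "fine_tune", "transfer_species",
           "evaluate_masked_mse", "evaluate_accuracy"]


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-4
    epochs: int = 3
    mask_rate: float = 0.15
    seed: int = 0
    stage: str = "mlm"  # mlm | annotate | finetune
    freeze_encoder: bool = False
    holdout_frac: float = 0.1
    log_path: str | None = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.stage not in ("mlm", "annotate", "finetune"):
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class StageReport:
    stage: str
    epoch_losses: list[float] = field(default_factory=list)
    final_loss: float = float("nan")
    steps: int = 0
    metrics: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Losses


def mse_masked_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over masked positions only."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.size == 0:
        raise ValueError("no masked positions to score")
    if pred.shape != target.shape:
        raise ValueError("pred and target lengths differ")
    return float(np.mean((pred - target) ** 2))


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-softmax probability of the true class."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= logits.shape[-1]:
        raise ValueError("label outside class range")
    logp = logits - logsumexp(logits, axis=-1, keepdims=True)
    return float(-logp[np.arange(labels.shape[0]), labels].mean())


# ---------------------------------------------------------------------------
# Internals


def _log_line(path: str | None, **payload) -> None:
    if path is None:
        return
    with open(path, "a") as fh:
        fh.write(json.dumps(payload) + "\n")


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo:lo + batch_size]


def _stratified_holdout(labels: list[str], frac: float,
                        seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seed-controlled stratified split; returns (train_idx, holdout_idx)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train, hold = [], []
    for lab in np.unique(labels):
        members = rng.permutation(np.where(labels == lab)[0])
        k = int(np.rint(frac * members.size))
        hold.append(members[:k])
        train.append(members[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(hold))


def _freeze_encoder_params(state: ModelState) -> list[Tensor]:
    """Parameters to optimize when the encoder is frozen: heads only."""
    head_keys = [k for k in state.params
                 if k.startswith("mlm_") or k.startswith("cls_")]
    return [state.params[k] for k in head_keys]


# ---------------------------------------------------------------------------
# Stage 1: masked-value pretraining


def pretrain_mlm(corpus: BinnedMatrix, vocab: GeneVocabulary, cfg: TrainConfig,
                 init: ModelState | None = None,
                 model_config: ModelConfig | None = None) -> tuple[ModelState, StageReport]:
    """Optimize the masked-value MSE objective over the corpus.

    With ``cfg.epochs == 0`` the state is returned unchanged with an empty
    trajectory. The loss trajectory is deterministic given ``cfg.seed``.
    """
    if corpus.bins.shape[0] == 0:
        raise ValueError("empty corpus")
    if init is None:
        if model_config is None:
            model_config = ModelConfig(n_gene_tokens=vocab.n_tokens,
                                       n_value_bins=corpus.config.n_bins)
        state = init_model(model_config, seed=cfg.seed, vocab=vocab)
    else:
        state = init.copy()
    report = StageReport(stage="mlm")
    if cfg.epochs == 0:
        return state, report

    sentences = encode_corpus(corpus, vocab, max_len=state.config.max_len)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(state.parameters(), lr=cfg.learning_rate)
    t0 = time.time()
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _minibatches(len(sentences), cfg.batch_size, rng):
            batch = pad_batch([sentences[i] for i in idx], state.config.max_len,
                              corpus.config.n_bins)
            batch = apply_mask(batch, rate=cfg.mask_rate,
                               seed=int(rng.integers(2 ** 31)))
            if not batch.mask_flags.any():
                continue
            out = forward(batch, state, train=True,
                          rng=np.random.default_rng(int(rng.integers(2 ** 31))))
            pred = out.masked_value_pred[batch.mask_flags]
            # regression on the normalized bin scale, bin/(n_bins-1) in (0, 1]
            scale = np.float32(1.0 / (corpus.config.n_bins - 1))
            diff = pred - Tensor(batch.value_targets.astype(np.float32) * scale)
            loss = diff.square().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            report.steps += 1
            _log_line(cfg.log_path, stage="mlm", step=report.steps, epoch=epoch,
                      loss=float(loss.data), lr=cfg.learning_rate)
        report.epoch_losses.append(float(np.mean(losses)))
    report.final_loss = report.epoch_losses[-1]
    report.metrics["elapsed_s"] = time.time() - t0
    return state, report


def evaluate_masked_mse(state: ModelState, corpus: BinnedMatrix,
                        vocab: GeneVocabulary, rate: float = 0.15,
                        seed: int = 0, batch_size: int = 64) -> dict[str, float]:
    """Masked MSE of the model vs the constant mean-bin predictor on the same
    masked positions (the natural no-context baseline), on the normalized
    bin scale the head is trained on."""
    sentences = encode_corpus(corpus, vocab, max_len=state.config.max_len)
    rng = np.random.default_rng(seed)
    scale = 1.0 / (corpus.config.n_bins - 1)
    preds, targets = [], []
    for lo in range(0, len(sentences), batch_size):
        batch = pad_batch(sentences[lo:lo + batch_size], state.config.max_len,
                          corpus.config.n_bins)
        batch = apply_mask(batch, rate=rate, seed=int(rng.integers(2 ** 31)))
        if not batch.mask_flags.any():
            continue
        out = forward(batch, state, train=False)
        preds.append(out.masked_value_pred.data[batch.mask_flags])
        targets.append(batch.value_targets.astype(np.float64) * scale)
    pred = np.concatenate(preds)
    target = np.concatenate(targets)
    baseline = mse_masked_loss(np.full_like(target, target.mean()), target)
    return {"model_mse": mse_masked_loss(pred, target),
            "baseline_mse": baseline, "n_masked": float(target.size)}


# ---------------------------------------------------------------------------
# Stage 2: cell-type annotation pretraining


def _attach_classifier(state: ModelState, labels: list[str], seed: int) -> ModelState:
    """Attach or grow the classifier head; logits of existing classes are
    preserved at initialization when the label set extends."""
    state = state.copy()
    d = state.config.d_model
    old_labels = state.classifier_labels
    new_labels = sorted(set(labels) | set(old_labels))
    rng = np.random.default_rng(seed)
    std = np.sqrt(2.0 / (d + len(new_labels)))
    W = rng.normal(0.0, std, size=(d, len(new_labels))).astype(np.float32)
    b = np.zeros(len(new_labels), dtype=np.float32)
    if old_labels and "cls_W" in state.params:
        for j, lab in enumerate(old_labels):
            jj = new_labels.index(lab)
            W[:, jj] = state.params["cls_W"].data[:, j]
            b[jj] = state.params["cls_b"].data[j]
    state.params["cls_W"] = Tensor(W, requires_grad=True)
    state.params["cls_b"] = Tensor(b, requires_grad=True)
    state.config.n_classes = len(new_labels)
    state.classifier_labels = new_labels
    return state


def _label_indices(cell_types: list[str], universe: list[str]) -> np.ndarray:
    lut = {lab: i for i, lab in enumerate(universe)}
    return np.array([lut[t] for t in cell_types], dtype=np.int64)


def evaluate_accuracy(state: ModelState, sentences: list[CellSentence],
                      labels: np.ndarray, n_bins: int,
                      batch_size: int = 64) -> float:
    correct = 0
    for lo in range(0, len(sentences), batch_size):
        batch = pad_batch(sentences[lo:lo + batch_size], state.config.max_len, n_bins)
        out = forward(batch, state, train=False)
        pred = out.class_logits.data.argmax(axis=1)
        correct += int((pred == labels[lo:lo + batch_size]).sum())
    return correct / len(sentences)


def _train_classifier(state: ModelState, corpus: BinnedMatrix,
                      vocab: GeneVocabulary, cfg: TrainConfig,
                      stage_name: str) -> tuple[ModelState, StageReport]:
    if corpus.cell_type is None:
        raise ValueError("corpus has no cell_type labels")
    if len(set(corpus.cell_type)) < 2:
        raise ValueError("need at least two cell types to train a classifier")
    state = _attach_classifier(state, sorted(set(corpus.cell_type)), cfg.seed)
    labels_all = _label_indices(corpus.cell_type, state.classifier_labels)
    sentences = encode_corpus(corpus, vocab, max_len=state.config.max_len)
    train_idx, hold_idx = _stratified_holdout(corpus.cell_type, cfg.holdout_frac,
                                              cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    params = (_freeze_encoder_params(state) if cfg.freeze_encoder
              else state.parameters())
    opt = Adam(params, lr=cfg.learning_rate)
    report = StageReport(stage=stage_name)
    n_bins = corpus.config.n_bins
    for epoch in range(cfg.epochs):
        losses = []
        for sel in _minibatches(train_idx.size, cfg.batch_size, rng):
            idx = train_idx[sel]
            batch = pad_batch([sentences[i] for i in idx], state.config.max_len,
                              n_bins)
            out = forward(batch, state, train=True,
                          rng=np.random.default_rng(int(rng.integers(2 ** 31))))
            loss = cross_entropy_with_logits(out.class_logits, labels_all[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            report.steps += 1
            _log_line(cfg.log_path, stage=stage_name, step=report.steps,
                      epoch=epoch, loss=float(loss.data), lr=cfg.learning_rate)
        report.epoch_losses.append(float(np.mean(losses)))
    report.final_loss = report.epoch_losses[-1] if report.epoch_losses else float("nan")
    if hold_idx.size:
        report.metrics["holdout_accuracy"] = evaluate_accuracy(
            state, [sentences[i] for i in hold_idx], labels_all[hold_idx], n_bins,
            cfg.batch_size)
    report.metrics["train_accuracy"] = evaluate_accuracy(
        state, [sentences[i] for i in train_idx], labels_all[train_idx], n_bins,
        cfg.batch_size)
    return state, report


def pretrain_annotation(corpus: BinnedMatrix, vocab: GeneVocabulary,
                        cfg: TrainConfig,
                        init: ModelState) -> tuple[ModelState, StageReport]:
    """Stage 2: classify cells into types, warm-started from the stage-1
    encoder, minimizing cross-entropy; held-out accuracy is recorded."""
    return _train_classifier(init, corpus, vocab, cfg, stage_name="annotate")


def fine_tune(state: ModelState, small_corpus: BinnedMatrix,
              vocab: GeneVocabulary, cfg: TrainConfig) -> tuple[ModelState, StageReport]:
    """Short supervised training on a small labeled corpus.

    New labels grow the classifier head (old-class logits preserved at init);
    the report carries before/after accuracy on the held-out slice.
    """
    overlap = [g for g in small_corpus.gene_ids if g in vocab]
    if not overlap:
        raise ValueError("corpus vocabulary is disjoint from the model vocabulary")
    if small_corpus.cell_type is None:
        raise ValueError("fine-tuning requires cell_type labels")
    # before-accuracy on the held-out slice, for classes the head already knows
    _, hold_idx = _stratified_holdout(small_corpus.cell_type, cfg.holdout_frac,
                                      cfg.seed)
    before = float("nan")
    if state.classifier_labels and hold_idx.size:
        known = [i for i in hold_idx
                 if small_corpus.cell_type[i] in state.classifier_labels]
        if known:
            sentences = encode_corpus(small_corpus, vocab,
                                      max_len=state.config.max_len)
            labels = _label_indices([small_corpus.cell_type[i] for i in known],
                                    state.classifier_labels)
            before = evaluate_accuracy(state, [sentences[i] for i in known],
                                       labels, small_corpus.config.n_bins,
                                       cfg.batch_size)
    new_state, report = _train_classifier(state, small_corpus, vocab, cfg,
                                          stage_name="finetune")
    report.metrics["holdout_accuracy_before"] = before
    return new_state, report


def transfer_species(state: ModelState, new_vocab: GeneVocabulary,
                     seed: int = 0) -> ModelState:
    """Adapt a trained model to a new species' gene vocabulary.

    The gene-identity embedding table is re-initialized at the new vocabulary
    size; the encoder, the value-bin table (bins are species-agnostic), and
    both heads are retained bit-identically.
    """
    new_state = state.copy()
    rng = np.random.default_rng(seed)
    d = state.config.d_model
    new_state.params["E_id"] = Tensor(
        rng.normal(0.0, 0.02, size=(new_vocab.n_tokens, d)), requires_grad=True)
    new_state.config.n_gene_tokens = new_vocab.n_tokens
    new_state.vocab_hash = new_vocab.content_hash()
    return new_state
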