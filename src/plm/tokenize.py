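"""Cell-sentence construction, batching with padding, and masking corruption.

A cell sentence is the cell's nonzero genes as (gene token, value bin) pairs,
ordered by bin descending (ties by gene token ascending, i.e. lexicographic
gene id), truncated to the model length, with a CLS token prepended. Only the
value channel is ever corrupted during masked-value pretraining; gene tokens
are left intact so the model predicts hidden expression levels from the
identity and expression of the remaining genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .io import BinnedMatrix, GeneVocabulary, CLS_TOKEN, PAD_TOKEN

__all__ = ["CellSentence", "Batch", "value_sentinels", "encode_cell",
           "encode_corpus", "pad_batch", "apply_mask"]


def value_sentinels(n_bins: int) -> dict[str, int]:
    """Reserved ids in the value-bin channel, placed after the real bins."""
    return {"pad": n_bins, "cls": n_bins + 1, "mask": n_bins + 2}


@dataclass
class CellSentence:
    gene_tokens: np.ndarray  # CLS first, then gene token ids
    value_bins: np.ndarray   # aligned; CLS position carries the CLS value id
    cell_id: str = ""

    def __post_init__(self):
        self.gene_tokens = np.asarray(self.gene_tokens, dtype=np.int64)
        self.value_bins = np.asarray(self.value_bins, dtype=np.int64)
        if self.gene_tokens.shape != self.value_bins.shape:
            raise ValueError("gene_tokens and value_bins must align")
        if self.gene_tokens[0] != CLS_TOKEN:
            raise ValueError("sentence must start with CLS")
        body = self.gene_tokens[1:]
        if len(set(body.tolist())) != body.size:
            raise ValueError("duplicate gene tokens in sentence")

    def __len__(self) -> int:
        return self.gene_tokens.size


@dataclass
class Batch:
    """Padded (and optionally mask-corrupted) batch of cell sentences."""

    gene_tokens: np.ndarray    # (B, L) int
    value_bins_in: np.ndarray  # (B, L) int; MASK sentinel at corrupted positions
    pad_flags: np.ndarray      # (B, L) bool
    mask_flags: np.ndarray     # (B, L) bool; all False before corruption
    value_targets: np.ndarray  # original bins at masked positions, flag scan order
    n_bins: int
    cell_ids: list[str] | None = None

    @property
    def lengths(self) -> np.ndarray:
        return (~self.pad_flags).sum(axis=1)


def encode_cell(binned_row: np.ndarray, vocab: GeneVocabulary, max_len: int = 512,
                gene_ids: list[str] | None = None, cell_id: str = "") -> CellSentence:
    """Build the sentence for one binned expression row.

    `binned_row` is aligned to `gene_ids` (or, when omitted, to the
    vocabulary's sorted gene order). Genes missing from the vocabulary are
    dropped; zero-bin genes are excluded; the remainder is sorted by
    (bin desc, token asc) and truncated to max_len - 1 before CLS.
    """
    binned_row = np.asarray(binned_row)
    if gene_ids is None:
        gene_ids = sorted(vocab.gene_to_token)
    if binned_row.size != len(gene_ids):
        raise ValueError("row length does not match gene ids")
    tokens, bins = [], []
    for g, b in zip(gene_ids, binned_row):
        if b > 0 and g in vocab:
            tokens.append(vocab.gene_to_token[g])
            bins.append(int(b))
    if not tokens:
        raise ValueError(f"cell {cell_id!r} has no nonzero vocabulary gene")
    order = sorted(range(len(tokens)), key=lambda i: (-bins[i], tokens[i]))[: max_len - 1]
    gene_seq = [CLS_TOKEN] + [tokens[i] for i in order]
    # CLS carries bin 0 here; pad_batch rewrites it with the CLS value sentinel
    bin_seq = [0] + [bins[i] for i in order]
    return CellSentence(gene_tokens=np.array(gene_seq), value_bins=np.array(bin_seq),
                        cell_id=cell_id)


def encode_corpus(b: BinnedMatrix, vocab: GeneVocabulary,
                  max_len: int = 512) -> list[CellSentence]:
    return [
        encode_cell(b.bins[i], vocab, max_len=max_len, gene_ids=b.gene_ids,
                    cell_id=b.cell_ids[i])
        for i in range(b.bins.shape[0])
    ]


def pad_batch(sentences: list[CellSentence], max_len: int, n_bins: int) -> Batch:
    """Right-pad sentences to a common length; PAD in both channels."""
    sent_ids = value_sentinels(n_bins)
    if not sentences:
        raise ValueError("empty batch")
    lengths = [len(s) for s in sentences]
    if max(lengths) > max_len:
        raise ValueError(f"sentence length {max(lengths)} exceeds max_len {max_len}")
    width = min(max_len, max(lengths))
    n = len(sentences)
    genes = np.full((n, width), PAD_TOKEN, dtype=np.int64)
    vals = np.full((n, width), sent_ids["pad"], dtype=np.int64)
    pad = np.ones((n, width), dtype=bool)
    for i, s in enumerate(sentences):
        ln = len(s)
        genes[i, :ln] = s.gene_tokens
        vals[i, :ln] = s.value_bins
        vals[i, 0] = sent_ids["cls"]
        pad[i, :ln] = False
    return Batch(gene_tokens=genes, value_bins_in=vals, pad_flags=pad,
                 mask_flags=np.zeros((n, width), dtype=bool),
                 value_targets=np.empty(0, dtype=np.int64), n_bins=n_bins,
                 cell_ids=[s.cell_id for s in sentences])


def unpad(batch: Batch) -> list[CellSentence]:
    """Inverse of pad_batch for an uncorrupted batch."""
    out = []
    sent_ids = value_sentinels(batch.n_bins)
    for i in range(batch.gene_tokens.shape[0]):
        ln = int(batch.lengths[i])
        vals = batch.value_bins_in[i, :ln].copy()
        vals[0] = 0  # CLS value sentinel back to the neutral bin
        out.append(CellSentence(
            gene_tokens=batch.gene_tokens[i, :ln].copy(), value_bins=vals,
            cell_id=batch.cell_ids[i] if batch.cell_ids else ""))
    return out


def apply_mask(batch: Batch, rate: float = 0.15, seed: int = 0) -> Batch:
    """Corrupt the value channel at exactly round(rate * n_maskable) positions
    per sentence, chosen uniformly without replacement among non-CLS, non-PAD
    positions. Gene tokens are never touched. Deterministic given `seed`.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sent_ids = value_sentinels(batch.n_bins)
    vals = batch.value_bins_in.copy()
    flags = np.zeros_like(batch.mask_flags)
    targets = []
    n, width = vals.shape
    for i in range(n):
        maskable = np.where(~batch.pad_flags[i])[0]
        maskable = maskable[maskable != 0]  # CLS excluded
        k = int(np.rint(rate * maskable.size))
        if k == 0:
            continue
        chosen = rng.choice(maskable, size=k, replace=False)
        chosen.sort()
        flags[i, chosen] = True
        targets.append(vals[i, chosen].copy())
        vals[i, chosen] = sent_ids["mask"]
    targets = np.concatenate(targets) if targets else np.empty(0, dtype=np.int64)
    return Batch(gene_tokens=batch.gene_tokens.copy(), value_bins_in=vals,
                 pad_flags=batch.pad_flags.copy(), mask_flags=flags,
                 value_targets=targets, n_bins=batch.n_bins, cell_ids=batch.cell_ids)


def save_batch(batch: Batch, path: str) -> None:
    with h5py.File(path, "w") as fh:
        for key in ("gene_tokens", "value_bins_in", "pad_flags", "mask_flags",
                    "value_targets"):
            fh.create_dataset(key, data=getattr(batch, key))
        fh.attrs["n_bins"] = batch.n_bins
        if batch.cell_ids is not None:
            fh.create_dataset("cell_ids", data=batch.cell_ids,
                              dtype=h5py.string_dtype())


def load_batch(path: str) -> Batch:
    with h5py.File(path, "r") as fh:
        cell_ids = None
        if "cell_ids" in fh:
            cell_ids = [s.decode() if isinstance(s, bytes) else str(s)
                        for s in fh["cell_ids"][:]]
        return Batch(gene_tokens=fh["gene_tokens"][:],
                     value_bins_in=fh["value_bins_in"][:],
                     pad_flags=fh["pad_flags"][:].astype(bool),
                     mask_flags=fh["mask_flags"][:].astype(bool),
                     value_targets=fh["value_targets"][:],
                     n_bins=int(fh.attrs["n_bins"]), cell_ids=cell_ids)
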