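"""Zero-shot annotation, embedding extraction, Louvain-style clustering
sweeps, and the ARI/NMI/SIL integration benchmark.

Zero-shot annotation ("reference mapping") runs the pretrained classifier on
new cells with no parameter update; genes absent from the model vocabulary
are dropped before encoding. Clustering builds a symmetric kNN graph
(Euclidean, default k = 15) over the learned cell embeddings and optimizes
modularity with a resolution parameter at each value on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.metrics import (adjusted_rand_score, normalized_mutual_info_score,
                             silhouette_score)
from sklearn.neighbors import kneighbors_graph

from .io import BinnedMatrix, GeneVocabulary
from .model import ModelState, cell_embedding, forward
from .tokenize import encode_corpus, pad_batch

__all__ = ["LabelSet", "Clustering", "MetricReport", "ConfusionMatrix",
           "zero_shot_annotate", "extract_embeddings", "louvain_sweep",
           "ari", "nmi", "silhouette", "confusion", "benchmark"]


@dataclass
class LabelSet:
    predicted: list[str]
    confidence: np.ndarray
    reference: list[str] | None = None
    universe: list[str] = field(default_factory=list)

    def to_frame(self, barcodes: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"predicted": self.predicted,
                           "confidence": self.confidence})
        if barcodes is not None:
            df.insert(0, "barcode", barcodes)
        if self.reference is not None:
            df["reference"] = self.reference
        return df


@dataclass
class Clustering:
    labels: np.ndarray  # contiguous cluster ids from 0
    resolution: float
    modularity: float


@dataclass
class MetricReport:
    resolutions: list[float]
    ari_curve: list[float]
    nmi_curve: list[float]
    sil: float
    best: dict[str, float]

    def to_dict(self) -> dict:
        return {"resolutions": self.resolutions, "ari_curve": self.ari_curve,
                "nmi_curve": self.nmi_curve, "sil": self.sil, "best": self.best}


@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # reference rows x predicted columns

    @property
    def n_cells(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_normalized(self) -> pd.DataFrame:
        arr = self.counts.to_numpy(dtype=float)
        sums = arr.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return pd.DataFrame(arr / sums, index=self.counts.index,
                            columns=self.counts.columns)

    def accuracy(self, merge_map: dict[str, str] | None = None) -> float:
        """Trace / total on the (optionally merged) label universe.

        `merge_map` collapses labels (e.g. protoxylem and metaxylem onto
        xylem) on both axes before scoring, the subtype-aware adjustment.
        """
        ref = list(self.counts.index)
        pred = list(self.counts.columns)
        arr = self.counts.to_numpy(dtype=float)
        if merge_map:
            ref = [merge_map.get(r, r) for r in ref]
            pred = [merge_map.get(p, p) for p in pred]
        total = arr.sum()
        agree = sum(arr[i, j] for i in range(len(ref)) for j in range(len(pred))
                    if ref[i] == pred[j])
        return float(agree / total) if total else float("nan")

    def to_tsv(self, path: str) -> None:
        self.counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Zero-shot annotation and embeddings


def _forward_corpus(state: ModelState, corpus: BinnedMatrix,
                    vocab: GeneVocabulary, batch_size: int = 64):
    overlap = [g for g in corpus.gene_ids if g in vocab]
    if not overlap:
        raise ValueError("no gene overlap between corpus and model vocabulary")
    sentences = encode_corpus(corpus, vocab, max_len=state.config.max_len)
    for lo in range(0, len(sentences), batch_size):
        batch = pad_batch(sentences[lo:lo + batch_size], state.config.max_len,
                          corpus.config.n_bins)
        yield forward(batch, state, train=False)


def zero_shot_annotate(state: ModelState, corpus: BinnedMatrix,
                       vocab: GeneVocabulary, batch_size: int = 64) -> LabelSet:
    """Predict each cell's type with the pretrained classifier, no training.

    Predictions are drawn from the model's training label universe; the
    confidence is the softmax probability of the argmax class.
    """
    if not state.classifier_labels:
        raise ValueError("model has no trained classifier head")
    preds, confs = [], []
    for out in _forward_corpus(state, corpus, vocab, batch_size):
        prob = softmax(out.class_logits.data.astype(np.float64), axis=1)
        idx = prob.argmax(axis=1)
        preds.extend(state.classifier_labels[i] for i in idx)
        confs.extend(prob[np.arange(idx.size), idx])
    return LabelSet(predicted=preds, confidence=np.asarray(confs),
                    reference=list(corpus.cell_type) if corpus.cell_type else None,
                    universe=list(state.classifier_labels))


def extract_embeddings(state: ModelState, corpus: BinnedMatrix,
                       vocab: GeneVocabulary, batch_size: int = 64) -> np.ndarray:
    """Pooled cell embeddings for clustering / integration benchmarking."""
    return np.vstack([cell_embedding(out)
                      for out in _forward_corpus(state, corpus, vocab, batch_size)])


# ---------------------------------------------------------------------------
# Clustering


def _knn_igraph(embeddings: np.ndarray, n_neighbors: int) -> ig.Graph:
    n = embeddings.shape[0]
    if n < n_neighbors + 1:
        raise ValueError("fewer cells than n_neighbors + 1")
    adj = kneighbors_graph(embeddings, n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()  # symmetrize: union of directed kNN edges
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    return ig.Graph(n=n, edges=edges)


def louvain_sweep(embeddings: np.ndarray, resolutions, n_neighbors: int = 15,
                  seed: int = 0) -> list[Clustering]:
    """Modularity community detection on the kNN graph at each resolution.

    Deterministic given `seed`; cluster ids are contiguous from 0.
    """
    graph = _knn_igraph(np.asarray(embeddings, dtype=np.float64), n_neighbors)
    out = []
    for res in resolutions:
        if res <= 0:
            raise ValueError("resolution must be positive")
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(res), seed=int(seed))
        labels = np.asarray(part.membership, dtype=np.int64)
        # contiguous relabel in order of first appearance
        _, labels = np.unique(labels, return_inverse=True)
        out.append(Clustering(labels=labels, resolution=float(res),
                              modularity=float(graph.modularity(part.membership))))
    return out


# ---------------------------------------------------------------------------
# Agreement metrics (conventions: NMI normalized by the arithmetic mean of the
# entropies; silhouette on Euclidean distances, singleton clusters contribute 0)


def _check_lengths(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings have different lengths")
    return a, b


def ari(a, b) -> float:
    """Permutation-model adjusted Rand index."""
    a, b = _check_lengths(a, b)
    return float(adjusted_rand_score(a, b))


def nmi(a, b) -> float:
    """Mutual information normalized by the arithmetic mean of entropies;
    0 when either labeling is constant (unless both are and agree)."""
    a, b = _check_lengths(a, b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def silhouette(embeddings: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(silhouette_score(np.asarray(embeddings, dtype=np.float64),
                                  labels, metric="euclidean"))


def confusion(labels: LabelSet) -> ConfusionMatrix:
    """Reference x predicted contingency table with named axes."""
    if labels.reference is None:
        raise ValueError("confusion matrix requires reference labels")
    ref = pd.Series(labels.reference, name="reference")
    pred = pd.Series(labels.predicted, name="predicted")
    table = pd.crosstab(ref, pred)
    return ConfusionMatrix(counts=table)


def benchmark(embeddings: np.ndarray, reference_labels, resolutions=None,
              n_neighbors: int = 15, seed: int = 0) -> MetricReport:
    """Integration benchmark: cluster at each resolution, score ARI/NMI
    against the reference labels, and compute the silhouette of the reference
    types over the embedding; reports curves plus per-metric maxima."""
    if resolutions is None:
        resolutions = [round(0.1 * i, 1) for i in range(1, 16)]  # 0.1 .. 1.5
    reference_labels = np.asarray(reference_labels)
    clusterings = louvain_sweep(embeddings, resolutions, n_neighbors, seed)
    ari_curve = [ari(reference_labels, c.labels) for c in clusterings]
    nmi_curve = [nmi(reference_labels, c.labels) for c in clusterings]
    sil = silhouette(embeddings, reference_labels)
    return MetricReport(resolutions=[float(r) for r in resolutions],
                        ari_curve=ari_curve, nmi_curve=nmi_curve, sil=sil,
                        best={"ari": max(ari_curve), "nmi": max(nmi_curve),
                              "sil": sil})
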