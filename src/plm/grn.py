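"""Per-cell gene networks from attention maps.

The encoder's self-attention for one cell is read out as a gene-gene
relatedness matrix: heads of the chosen layer(s) are averaged, the CLS row
and column are removed, the matrix is symmetrized as (A + A^T)/2, and the
off-diagonal entries are min-max normalized to [0, 1]. Hubs are the genes
with the largest total normalized attention; networks grow breadth-first
from the hubs, attaching each frontier gene's top-k partners per level up to
a depth limit (defaults: k = 5 at depth 2; the reduced direct-interaction
view uses k = 2 at depth 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import ModelState, forward
from .tokenize import CellSentence, pad_batch

__all__ = ["AttentionMatrix", "GeneNetwork", "cell_attention_matrix",
           "select_hubs", "expand_network", "reduce_subgraph",
           "export_network", "import_network", "mean_pair_attention",
           "module_recovery_auc"]


@dataclass
class AttentionMatrix:
    genes: list[str]
    scores: np.ndarray  # square, entries in [0, 1], diagonal unused
    cell_id: str = ""
    provenance: str = "last_layer_mean_heads"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n = len(self.genes)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square over genes")
        off = ~np.eye(n, dtype=bool)
        if n > 1 and (self.scores[off].min() < -1e-12 or
                      self.scores[off].max() > 1 + 1e-12):
            raise ValueError("normalized scores must lie in [0, 1]")


@dataclass
class GeneNetwork:
    hubs: list[str]
    nodes: dict[str, str]  # gene -> role ("hub" | "neighbor")
    edges: list[tuple[str, str, float, int]]  # source, target, weight, level
    k: int
    depth: int
    cell_id: str = ""
    field_names: tuple = field(default=("source", "target", "weight", "level"))


def _normalize(sym: np.ndarray) -> np.ndarray:
    """Min-max scale the off-diagonal of a symmetric matrix to [0, 1];
    a constant matrix maps to all zeros."""
    n = sym.shape[0]
    out = np.zeros_like(sym)
    if n < 2:
        return out
    off = ~np.eye(n, dtype=bool)
    lo, hi = sym[off].min(), sym[off].max()
    if hi > lo:
        out[off] = (sym[off] - lo) / (hi - lo)
    return out


def cell_attention_matrix(state: ModelState, sentence: CellSentence,
                          n_bins: int, vocab=None,
                          aggregation: str = "last_layer_mean_heads") -> AttentionMatrix:
    """Gene-gene normalized attention for one cell.

    Head-averaged attention of the final layer (or the mean over all layers),
    CLS removed, symmetrized, then min-max normalized to [0, 1]. Gene names
    come from `vocab` when given, else token ids are used as names.
    """
    if len(sentence) < 3:  # CLS + at least two genes
        raise ValueError("sentence must contain at least two genes")
    if aggregation not in ("last_layer_mean_heads", "mean_all"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    batch = pad_batch([sentence], state.config.max_len, n_bins)
    out = forward(batch, state, return_attentions=True, train=False)
    per_layer = [a[0].mean(axis=0) for a in out.attentions]  # head-averaged, (L, L)
    raw = per_layer[-1] if aggregation == "last_layer_mean_heads" \
        else np.mean(per_layer, axis=0)
    raw = raw[1:, 1:]  # drop CLS row/column
    sym = (raw.astype(np.float64) + raw.T) / 2.0
    tokens = sentence.gene_tokens[1:].tolist()
    if vocab is not None:
        lut = vocab.token_to_gene
        genes = [lut.get(t, str(t)) for t in tokens]
    else:
        genes = [str(t) for t in tokens]
    return AttentionMatrix(genes=genes, scores=_normalize(sym),
                           cell_id=sentence.cell_id, provenance=aggregation)


def attention_from_matrix(genes: list[str], raw: np.ndarray,
                          cell_id: str = "", provenance: str = "external") -> AttentionMatrix:
    """Build an AttentionMatrix from a raw (not yet normalized) square matrix:
    symmetrize then min-max normalize. Scale-invariant: multiplying `raw` by
    any positive constant gives the same result."""
    raw = np.asarray(raw, dtype=np.float64)
    sym = (raw + raw.T) / 2.0
    return AttentionMatrix(genes=list(genes), scores=_normalize(sym),
                           cell_id=cell_id, provenance=provenance)


def select_hubs(att: AttentionMatrix, n_hubs: int) -> list[str]:
    """Top genes by total normalized attention (row sum, diagonal excluded);
    ties break toward the lexicographically smaller gene id."""
    if n_hubs <= 0:
        raise ValueError("n_hubs must be positive")
    n = len(att.genes)
    if n_hubs > n:
        raise ValueError("n_hubs exceeds number of genes")
    off = ~np.eye(n, dtype=bool)
    sums = (att.scores * off).sum(axis=1)
    order = sorted(range(n), key=lambda i: (-sums[i], att.genes[i]))
    return [att.genes[i] for i in order[:n_hubs]]


def _top_partners(att: AttentionMatrix, gene: str, k: int) -> list[tuple[str, float]]:
    i = att.genes.index(gene)
    pairs = [(att.genes[j], float(att.scores[i, j]))
             for j in range(len(att.genes)) if j != i]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs[:k]


def expand_network(att: AttentionMatrix, hubs: list[str], k: int = 5,
                   depth: int = 2) -> GeneNetwork:
    """Breadth-first expansion from the hubs.

    Level 1 attaches each hub's k highest-score partners; level l+1 attaches
    each level-l node's k highest-score partners not already in the network.
    Deterministic: ties break score-descending then gene-id ascending.
    """
    if k < 1 or depth < 0:
        raise ValueError("k must be >= 1 and depth >= 0")
    unknown = [h for h in hubs if h not in att.genes]
    if unknown:
        raise ValueError(f"unknown hub gene(s): {unknown}")
    nodes = {h: "hub" for h in hubs}
    edges: list[tuple[str, str, float, int]] = []
    frontier = list(hubs)
    for level in range(1, depth + 1):
        next_frontier = []
        for gene in frontier:
            for partner, weight in _top_partners(att, gene, k):
                if partner not in nodes:
                    nodes[partner] = "neighbor"
                    next_frontier.append(partner)
                if not any(e[0] == gene and e[1] == partner or
                           e[0] == partner and e[1] == gene for e in edges):
                    edges.append((gene, partner, weight, level))
        frontier = next_frontier
    return GeneNetwork(hubs=list(hubs), nodes=nodes, edges=edges, k=k,
                       depth=depth, cell_id=att.cell_id)


def reduce_subgraph(att: AttentionMatrix, net: GeneNetwork, k: int = 2,
                    depth: int = 1) -> GeneNetwork:
    """Re-expand from the same hubs with smaller k and depth; the result is a
    subgraph of the original network."""
    if k > net.k or depth > net.depth:
        raise ValueError("reduced k/depth must not exceed the originals")
    return expand_network(att, net.hubs, k=k, depth=depth)


def mean_pair_attention(state: ModelState, sentences: list[CellSentence],
                        n_bins: int, vocab,
                        aggregation: str = "last_layer_mean_heads"):
    """Average normalized attention per gene pair across cells.

    Each cell contributes its sentence's gene-gene normalized attention;
    pairs are averaged over the cells in which both genes appear. Returns
    (gene id list, mean score matrix with NaN for never-co-observed pairs).
    """
    genes = sorted(vocab.gene_to_token)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for sent in sentences:
        att = cell_attention_matrix(state, sent, n_bins, vocab=vocab,
                                    aggregation=aggregation)
        rows = np.array([index[g] for g in att.genes])
        total[np.ix_(rows, rows)] += att.scores
        count[np.ix_(rows, rows)] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return genes, mean


def masked_pair_attention(state: ModelState, sentences: list[CellSentence],
                          n_bins: int, vocab, mask_rate: float = 0.15,
                          rounds: int = 6, seed: int = 0,
                          aggregation: str = "last_layer_mean_heads"):
    """Attention cast by value-masked genes, averaged per gene pair.

    Masked-value training shapes attention exactly where a value is hidden:
    a masked gene must look at informative partners to reconstruct its bin.
    This readout repeats the training-time corruption `rounds` times per
    cell and accumulates the (masked query gene -> key gene) attention rows
    of the chosen layer(s), head-averaged. The accumulated matrix is
    symmetrized and min-max normalized to [0, 1] like the per-cell readout.
    Returns (gene id list, normalized mean matrix, NaN where never observed).
    """
    from .tokenize import apply_mask, pad_batch as _pad

    genes = sorted(vocab.gene_to_token)
    index = {vocab.gene_to_token[g]: i for i, g in enumerate(genes)}
    n = len(genes)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    layer_sel = (lambda ats: ats[-1]) if aggregation == "last_layer_mean_heads" \
        else (lambda ats: np.mean(ats, axis=0))
    if aggregation not in ("last_layer_mean_heads", "mean_all"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    for _ in range(rounds):
        for lo in range(0, len(sentences), 64):
            batch = _pad(sentences[lo:lo + 64], state.config.max_len, n_bins)
            masked = apply_mask(batch, rate=mask_rate,
                                seed=int(rng.integers(2 ** 31)))
            if not masked.mask_flags.any():
                continue
            out = forward(masked, state, return_attentions=True)
            att = layer_sel([a.mean(axis=1) for a in out.attentions])  # (B,L,L)
            for bi in range(att.shape[0]):
                valid = ~masked.pad_flags[bi]
                key_pos = np.where(valid)[0][1:]  # CLS column excluded
                query_pos = np.where(masked.mask_flags[bi])[0]
                if query_pos.size == 0:
                    continue
                toks = masked.gene_tokens[bi]
                qi = np.array([index[t] for t in toks[query_pos]])
                ki = np.array([index[t] for t in toks[key_pos]])
                total[np.ix_(qi, ki)] += att[bi][np.ix_(query_pos, key_pos)]
                count[np.ix_(qi, ki)] += 1
    directed = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    # nan-aware symmetrization, then min-max over observed off-diagonals
    with np.errstate(invalid="ignore"):
        sym = np.nanmean(np.stack([directed, directed.T]), axis=0)
    off = ~np.eye(n, dtype=bool)
    obs = off & ~np.isnan(sym)
    out_m = np.full((n, n), np.nan)
    if obs.any():
        lo_v, hi_v = np.nanmin(sym[obs]), np.nanmax(sym[obs])
        if hi_v > lo_v:
            out_m[obs] = (sym[obs] - lo_v) / (hi_v - lo_v)
        else:
            out_m[obs] = 0.0
    return genes, out_m


def module_recovery_auc(genes: list[str], mean_scores: np.ndarray,
                        module_genes: list[str]) -> dict[str, float]:
    """How well mean pairwise attention separates a planted co-regulated
    module: rank-AUC (Mann-Whitney) of within-module pairs vs all other
    pairs, plus the two group means."""
    from scipy.stats import mannwhitneyu

    in_module = np.array([g in set(module_genes) for g in genes])
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    scores = mean_scores[iu]
    within = in_module[iu[0]] & in_module[iu[1]]
    ok = ~np.isnan(scores)
    w = scores[ok & within]
    b = scores[ok & ~within]
    if w.size == 0 or b.size == 0:
        raise ValueError("no scored pairs in one of the groups")
    u_stat = mannwhitneyu(w, b, alternative="greater").statistic
    return {"auc": float(u_stat / (w.size * b.size)),
            "within_mean": float(w.mean()), "between_mean": float(b.mean())}


def export_network(net: GeneNetwork, path: str, fmt: str = "edge_tsv") -> None:
    if fmt == "edge_tsv":
        df = pd.DataFrame(net.edges, columns=["source", "target", "weight", "level"])
        with open(path, "w") as fh:
            fh.write(f"# hubs={','.join(net.hubs)}\tk={net.k}\tdepth={net.depth}"
                     f"\tcell={net.cell_id}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif fmt == "graphml":
        g = nx.Graph(hubs=",".join(net.hubs), k=net.k, depth=net.depth,
                     cell_id=net.cell_id)
        for gene, role in net.nodes.items():
            g.add_node(gene, role=role)
        for s, t, w, lvl in net.edges:
            # undirected graph; keep the BFS parent in an attribute so the
            # expansion orientation survives the round-trip
            g.add_edge(s, t, weight=float(w), level=int(lvl), parent=s)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_network(path: str, fmt: str = "edge_tsv") -> GeneNetwork:
    if fmt == "edge_tsv":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").rstrip("\n")
            meta = dict(item.split("=", 1) for item in header.split("\t"))
            hubs = meta["hubs"].split(",") if meta["hubs"] else []
            df = pd.read_csv(fh, sep="\t",
                             dtype={"source": str, "target": str})
        edges = [(str(r.source), str(r.target), float(r.weight), int(r.level))
                 for r in df.itertuples()]
        nodes = {h: "hub" for h in hubs}
        for s, t, _, _ in edges:
            nodes.setdefault(s, "neighbor")
            nodes.setdefault(t, "neighbor")
        return GeneNetwork(hubs=hubs, nodes=nodes, edges=edges,
                           k=int(meta["k"]), depth=int(meta["depth"]),
                           cell_id=meta.get("cell", ""))
    if fmt == "graphml":
        g = nx.read_graphml(path)
        hubs = g.graph["hubs"].split(",") if g.graph.get("hubs") else []
        nodes = {str(n): str(d.get("role", "neighbor")) for n, d in g.nodes(data=True)}
        edges = []
        for s, t, d in g.edges(data=True):
            if str(d.get("parent", s)) != str(s):
                s, t = t, s
            edges.append((str(s), str(t), float(d["weight"]), int(d["level"])))
        return GeneNetwork(hubs=hubs, nodes=nodes, edges=edges,
                           k=int(g.graph["k"]), depth=int(g.graph["depth"]),
                           cell_id=str(g.graph.get("cell_id", "")))
    raise ValueError(f"unknown format {fmt!r}")
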