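"""Gene-program discovery from the learned gene-token embedding table.

Programs are communities in a kNN graph over the context-free gene
embeddings (the gene-identity table rows), found by modularity optimization;
the number of programs is emergent, not fixed. Program activity per cell
type is the mean over program genes of the z-scored (across types) mean
log-normalized expression — membership comes from the embeddings, activation
from the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import louvain_sweep
from .io import ExpressionMatrix, GeneVocabulary, N_SPECIAL_TOKENS
from .model import ModelState

__all__ = ["GeneEmbeddingTable", "ProgramAssignment", "ProgramActivity",
           "extract_gene_embeddings", "cluster_programs", "program_activity"]


@dataclass
class GeneEmbeddingTable:
    gene_ids: list[str]
    embeddings: np.ndarray  # gene x d_model, vocabulary order

    def __post_init__(self):
        if len(self.gene_ids) != self.embeddings.shape[0]:
            raise ValueError("gene ids and embedding rows misaligned")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("non-finite gene embeddings")


@dataclass
class ProgramAssignment:
    gene_ids: list[str]
    program: np.ndarray  # one program id per gene, contiguous from 0

    @property
    def n_programs(self) -> int:
        return int(self.program.max()) + 1 if self.program.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids, "program": self.program})

    def members(self, program_id: int) -> list[str]:
        return [g for g, p in zip(self.gene_ids, self.program) if p == program_id]


@dataclass
class ProgramActivity:
    values: pd.DataFrame  # program rows x cell-type columns


def extract_gene_embeddings(state: ModelState,
                            vocab: GeneVocabulary) -> GeneEmbeddingTable:
    """The gene-identity embedding rows for real genes (special ids dropped)."""
    table = state.params["E_id"].data
    genes = sorted(vocab.gene_to_token)
    rows = np.array([vocab.gene_to_token[g] for g in genes])
    if rows.size and rows.max() >= table.shape[0]:
        raise ValueError("vocabulary does not match the embedding table")
    assert rows.min(initial=N_SPECIAL_TOKENS) >= N_SPECIAL_TOKENS
    return GeneEmbeddingTable(gene_ids=genes, embeddings=table[rows].copy())


def cluster_programs(table: GeneEmbeddingTable, n_neighbors: int = 15,
                     resolution: float = 1.0, seed: int = 0) -> ProgramAssignment:
    """Community detection over the gene-embedding kNN graph; the program
    count is emergent from the resolution."""
    if table.embeddings.shape[0] < n_neighbors + 1:
        raise ValueError("fewer genes than n_neighbors + 1")
    clustering = louvain_sweep(table.embeddings, [resolution],
                               n_neighbors=n_neighbors, seed=seed)[0]
    return ProgramAssignment(gene_ids=list(table.gene_ids),
                             program=clustering.labels)


def program_activity(assign: ProgramAssignment,
                     m: ExpressionMatrix) -> ProgramActivity:
    """Program x cell-type activity matrix.

    Per gene: mean expression per type, z-scored across types (genes constant
    across types contribute 0); per program and type: mean over member genes.
    Expects log-normalized expression with cell_type labels.
    """
    if m.cell_type is None:
        raise ValueError("expression matrix has no cell_type labels")
    shared = [g for g in assign.gene_ids if g in set(m.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between assignment and matrix")
    sub = m.subset_genes(shared)
    types = sorted(set(m.cell_type))
    type_mean = np.vstack([
        sub.counts[np.asarray(m.cell_type) == t].mean(axis=0) for t in types
    ])  # type x gene
    mu = type_mean.mean(axis=0)
    sd = type_mean.std(axis=0)
    z = np.where(sd > 0, (type_mean - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    prog_of = dict(zip(assign.gene_ids, assign.program))
    n_prog = assign.n_programs
    values = np.zeros((n_prog, len(types)))
    for p in range(n_prog):
        cols = [j for j, g in enumerate(shared) if prog_of[g] == p]
        if cols:
            values[p] = z[:, cols].mean(axis=1)
    df = pd.DataFrame(values, columns=types,
                      index=[f"program{p}" for p in range(n_prog)])
    return ProgramActivity(values=df)
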