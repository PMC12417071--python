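"""Expression-matrix I/O, preprocessing, value binning, and the gene vocabulary.

Cells are always rows. Readers accept 10x-style Matrix Market directories
(matrix.mtx + features.tsv + barcodes.tsv, optionally gzipped) and dense
CSV/TSV; an on-disk genes-as-rows orientation is handled via a flag.

Preprocessing is the common convention for transformer tokenizers of
single-cell data: per-cell total-count normalization, log1p, dispersion-ranked
highly-variable-gene selection, then per-cell quantile binning of the nonzero
values with a reserved zero bin.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "GeneVocabulary",
    "BinConfig",
    "BinnedMatrix",
    "read_expression",
    "write_expression",
    "read_annotations",
    "normalize_log",
    "select_hvgs",
    "bin_expression",
    "build_vocabulary",
    "save_binned_corpus",
    "load_binned_corpus",
]

# Reserved gene-token ids (value-bin sentinels live in tokenize.py).
PAD_TOKEN = 0
CLS_TOKEN = 1
MASK_TOKEN = 2
N_SPECIAL_TOKENS = 3
SPECIAL_TOKEN_NAMES = {"<pad>": PAD_TOKEN, "<cls>": CLS_TOKEN, "<mask>": MASK_TOKEN}


@dataclass
class ExpressionMatrix:
    """Dense cell×gene matrix with identifiers and per-cell labels.

    `counts` holds raw counts on input and normalized values after
    :func:`normalize_log`; entries are never negative.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    batch: list[str] | None = None
    cell_type: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix columns")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if np.any(self.counts < 0):
            raise ValueError("negative entries in expression matrix")
        for name in ("batch", "cell_type"):
            lab = getattr(self, name)
            if lab is not None:
                lab = list(map(str, lab))
                if len(lab) != n_cells:
                    raise ValueError(f"{name} length does not match number of cells")
                setattr(self, name, lab)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in gene_ids]
        return replace(self, counts=self.counts[:, cols], gene_ids=list(gene_ids))

    def subset_cells(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            counts=self.counts[rows],
            cell_ids=[self.cell_ids[i] for i in rows],
            gene_ids=list(self.gene_ids),
            batch=None if self.batch is None else [self.batch[i] for i in rows],
            cell_type=None if self.cell_type is None else [self.cell_type[i] for i in rows],
        )


@dataclass
class BinConfig:
    """Expression-bin configuration; `n_bins` includes the reserved zero bin."""

    n_bins: int = 51
    scheme: str = "per_cell_quantile"

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.scheme != "per_cell_quantile":
            raise ValueError(f"unknown binning scheme: {self.scheme}")


@dataclass
class BinnedMatrix:
    """Integer cell×gene bin matrix; bin 0 iff the underlying value is zero."""

    bins: np.ndarray
    config: BinConfig
    cell_ids: list[str]
    gene_ids: list[str]
    batch: list[str] | None = None
    cell_type: list[str] | None = None

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=np.int64)
        if self.bins.min(initial=0) < 0 or self.bins.max(initial=0) > self.config.n_bins - 1:
            raise ValueError("bin values outside [0, n_bins-1]")


@dataclass
class GeneVocabulary:
    """Deterministic gene → token mapping (sorted ids after the 3 special ids)."""

    gene_to_token: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, gene_ids) -> "GeneVocabulary":
        genes = list(map(str, gene_ids))
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene ids in vocabulary input")
        mapping = {g: N_SPECIAL_TOKENS + i for i, g in enumerate(sorted(genes))}
        return cls(gene_to_token=mapping)

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_token)

    @property
    def n_tokens(self) -> int:
        """Total token-table size, special ids included."""
        return N_SPECIAL_TOKENS + len(self.gene_to_token)

    @property
    def token_to_gene(self) -> dict[int, str]:
        return {t: g for g, t in self.gene_to_token.items()}

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_to_token

    def content_hash(self) -> str:
        import hashlib

        payload = json.dumps(sorted(self.gene_to_token.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save_json(self, path: str) -> None:
        obj = {"special_tokens": SPECIAL_TOKEN_NAMES,
               "gene_to_token": dict(sorted(self.gene_to_token.items()))}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=False)

    @classmethod
    def load_json(cls, path: str) -> "GeneVocabulary":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(gene_to_token={str(k): int(v) for k, v in obj["gene_to_token"].items()})

    def save_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene\ttoken\n")
            for g, t in sorted(self.gene_to_token.items()):
                fh.write(f"{g}\t{t}\n")

    @classmethod
    def load_tsv(cls, path: str) -> "GeneVocabulary":
        df = pd.read_csv(path, sep="\t")
        return cls(gene_to_token=dict(zip(df["gene"].astype(str), df["token"].astype(int))))


def build_vocabulary(gene_ids) -> GeneVocabulary:
    """Build the deterministic vocabulary: sorted gene ids after the special ids."""
    return GeneVocabulary.from_genes(gene_ids)


# ---------------------------------------------------------------------------
# Readers / writers


def _open_maybe_gz(path: str):
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def _find_file(directory: str, stems: list[str]) -> str:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = os.path.join(directory, stem + suffix)
            if os.path.exists(p):
                return p
    raise FileNotFoundError(f"none of {stems} found in {directory}")


def read_expression(path: str, fmt: str = "mtx_dir",
                    genes_as_rows: bool | None = None) -> ExpressionMatrix:
    """Read a cell×gene matrix from an MTX directory or a dense CSV/TSV.

    ``genes_as_rows`` declares the on-disk orientation. Default: True for
    MTX directories (the 10x convention stores genes as rows) and False for
    dense tables.
    """
    if fmt == "mtx_dir":
        if genes_as_rows is None:
            genes_as_rows = True
        mtx = _find_file(path, ["matrix.mtx"])
        feat = _find_file(path, ["features.tsv", "genes.tsv"])
        barc = _find_file(path, ["barcodes.tsv"])
        mat = scipy.io.mmread(mtx)
        mat = scipy.sparse.coo_matrix(mat).toarray().astype(np.float64)
        with _open_maybe_gz(feat) as fh:
            genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with _open_maybe_gz(barc) as fh:
            cells = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        if genes_as_rows:
            mat = mat.T
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} inconsistent with {len(cells)} barcodes "
                f"and {len(genes)} features")
        return ExpressionMatrix(counts=mat, cell_ids=cells, gene_ids=genes)
    if fmt in ("csv", "tsv"):
        if genes_as_rows is None:
            genes_as_rows = False
        sep = "," if fmt == "csv" else "\t"
        with _open_maybe_gz(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate gene_ids in header")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if genes_as_rows:
            df = df.T
        return ExpressionMatrix(counts=df.to_numpy(dtype=np.float64),
                                cell_ids=[str(c) for c in df.index],
                                gene_ids=[str(g) for g in df.columns])
    raise ValueError(f"unknown format: {fmt}")


def write_expression(m: ExpressionMatrix, path: str) -> None:
    """Write an MTX directory (genes-as-rows, 10x layout) plus an annotation TSV
    when labels are present."""
    os.makedirs(path, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(m.counts.T)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sparse)
    with open(os.path.join(path, "features.tsv"), "w") as fh:
        fh.write("\n".join(m.gene_ids) + "\n")
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(m.cell_ids) + "\n")
    if m.batch is not None or m.cell_type is not None:
        df = pd.DataFrame({
            "barcode": m.cell_ids,
            "cell_type": m.cell_type if m.cell_type is not None else [""] * m.n_cells,
            "batch": m.batch if m.batch is not None else [""] * m.n_cells,
        })
        df.to_csv(os.path.join(path, "annotations.tsv"), sep="\t", index=False)


def read_annotations(path: str) -> pd.DataFrame:
    """Read a barcode/cell_type/batch TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "cell_type", "batch"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    return df


def attach_annotations(m: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    ann = ann.set_index("barcode")
    missing = [c for c in m.cell_ids if c not in ann.index]
    if missing:
        raise ValueError(f"annotations missing for {len(missing)} barcodes")
    return replace(m,
                   cell_type=[str(ann.loc[c, "cell_type"]) for c in m.cell_ids],
                   batch=[str(ann.loc[c, "batch"]) for c in m.cell_ids])


# ---------------------------------------------------------------------------
# Preprocessing


def normalize_log(m: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to `target_sum` total counts, then apply log1p.

    Zeros stay zero and within-cell ranking is preserved (monotone transform).
    """
    totals = m.counts.sum(axis=1)
    zero_cells = np.where(totals == 0)[0]
    if zero_cells.size:
        raise ValueError(f"cell(s) with zero total counts: {zero_cells[:5].tolist()}")
    scaled = m.counts * (target_sum / totals)[:, None]
    return replace(m, counts=np.log1p(scaled))


def select_hvgs(m: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the `n_top` genes with the highest dispersion (variance/mean).

    Computed on the values as given (log-normalized recommended). Genes with
    zero mean get dispersion 0. Ties break toward the lexicographically
    smaller gene id; returned genes are in rank order.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > m.n_genes:
        raise ValueError("n_top exceeds number of genes")
    mean = m.counts.mean(axis=0)
    var = m.counts.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = sorted(range(m.n_genes), key=lambda j: (-disp[j], m.gene_ids[j]))
    keep = [m.gene_ids[j] for j in order[:n_top]]
    return m.subset_genes(keep)


def bin_expression(m: ExpressionMatrix, cfg: BinConfig | None = None) -> BinnedMatrix:
    """Per-cell quantile binning with a reserved zero bin.

    Zeros map to bin 0. Nonzero values are ranked within the cell (average
    ranks for ties) and binned as ceil(r * (n_bins-1)) with r = rank / n_nonzero,
    so bins run 1..n_bins-1 and are invariant to any strictly monotone
    per-cell transform.
    """
    cfg = cfg or BinConfig()
    if np.any(m.counts < 0):
        raise ValueError("bin_expression requires nonnegative values")
    bins = np.zeros(m.counts.shape, dtype=np.int64)
    top = cfg.n_bins - 1
    for i in range(m.n_cells):
        row = m.counts[i]
        nz = np.nonzero(row)[0]
        if nz.size == 0:
            continue
        r = rankdata(row[nz], method="average") / nz.size
        bins[i, nz] = np.ceil(r * top).astype(np.int64)
    return BinnedMatrix(bins=bins, config=cfg, cell_ids=list(m.cell_ids),
                        gene_ids=list(m.gene_ids), batch=m.batch, cell_type=m.cell_type)


# ---------------------------------------------------------------------------
# Binned-corpus container (HDF5)


def save_binned_corpus(b: BinnedMatrix, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("bins", data=b.bins, compression="gzip")
        fh.attrs["n_bins"] = b.config.n_bins
        fh.attrs["scheme"] = b.config.scheme
        str_dt = h5py.string_dtype()
        fh.create_dataset("cell_ids", data=b.cell_ids, dtype=str_dt)
        fh.create_dataset("gene_ids", data=b.gene_ids, dtype=str_dt)
        if b.batch is not None:
            fh.create_dataset("batch", data=b.batch, dtype=str_dt)
        if b.cell_type is not None:
            fh.create_dataset("cell_type", data=b.cell_type, dtype=str_dt)


def load_binned_corpus(path: str) -> BinnedMatrix:
    with h5py.File(path, "r") as fh:
        def strs(key):
            if key not in fh:
                return None
            return [s.decode() if isinstance(s, bytes) else str(s) for s in fh[key][:]]

        return BinnedMatrix(
            bins=fh["bins"][:],
            config=BinConfig(n_bins=int(fh.attrs["n_bins"]), scheme=str(fh.attrs["scheme"])),
            cell_ids=strs("cell_ids"),
            gene_ids=strs("gene_ids"),
            batch=strs("batch"),
            cell_type=strs("cell_type"),
        )
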