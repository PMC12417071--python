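"""Reproducible synthetic scRNA-seq corpora with known ground truth.

The generative model, per cell i and gene j with latent rate mu_ij:

  log mu_ij = log(base_j) + [j is a marker of type(i)] * log(marker_fold)
              + batch_effect[batch(i), j]
              + module term (co-regulated genes only)

  base_j          ~ LogNormal, rescaled so expected library size is
                    library_size_mean
  batch_effect    ~ Normal(0, batch_scale_sd^2) per (batch, gene)
  module term     = tau * (sqrt(rho) * z_i + sqrt(1-rho) * eta_ij) - tau^2/2,
                    z_i a shared per-cell factor, eta_ij independent noise,
                    so module genes' latent log-rates correlate at exactly rho
  counts_ij       ~ NegativeBinomial(mean mu_ij * s_i, dispersion theta),
                    sampled as Poisson(Gamma(theta, mu/theta))

Every draw flows from `seed`; the corpus carries its marker and module maps
so downstream recovery tests have exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

__all__ = ["SynthConfig", "SynthCorpus", "Module", "generate_corpus",
           "truth_labels", "split", "calibration_config"]


@dataclass
class Module:
    """A planted co-regulated gene set with target log-rate correlation rho."""

    genes: list[str]
    rho: float = 0.8
    tau: float = 1.0  # log-sd of the co-activation factor

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


@dataclass
class SynthConfig:
    n_cells: int = 2000
    n_genes: int = 500
    n_types: int = 4
    markers_per_type: int = 20
    marker_fold: float = 5.0
    n_batches: int = 2
    batch_scale_sd: float = 0.3
    modules: list[Module] = field(default_factory=list)
    library_size_mean: float = 2000.0
    dispersion: float = 1.0  # NB size parameter theta; smaller = more overdispersed
    base_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValueError("more markers than genes")
        universe = {f"g{j:04d}" for j in range(self.n_genes)}
        for mod in self.modules:
            unknown = set(mod.genes) - universe
            if unknown:
                raise ValueError(f"module genes outside universe: {sorted(unknown)[:3]}")


@dataclass
class SynthCorpus:
    matrix: ExpressionMatrix
    marker_map: dict[str, list[str]]  # type name -> marker gene ids
    module_map: dict[str, list[str]]  # module name -> gene ids
    config: SynthConfig
    module_factors: dict[str, np.ndarray] = field(default_factory=dict)
    # per-cell latent co-activation factor z of each module: cells with large
    # z express the module jointly high; used to pick module-active cells


def calibration_config(seed: int = 7) -> SynthConfig:
    """The standard calibration corpus used across the test harness:
    2,000 cells x 500 genes, 4 well-separated types (20 markers each at
    5-fold), 2 batches at log-sd 0.3, one 25-gene module at rho = 0.8."""
    module_genes = [f"g{j:04d}" for j in range(80, 105)]  # outside marker blocks
    return SynthConfig(n_cells=2000, n_genes=500, n_types=4, markers_per_type=20,
                       marker_fold=5.0, n_batches=2, batch_scale_sd=0.3,
                       modules=[Module(genes=module_genes, rho=0.8)], seed=seed)


def generate_corpus(cfg: SynthConfig) -> SynthCorpus:
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{j:04d}" for j in range(cfg.n_genes)]
    gene_index = {g: j for j, g in enumerate(genes)}

    # markers: disjoint leading blocks of the gene universe
    marker_map = {}
    for t in range(cfg.n_types):
        lo = t * cfg.markers_per_type
        marker_map[f"type{t}"] = genes[lo:lo + cfg.markers_per_type]

    base = rng.lognormal(mean=0.0, sigma=cfg.base_log_sd, size=cfg.n_genes)
    base *= cfg.library_size_mean / base.sum()

    types = rng.integers(0, cfg.n_types, size=cfg.n_cells)
    batches = rng.integers(0, cfg.n_batches, size=cfg.n_cells)
    batch_eff = rng.normal(0.0, cfg.batch_scale_sd, size=(cfg.n_batches, cfg.n_genes))

    log_mu = np.tile(np.log(base), (cfg.n_cells, 1))
    for t in range(cfg.n_types):
        cols = [gene_index[g] for g in marker_map[f"type{t}"]]
        log_mu[np.ix_(types == t, cols)] += np.log(cfg.marker_fold)
    log_mu += batch_eff[batches]

    module_map = {}
    module_factors = {}
    for k, mod in enumerate(cfg.modules):
        name = f"module{k}"
        module_map[name] = list(mod.genes)
        cols = [gene_index[g] for g in mod.genes]
        z = rng.normal(size=(cfg.n_cells, 1))
        eta = rng.normal(size=(cfg.n_cells, len(cols)))
        shared = np.sqrt(mod.rho) * z + np.sqrt(1.0 - mod.rho) * eta
        log_mu[:, cols] += mod.tau * shared - mod.tau ** 2 / 2.0
        module_factors[name] = z[:, 0].copy()

    mu = np.exp(log_mu)
    theta = cfg.dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.float64)

    # no all-zero cells: give any empty cell one count of its type's first marker
    empty = np.where(counts.sum(axis=1) == 0)[0]
    for i in empty:
        counts[i, gene_index[marker_map[f"type{types[i]}"][0]]] = 1.0

    matrix = ExpressionMatrix(
        counts=counts,
        cell_ids=[f"cell{i:05d}" for i in range(cfg.n_cells)],
        gene_ids=genes,
        batch=[f"batch{b}" for b in batches],
        cell_type=[f"type{t}" for t in types],
    )
    return SynthCorpus(matrix=matrix, marker_map=marker_map,
                       module_map=module_map, config=cfg,
                       module_factors=module_factors)


def truth_labels(c: SynthCorpus):
    """Ground truth for evaluation: (cell-type labels, marker map, module map)."""
    return list(c.matrix.cell_type), dict(c.marker_map), dict(c.module_map)


def split(c: SynthCorpus, fractions=(0.9, 0.1), stratify_by: str = "cell_type",
          seed: int = 0) -> tuple[SynthCorpus, SynthCorpus]:
    """Stratified disjoint split; per-stratum proportions held within one cell."""
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 2:
        raise ValueError("fractions must be two values summing to 1")
    labels = c.matrix.cell_type if stratify_by == "cell_type" else c.matrix.batch
    if labels is None:
        raise ValueError(f"corpus lacks {stratify_by} labels")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train_idx = []
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if members.size == 0:
            raise ValueError(f"empty stratum {lab}")
        perm = rng.permutation(members)
        k = int(np.rint(fractions[0] * members.size))
        train_idx.append(perm[:k])
    train_mask = np.zeros(c.matrix.n_cells, dtype=bool)
    train_mask[np.concatenate(train_idx)] = True

    def _sub(mask):
        rows = np.where(mask)[0]
        return SynthCorpus(matrix=c.matrix.subset_cells(rows),
                           marker_map=dict(c.marker_map),
                           module_map=dict(c.module_map), config=c.config,
                           module_factors={k: v[rows]
                                           for k, v in c.module_factors.items()})

    return _sub(train_mask), _sub(~train_mask)
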