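"""Seeded synthetic scRNA-seq generator with known activities and GRN.

Cell types up-regulate disjoint TF subsets; a sparse signed ground-truth GRN
maps activities to gene means through a softplus link; counts are Poisson
with log-normal library sizes, optionally thinned by Bernoulli dropout.
Every stage of the pipeline can be validated against the stored ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import sparse

from .io_prior import ExpressionMatrix, PriorNetwork
from .ulm import TFActivityMatrix


@dataclass
class SimConfig:
    n_cells: int = 1000
    n_genes: int = 200
    n_tfs: int = 20
    n_cell_types: int = 3
    edges_per_tf: int = 15
    activity_scale: float = 5.0
    baseline_activity: float = 1.0
    noise_sd: float = 0.3
    dropout_p: float = 0.0
    neg_edge_fraction: float = 0.2
    library_size: float = 5000.0
    library_sd: float = 0.3
    overdispersion: float = 0.0   # >0 switches Poisson to negative binomial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_tfs:
            raise ValueError("need n_genes >= n_tfs")
        if self.edges_per_tf > self.n_genes:
            raise ValueError("edges_per_tf cannot exceed n_genes")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if not 0.0 <= self.neg_edge_fraction <= 1.0:
            raise ValueError("neg_edge_fraction must lie in [0, 1]")
        if self.n_cell_types > self.n_tfs:
            raise ValueError("more cell types than TFs to up-regulate")


@dataclass
class SyntheticDataset:
    expr: ExpressionMatrix
    true_activities: TFActivityMatrix
    true_grn: np.ndarray          # signed weighted TF x gene
    labels: list[str]
    config: SimConfig

    @property
    def tf_ids(self) -> list[str]:
        return self.true_activities.tf_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.expr.gene_ids

    def true_edges(self) -> set[tuple[str, str]]:
        tf_idx, gene_idx = np.nonzero(self.true_grn)
        return {(self.tf_ids[i], self.gene_ids[j])
                for i, j in zip(tf_idx, gene_idx)}


def _softplus(x):
    return np.logaddexp(0.0, x)


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate a dataset with known activities, GRN and cell-type labels."""
    rng = np.random.default_rng(cfg.seed)
    cell_ids = [f"cell_{i}" for i in range(cfg.n_cells)]
    gene_ids = [f"g{j}" for j in range(cfg.n_genes)]
    tf_ids = [f"TF{i}" for i in range(cfg.n_tfs)]

    # disjoint up-regulated TF blocks per cell type
    per_type = cfg.n_tfs // cfg.n_cell_types
    type_means = np.full((cfg.n_cell_types, cfg.n_tfs), cfg.baseline_activity)
    for t in range(cfg.n_cell_types):
        block = slice(t * per_type, (t + 1) * per_type)
        type_means[t, block] += cfg.activity_scale

    # near-equal cell counts per type, remainder to the first types
    counts = np.full(cfg.n_cell_types, cfg.n_cells // cfg.n_cell_types)
    counts[: cfg.n_cells % cfg.n_cell_types] += 1
    type_of_cell = np.repeat(np.arange(cfg.n_cell_types), counts)
    labels = [f"type_{t}" for t in type_of_cell]

    activities = (type_means[type_of_cell]
                  + cfg.noise_sd * rng.standard_normal((cfg.n_cells, cfg.n_tfs)))

    grn = np.zeros((cfg.n_tfs, cfg.n_genes))
    for i in range(cfg.n_tfs):
        targets = rng.choice(cfg.n_genes, size=cfg.edges_per_tf, replace=False)
        w = np.abs(rng.standard_normal(cfg.edges_per_tf))
        n_neg = int(round(cfg.neg_edge_fraction * cfg.edges_per_tf))
        if n_neg:
            neg = rng.choice(cfg.edges_per_tf, size=n_neg, replace=False)
            w[neg] *= -1.0
        grn[i, targets] = w

    mean = _softplus(activities @ grn)
    lib = rng.lognormal(np.log(cfg.library_size), cfg.library_sd, size=cfg.n_cells)
    lam = mean / mean.sum(axis=1, keepdims=True) * lib[:, None]
    if cfg.overdispersion > 0:
        # NB via gamma-Poisson mixture, dispersion = 1/overdispersion
        shape = 1.0 / cfg.overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts_mat = rng.poisson(lam).astype(float)

    if cfg.dropout_p > 0:
        u = rng.uniform(size=counts_mat.shape)
        counts_mat = counts_mat * (u > cfg.dropout_p)

    expr = ExpressionMatrix(counts_mat, cell_ids, gene_ids, layer="counts")
    acts = TFActivityMatrix(activities, cell_ids, tf_ids, source="model")
    return SyntheticDataset(expr=expr, true_activities=acts, true_grn=grn,
                            labels=labels, config=cfg)


def corrupt_prior(
    dataset: SyntheticDataset,
    remove_fraction: float = 0.2,
    add_fraction: float = 0.2,
    seed: int = 0,
) -> PriorNetwork:
    """Signed prior derived from the true GRN with edges dropped and added.

    ``remove_fraction`` of true edges are deleted and ``add_fraction`` (of the
    true edge count) random false edges are inserted with random signs,
    emulating an incomplete and partially wrong curated network.
    """
    rng = np.random.default_rng(seed)
    signs = np.sign(dataset.true_grn)
    tf_idx, gene_idx = np.nonzero(signs)
    n_edges = len(tf_idx)
    n_remove = int(round(remove_fraction * n_edges))
    if n_remove:
        drop = rng.choice(n_edges, size=n_remove, replace=False)
        signs[tf_idx[drop], gene_idx[drop]] = 0.0
    n_add = int(round(add_fraction * n_edges))
    zero_tf, zero_gene = np.nonzero(dataset.true_grn == 0)
    if n_add and len(zero_tf):
        pick = rng.choice(len(zero_tf), size=min(n_add, len(zero_tf)), replace=False)
        signs[zero_tf[pick], zero_gene[pick]] = rng.choice([-1.0, 1.0], size=len(pick))
    return PriorNetwork(
        tf_ids=list(dataset.tf_ids),
        gene_ids=list(dataset.gene_ids),
        weights=sparse.csr_matrix(signs),
    )
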