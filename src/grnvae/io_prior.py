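"""Readers, filters and normalization for expression matrices and prior networks.

Expression matrices are accepted as dense CSV/TSV (cells x genes, header row =
gene names, first column = cell barcodes), Matrix Market triplets with
``barcodes.tsv``/``features.tsv`` sidecars, or h5ad containers.  Prior
regulatory networks are three-column tables ``tf, target, sign``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

_SIGN_ALIASES = {
    "+1": 1.0, "1": 1.0, "+": 1.0, "activation": 1.0, "activator": 1.0,
    "positive": 1.0, "up": 1.0,
    "-1": -1.0, "-": -1.0, "repression": -1.0, "repressor": -1.0,
    "negative": -1.0, "down": -1.0,
}


class DataError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with identifier sidecars.

    ``layer`` distinguishes raw counts from log-normalized values so that
    downstream steps can refuse double normalization.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise DataError(f"duplicate {name} identifier(s): {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values contain non-finite entries")
        if self.values.min(initial=0.0) < 0:
            i, j = np.argwhere(self.values < 0)[0]
            raise DataError(
                f"negative value at cell {self.cell_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )
        if self.layer not in ("counts", "lognorm"):
            raise DataError(f"unknown layer flag {self.layer!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cell_idx=None, gene_idx=None) -> "ExpressionMatrix":
        cell_idx = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        gene_idx = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        return ExpressionMatrix(
            values=self.values[np.ix_(cell_idx, gene_idx)],
            cell_ids=[self.cell_ids[i] for i in cell_idx],
            gene_ids=[self.gene_ids[j] for j in gene_idx],
            layer=self.layer,
        )


@dataclass
class PriorNetwork:
    """A signed sparse TF x gene weight matrix built from an edge table."""

    tf_ids: list[str]
    gene_ids: list[str]
    weights: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.weights = sparse.csr_matrix(self.weights, dtype=np.float64)
        if self.weights.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise DataError("prior weight matrix shape does not match identifier lists")
        for name, ids in (("tf", self.tf_ids), ("gene", self.gene_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise DataError(f"duplicate {name} identifier(s): {sorted(dupes)[:5]}")

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.weights.todense(), dtype=np.float64)

    def subset(self, tf_idx=None, gene_idx=None) -> "PriorNetwork":
        tf_idx = np.arange(self.n_tfs) if tf_idx is None else np.asarray(tf_idx)
        gene_idx = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        w = self.weights.tocsr()[tf_idx][:, gene_idx]
        return PriorNetwork(
            tf_ids=[self.tf_ids[i] for i in tf_idx],
            gene_ids=[self.gene_ids[j] for j in gene_idx],
            weights=w,
        )


@dataclass
class FilterConfig:
    min_cells_per_gene: int = 10
    min_genes_per_cell: int = 3
    min_targets_per_tf: int = 10
    mito_fraction_max: Optional[float] = None
    mito_prefixes: tuple[str, ...] = ("MT-", "mt-")
    hvg_n: Optional[int] = None
    target_sum: float = 1e4

    def __post_init__(self) -> None:
        if min(self.min_cells_per_gene, self.min_genes_per_cell, self.min_targets_per_tf) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.target_sum <= 0:
            raise ValueError("target_sum must be > 0")
        if self.mito_fraction_max is not None and not (0 < self.mito_fraction_max <= 1):
            raise ValueError("mito_fraction_max must lie in (0, 1]")


def _duplicates(ids: Sequence[str]) -> set:
    seen: set = set()
    dup: set = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_expression(path, format: Optional[str] = None) -> ExpressionMatrix:
    """Load a cells x genes counts matrix from CSV/TSV, MTX or h5ad.

    ``format`` is inferred from the file suffix when omitted.  MTX input
    expects ``barcodes.tsv`` and ``features.tsv`` (or ``genes.tsv``) sidecars
    next to the matrix file; orientation is normalized to cells x genes using
    the sidecar lengths.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv", ".txt": "csv",
                  ".h5ad": "h5ad"}.get(suffix)
        if format is None:
            raise DataError(f"cannot infer format from suffix {suffix!r}")
    if format == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        with open(path) as fh:
            # pandas mangles duplicate column names; validate the raw header
            raw_genes = fh.readline().rstrip("\n").split(sep)[1:]
        return ExpressionMatrix(
            values=df.to_numpy(dtype=np.float64),
            cell_ids=[str(x) for x in df.index],
            gene_ids=[str(x) for x in raw_genes],
        )
    if format == "mtx":
        mat = spio.mmread(path)
        mat = sparse.csr_matrix(mat)
        cells = _read_sidecar(path, ("barcodes.tsv",))
        genes = _read_sidecar(path, ("features.tsv", "genes.tsv"))
        if mat.shape == (len(genes), len(cells)) and mat.shape != (len(cells), len(genes)):
            mat = mat.T.tocsr()  # CellRanger convention stores genes x cells
        if mat.shape != (len(cells), len(genes)):
            raise DataError(
                f"matrix shape {mat.shape} matches neither orientation of "
                f"{len(cells)} barcodes x {len(genes)} features"
            )
        return ExpressionMatrix(
            values=np.asarray(mat.todense(), dtype=np.float64),
            cell_ids=cells, gene_ids=genes,
        )
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.layers["counts"] if "counts" in adata.layers else adata.X
        if sparse.issparse(x):
            x = np.asarray(x.todense())
        return ExpressionMatrix(
            values=np.asarray(x, dtype=np.float64),
            cell_ids=[str(x) for x in adata.obs_names],
            gene_ids=[str(x) for x in adata.var_names],
        )
    raise DataError(f"unknown format {format!r}")


def _read_sidecar(mtx_path: Path, names: tuple[str, ...]) -> list[str]:
    for name in names:
        p = mtx_path.parent / name
        if p.exists():
            col = pd.read_csv(p, sep="\t", header=None).iloc[:, 0]
            return [str(x) for x in col]
    raise DataError(f"missing sidecar ({' or '.join(names)}) next to {mtx_path}")


def load_prior_network(path, strict: bool = True) -> PriorNetwork:
    """Read a TF/target/sign edge table into a signed sparse matrix.

    A missing sign column defaults to +1; textual labels such as
    "activation"/"repression" are mapped through an alias table.  Duplicate
    (TF, target) pairs collapse by sign-sum clamped to {-1, 0, +1};
    sign-conflicting duplicates cancel to 0 and are logged.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise DataError("prior table needs at least two columns (tf, target)")
    if df.empty:
        raise DataError("prior table is empty")
    df = df.iloc[:, :3].copy()
    df.columns = ["tf", "target", "sign"][: df.shape[1]]
    if "sign" not in df.columns:
        df["sign"] = 1.0
    signs = []
    for raw in df["sign"]:
        key = str(raw).strip().lower()
        if key in _SIGN_ALIASES:
            signs.append(_SIGN_ALIASES[key])
            continue
        try:
            val = float(raw)
        except (TypeError, ValueError):
            val = None
        if val in (1.0, -1.0):
            signs.append(val)
        elif strict:
            raise DataError(f"unparseable sign {raw!r} for edge "
                            f"({df['tf'][len(signs)]}, {df['target'][len(signs)]})")
        else:
            signs.append(np.sign(val) if val else 0.0)
    df["sign"] = signs

    tf_ids = list(pd.unique(df["tf"].astype(str)))
    gene_ids = list(pd.unique(df["target"].astype(str)))
    tf_pos = {t: i for i, t in enumerate(tf_ids)}
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    rows = df["tf"].astype(str).map(tf_pos).to_numpy()
    cols = df["target"].astype(str).map(gene_pos).to_numpy()
    w = sparse.coo_matrix(
        (df["sign"].to_numpy(dtype=np.float64), (rows, cols)),
        shape=(len(tf_ids), len(gene_ids)),
    ).tocsr()  # duplicate entries sum
    clamped = w.copy()
    clamped.data = np.sign(clamped.data)
    n_unique = len(df.drop_duplicates(["tf", "target"]))
    n_cancelled = n_unique - int((clamped.data != 0).sum())
    if n_cancelled > 0:
        logger.warning("%d prior edge(s) with conflicting signs cancelled to 0",
                       n_cancelled)
    clamped.eliminate_zeros()
    return PriorNetwork(tf_ids=tf_ids, gene_ids=gene_ids, weights=clamped)


# ---------------------------------------------------------------------------
# filtering & normalization
# ---------------------------------------------------------------------------

def filter_dataset(
    expr: ExpressionMatrix,
    prior: PriorNetwork,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[ExpressionMatrix, PriorNetwork]:
    """Apply the standard filtering cascade and align expression with the prior.

    Single pass, in order: (1) drop genes expressed in fewer than
    ``min_cells_per_gene`` cells; (2) drop cells expressing fewer than
    ``min_genes_per_cell`` genes; (3) drop genes with no TF in the prior;
    (4) drop TFs with fewer than ``min_targets_per_tf`` surviving targets;
    (5) optional mitochondrial-fraction cell filter; (6) optional HVG
    restriction.  Gene names are matched case-insensitively.
    """
    if expr.layer != "counts":
        raise DataError("filter_dataset expects the counts layer")
    x = expr.values

    gene_keep = (x > 0).sum(axis=0) >= cfg.min_cells_per_gene
    expr = expr.subset(gene_idx=np.flatnonzero(gene_keep))

    cell_keep = (expr.values > 0).sum(axis=1) >= cfg.min_genes_per_cell
    expr = expr.subset(cell_idx=np.flatnonzero(cell_keep))

    # align prior genes to surviving expression genes (case-insensitive)
    prior_gene_lc = {g.lower(): j for j, g in enumerate(prior.gene_ids)}
    expr_gene_hit, prior_gene_idx = [], []
    for j, g in enumerate(expr.gene_ids):
        pj = prior_gene_lc.get(g.lower())
        if pj is not None and prior.weights[:, pj].count_nonzero() > 0:
            expr_gene_hit.append(j)
            prior_gene_idx.append(pj)
    expr = expr.subset(gene_idx=np.array(expr_gene_hit, dtype=int))
    prior = prior.subset(gene_idx=np.array(prior_gene_idx, dtype=int))
    prior = PriorNetwork(prior.tf_ids, list(expr.gene_ids), prior.weights)

    targets_per_tf = np.asarray(
        (prior.weights != 0).sum(axis=1)
    ).ravel()
    tf_keep = np.flatnonzero(targets_per_tf >= cfg.min_targets_per_tf)
    prior = prior.subset(tf_idx=tf_keep)

    # TF removal can orphan genes; single pass by design, so only log them
    orphaned = int((np.asarray((prior.weights != 0).sum(axis=0)).ravel() == 0).sum())
    if orphaned:
        logger.info("%d genes left without a prior TF after TF filtering", orphaned)

    if cfg.mito_fraction_max is not None:
        mito = np.array([g.startswith(cfg.mito_prefixes) for g in expr.gene_ids])
        totals = expr.values.sum(axis=1)
        frac = np.divide(expr.values[:, mito].sum(axis=1), totals,
                         out=np.zeros_like(totals), where=totals > 0)
        expr = expr.subset(cell_idx=np.flatnonzero(frac <= cfg.mito_fraction_max))

    if cfg.hvg_n is not None and cfg.hvg_n < expr.n_genes:
        var = expr.values.var(axis=0)
        top = np.sort(np.argsort(var)[::-1][: cfg.hvg_n])
        expr = expr.subset(gene_idx=top)
        keep_lc = {g.lower() for g in expr.gene_ids}
        gidx = [j for j, g in enumerate(prior.gene_ids) if g.lower() in keep_lc]
        prior = prior.subset(gene_idx=np.array(gidx, dtype=int))
        prior = PriorNetwork(prior.tf_ids, list(expr.gene_ids), prior.weights)

    if prior.n_tfs == 0 or expr.n_genes == 0 or expr.n_cells == 0:
        raise DataError(
            "filtering removed everything; relax min_cells_per_gene / "
            "min_genes_per_cell / min_targets_per_tf"
        )
    return expr, prior


def lognormalize(expr: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then natural log1p.

    All-zero cells pass through as zeros.  Refuses input already flagged
    ``lognorm`` to prevent double normalization.
    """
    if expr.layer == "lognorm":
        raise DataError("input is already log-normalized")
    totals = expr.values.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.ones_like(totals), where=totals > 0)
    values = np.log1p(expr.values * scale)
    return replace(expr, values=values, layer="lognorm")
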