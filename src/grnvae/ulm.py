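"""Univariate-linear-model TF activity scoring against a signed prior network.

For every (cell, TF) pair the cell's expression vector over genes is regressed
on the TF's signed prior weight vector (intercept included, non-targets carry
weight 0).  The activity score is the t-statistic of the slope, the convention
used by regulon-scoring toolkits; the raw slope ("weighted sum" scorer) is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_prior import ExpressionMatrix, PriorNetwork, DataError

#: cap applied to t-statistics of (near-)perfect fits instead of +/-inf
T_CAP = 1e6


@dataclass
class TFActivityMatrix:
    """Cells x TFs real-valued activity scores."""

    values: np.ndarray
    cell_ids: list[str]
    tf_ids: list[str]
    source: str = "ulm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.tf_ids)):
            raise ValueError("activity matrix shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity matrix contains non-finite values")
        if self.source not in ("ulm", "model", "blended"):
            raise ValueError(f"unknown source flag {self.source!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_tfs(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.tf_ids)


def ulm_activities(
    expr: ExpressionMatrix,
    prior: PriorNetwork,
    scorer: str = "tstat",
) -> TFActivityMatrix:
    """Score per-cell TF activities by univariate regression on prior weights.

    Parameters
    ----------
    expr
        Log-normalized expression, gene-aligned with ``prior``.
    prior
        Signed TF x gene prior network.
    scorer
        ``"tstat"`` (default) returns the slope t-statistic; ``"wsum"``
        returns the raw weighted sum ``W @ x`` per cell.
    """
    if expr.layer != "lognorm":
        raise DataError("ulm_activities expects log-normalized expression")
    if list(expr.gene_ids) != list(prior.gene_ids):
        raise DataError("expression and prior gene lists are not aligned")
    n_genes = expr.n_genes
    if n_genes < 3:
        raise DataError("need at least 3 genes for a t-statistic")

    W = prior.dense()  # TFs x genes
    if scorer == "wsum":
        vals = expr.values @ W.T
        return TFActivityMatrix(vals, list(expr.cell_ids), list(prior.tf_ids), "ulm")
    if scorer != "tstat":
        raise ValueError(f"unknown scorer {scorer!r}")

    w_var = W.var(axis=1)
    degenerate = np.flatnonzero(w_var == 0)
    if degenerate.size:
        names = [prior.tf_ids[i] for i in degenerate]
        raise DataError(f"zero-variance prior weight vector for TF(s): {names}")

    X = expr.values  # cells x genes (response y, one regression per cell/TF)
    Wc = W - W.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = (Wc**2).sum(axis=1)  # per TF
    sxy = Xc @ Wc.T            # cells x TFs
    syy = (Xc**2).sum(axis=1, keepdims=True)  # per cell

    slope = sxy / sxx
    rss = syy - sxy**2 / sxx
    rss = np.maximum(rss, 0.0)
    dof = n_genes - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (dof * sxx))
        t = slope / se
    # all-zero (or constant) cells: slope 0 / se 0 -> define activity 0
    t[np.isnan(t)] = 0.0
    t = np.clip(t, -T_CAP, T_CAP)
    return TFActivityMatrix(t, list(expr.cell_ids), list(prior.tf_ids), "ulm")
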