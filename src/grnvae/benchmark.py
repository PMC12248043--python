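"""Evaluation machinery: clustering sweeps, dropout masking, GRN edge
recovery, stratified subsetting and knockdown scoring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    adjusted_rand_score, average_precision_score, f1_score,
    normalized_mutual_info_score, roc_auc_score,
)
from sklearn.neighbors import NearestNeighbors

from .io_prior import ExpressionMatrix
from .model import WeightedGRN
from .ulm import TFActivityMatrix
from .downstream import _minmax_rescale, ranksum_p, rescaled_lfc

DEFAULT_RESOLUTIONS = tuple(np.round(np.linspace(0.2, 3.0, 15), 3))


@dataclass
class DropoutMaskConfig:
    p: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("dropout probability must lie in [0, 1]")


@dataclass
class GRNEvalReport:
    auroc: float
    auprc: float
    n_edges_gold: int
    n_pairs_scored: int


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def leiden_labels(values: np.ndarray, resolution: float, k: int = 15,
                  seed: int = 0) -> np.ndarray:
    """Leiden partition of a kNN graph (Euclidean) built on row vectors."""
    import igraph as ig
    import leidenalg

    n = values.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(values)
    _, idx = nn.kneighbors(values)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed,
    )
    return np.asarray(part.membership)


def majority_vote(clusters: np.ndarray, truth: Sequence[str]) -> np.ndarray:
    """Assign each cluster its most frequent truth label (ties lexicographic)."""
    truth = np.asarray([str(t) for t in truth])
    voted = np.empty(len(clusters), dtype=object)
    for c in np.unique(clusters):
        members = truth[clusters == c]
        labels, counts = np.unique(members, return_counts=True)
        # np.unique sorts labels, argmax takes the first max -> lexicographic tie-break
        voted[clusters == c] = labels[np.argmax(counts)]
    return voted.astype(str)


def _composition_auc(clusters: np.ndarray, truth: np.ndarray) -> float:
    """Macro one-vs-rest AUROC of the cluster-composition score.

    A cell's score for class c is the fraction of its cluster's members whose
    true label is c.
    """
    classes = np.unique(truth)
    aucs = []
    for c in classes:
        is_c = (truth == c).astype(float)
        score = np.empty(len(clusters))
        for cl in np.unique(clusters):
            mask = clusters == cl
            score[mask] = is_c[mask].mean()
        if is_c.min() == is_c.max():
            continue  # degenerate single-class column
        aucs.append(roc_auc_score(is_c, score))
    return float(np.mean(aucs)) if aucs else float("nan")


def evaluate_clustering(
    acts: TFActivityMatrix,
    truth_labels: Sequence[str],
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS,
    k: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Leiden sweep over resolutions with majority-vote label assignment.

    Returns one row per resolution with ARI, NMI, macro F1 and the
    composition-score AUC against the truth labels.
    """
    truth = np.asarray([str(t) for t in truth_labels])
    if acts.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if len(np.unique(truth)) < 2:
        raise ValueError("need at least 2 distinct truth labels")
    if len(truth) != acts.n_cells:
        raise ValueError("labels length does not match activity matrix")
    if not len(resolutions):
        raise ValueError("resolutions must be nonempty")
    rows = []
    for res in resolutions:
        clusters = leiden_labels(acts.values, float(res), k=k, seed=seed)
        voted = majority_vote(clusters, truth)
        rows.append({
            "resolution": float(res),
            "ari": adjusted_rand_score(truth, clusters),
            "nmi": normalized_mutual_info_score(truth, clusters),
            "macro_f1": f1_score(truth, voted, average="macro"),
            "auc": _composition_auc(clusters, truth),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dropout masking
# ---------------------------------------------------------------------------

def apply_dropout(expr: ExpressionMatrix, cfg: DropoutMaskConfig) -> ExpressionMatrix:
    """Bernoulli-mask entries: keep where Uniform(0,1) > p, zero otherwise."""
    rng = np.random.default_rng(cfg.seed)
    u = rng.uniform(size=expr.values.shape)
    keep = u > cfg.p
    return ExpressionMatrix(expr.values * keep, list(expr.cell_ids),
                            list(expr.gene_ids), expr.layer)


# ---------------------------------------------------------------------------
# GRN edge recovery
# ---------------------------------------------------------------------------

def evaluate_grn(pred: WeightedGRN, gold_edges) -> GRNEvalReport:
    """AUROC / AUPRC of |weight| ranking against a gold-standard edge set.

    Scoring is restricted to (tf, gene) pairs whose TF and gene both occur in
    the predicted GRN; gold membership is the positive label.
    """
    gold = {(str(t), str(g)) for t, g in gold_edges}
    tf_set = set(pred.tf_ids)
    gene_set = set(pred.gene_ids)
    gold_in = {(t, g) for t, g in gold if t in tf_set and g in gene_set}
    if not gold_in:
        raise ValueError("no gold edge falls inside the predicted TF/gene space")
    y, s = [], []
    for i, tf in enumerate(pred.tf_ids):
        for j, gene in enumerate(pred.gene_ids):
            y.append((tf, gene) in gold_in)
            s.append(abs(pred.weights[i, j]))
    y = np.asarray(y)
    s = np.asarray(s)
    if y.all() or not y.any():
        raise ValueError("gold standard yields 0 positives or 0 negatives")
    return GRNEvalReport(
        auroc=float(roc_auc_score(y, s)),
        auprc=float(average_precision_score(y, s)),
        n_edges_gold=int(y.sum()),
        n_pairs_scored=len(y),
    )


# ---------------------------------------------------------------------------
# stratified subsetting
# ---------------------------------------------------------------------------

def stratified_subsets(
    expr: ExpressionMatrix,
    k: int = 5,
    seed: int = 0,
    labels: Optional[Sequence[str]] = None,
    resolution: float = 1.0,
) -> list[np.ndarray]:
    """Split cells into ``k`` disjoint subsets preserving cluster proportions.

    Clusters come from ``labels`` when given, else a Leiden partition of the
    expression matrix at ``resolution``.  Within each cluster, cells are
    shuffled (seeded) and dealt round-robin, so per-subset cluster
    proportions stay within one cell of the global proportions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if labels is not None:
        clusters = np.asarray([str(x) for x in labels])
    else:
        clusters = leiden_labels(expr.values, resolution, seed=seed).astype(str)
    rng = np.random.default_rng(seed)
    subsets: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        if len(idx) < k:
            warnings.warn(f"cluster {c!r} has {len(idx)} cells (< k={k}); "
                          "spread over as many subsets as possible")
        idx = rng.permutation(idx)
        for pos, cell in enumerate(idx):
            subsets[pos % k].append(int(cell))
    return [np.sort(np.asarray(s, dtype=int)) for s in subsets]


# ---------------------------------------------------------------------------
# knockdown evaluation
# ---------------------------------------------------------------------------

def knockdown_evaluation(
    acts: TFActivityMatrix,
    groups: Sequence[str],
    tf: str,
) -> tuple[float, float]:
    """(LFC, Wilcoxon p) for one TF between perturbed and control cells.

    Activities are min-max rescaled per TF (means floored at 0.01);
    LFC = log2(mean_perturbed / mean_control); p is the two-sided Wilcoxon
    rank-sum p-value on the raw activities.
    """
    if tf not in acts.tf_ids:
        raise KeyError(f"unknown TF {tf!r}")
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != acts.n_cells:
        raise ValueError("groups length does not match activity matrix")
    pert = groups == "perturbed"
    ctrl = groups == "control"
    if pert.sum() < 3 or ctrl.sum() < 3:
        raise ValueError("both groups need at least 3 cells")
    j = acts.tf_ids.index(tf)
    rescaled = _minmax_rescale(acts.values)[:, j]
    lfc = rescaled_lfc(rescaled[pert], rescaled[ctrl])
    p = ranksum_p(acts.values[pert, j], acts.values[ctrl, j])
    return lfc, p
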