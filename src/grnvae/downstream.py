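"""Downstream analyses: differential TF activity, co-regulation, enrichment.

All tables are plain pandas DataFrames so they serialize to TSV directly.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .model import WeightedGRN
from .training import CellTypeGRNSet
from .ulm import TFActivityMatrix

#: floor applied to rescaled activity means before taking log ratios
LFC_PSEUDOCOUNT = 0.01


def _minmax_rescale(values: np.ndarray) -> np.ndarray:
    """Per-column min-max rescale to [0, 1]; constant columns map to 0.5."""
    lo = values.min(axis=0, keepdims=True)
    hi = values.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.full_like(values, 0.5, dtype=float)
    np.divide(values - lo, span, out=out, where=span > 0)
    return out


def ranksum_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution for small tie-free samples (combined n <= 40),
    normal approximation otherwise; identical groups return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return 1.0
    small = len(combined) <= 40 and len(np.unique(combined)) == len(combined)
    if small:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="exact").pvalue)
    return float(stats.ranksums(a, b).pvalue)


def rescaled_lfc(a: np.ndarray, b: np.ndarray,
                 pseudocount: float = LFC_PSEUDOCOUNT) -> float:
    """log2 ratio of two rescaled-activity means, floored at the pseudocount."""
    ma = max(float(np.mean(a)), pseudocount)
    mb = max(float(np.mean(b)), pseudocount)
    return float(np.log2(ma / mb))


def differential_tf_activity(
    acts: TFActivityMatrix,
    labels: Sequence[str],
    p_threshold: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum differential TF activity per cell type.

    Activities are min-max rescaled per TF to [0, 1] before the log2
    fold change (means floored at 0.01); the raw mean difference is reported
    alongside.  Benjamini-Hochberg adjustment is applied across TFs within
    each cell type; rows with adjusted p >= ``p_threshold`` are dropped and
    the result is sorted by LFC (descending) within cell type.
    """
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != acts.n_cells:
        raise ValueError("labels length does not match activity matrix")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 distinct labels")
    rescaled = _minmax_rescale(acts.values)

    frames = []
    for g in groups:
        in_g = labels == g
        if in_g.sum() < min_group or (~in_g).sum() < min_group:
            warnings.warn(f"group {g!r} has fewer than {min_group} cells on one "
                          "side; excluded from differential testing")
            continue
        pvals, lfcs, diffs = [], [], []
        for j in range(acts.n_tfs):
            a = acts.values[in_g, j]
            b = acts.values[~in_g, j]
            pvals.append(ranksum_p(a, b))
            lfcs.append(rescaled_lfc(rescaled[in_g, j], rescaled[~in_g, j]))
            diffs.append(float(a.mean() - b.mean()))
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "tf": acts.tf_ids, "cell_type": g, "lfc": lfcs,
            "mean_diff": diffs, "p": pvals, "p_adj": p_adj,
        }))
    if not frames:
        raise ValueError("no group large enough for differential testing")
    table = pd.concat(frames, ignore_index=True)
    table = table[table["p_adj"] < p_threshold]
    table = table.sort_values(["cell_type", "lfc"], ascending=[True, False])
    return table.reset_index(drop=True)


def cosine_similarity(w1, w2) -> float:
    """Cosine similarity of two weight vectors; errors on zero vectors."""
    w1 = np.asarray(w1, dtype=float).ravel()
    w2 = np.asarray(w2, dtype=float).ravel()
    if w1.shape != w2.shape:
        raise ValueError("vectors must have equal length")
    n1 = np.linalg.norm(w1)
    n2 = np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(w1, w2) / (n1 * n2), -1.0, 1.0))


def coregulatory_network(
    grns: CellTypeGRNSet,
    da: pd.DataFrame,
    top_k_per_type: int = 5,
    sim_threshold: float = 0.5,
) -> pd.DataFrame:
    """Undirected TF-TF co-regulation edges across cell-type contexts.

    Nodes are the ``top_k_per_type`` differentially active (TF, cell type)
    pairs; an edge links two nodes when the cosine similarity of their GRN
    weight rows is at least ``sim_threshold``.  Each unordered pair appears
    once; self-pairs (same TF, same context) are excluded.
    """
    if da.empty:
        raise ValueError("differential activity table is empty")
    nodes = []
    for ct, sub in da.groupby("cell_type"):
        if ct not in grns.grns:
            continue
        grn = grns.grns[ct]
        for tf in sub.sort_values("lfc", ascending=False)["tf"].head(top_k_per_type):
            if tf in grn.tf_ids:
                vec = grn.weights[grn.tf_ids.index(tf)]
                if np.any(vec):
                    nodes.append((str(tf), str(ct), vec))
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            tf1, ct1, v1 = nodes[i]
            tf2, ct2, v2 = nodes[j]
            sim = cosine_similarity(v1, v2)
            if sim >= sim_threshold:
                edges.append((tf1, ct1, tf2, ct2, sim))
    return pd.DataFrame(edges, columns=["tf1", "cell_type1", "tf2",
                                        "cell_type2", "similarity"])


def grn_correlation_clustering(grns: CellTypeGRNSet):
    """Pairwise Pearson correlation of |W| (min-max normalized) + UPGMA order.

    Returns ``(corr: DataFrame, leaf_order: list[str])``.
    """
    contexts = grns.contexts()
    if len(contexts) < 2:
        raise ValueError("need at least 2 GRNs to compare")
    flats = {}
    for ct in contexts:
        w = np.abs(grns.grns[ct].weights).ravel()
        span = w.max() - w.min()
        if span == 0:
            raise ValueError(f"GRN for context {ct!r} is constant; "
                             "correlation undefined")
        flats[ct] = (w - w.min()) / span
    n = len(contexts)
    corr = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = stats.pearsonr(flats[contexts[i]], flats[contexts[j]]).statistic
            corr[i, j] = corr[j, i] = r
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = [contexts[k] for k in hierarchy.leaves_list(link)]
    corr_df = pd.DataFrame(corr, index=contexts, columns=contexts)
    return corr_df, order


def top_targets_enrichment(
    grn: WeightedGRN,
    tf: str,
    gene_sets: Mapping[str, Sequence[str]],
    top_fraction: float = 0.01,
    p_threshold: float = 0.05,
    rank_by_abs: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of top-ranked targets in gene sets.

    Targets are ranked by descending signed weight (``rank_by_abs=True``
    ranks by magnitude); the top ``ceil(top_fraction * n_genes)`` genes are
    tested per set against the GRN gene universe, with BH adjustment across
    sets.  Sets disjoint from the universe are skipped with a warning.
    """
    if tf not in grn.tf_ids:
        raise KeyError(f"unknown TF {tf!r}")
    if not gene_sets:
        raise ValueError("gene_sets is empty")
    weights = grn.weights[grn.tf_ids.index(tf)]
    key = np.abs(weights) if rank_by_abs else weights
    n_universe = len(grn.gene_ids)
    k_top = int(np.ceil(top_fraction * n_universe))
    top_idx = np.argsort(-key, kind="stable")[:k_top]
    top_genes = {grn.gene_ids[j] for j in top_idx}
    universe = set(grn.gene_ids)

    rows = []
    for name, members in gene_sets.items():
        members_in = set(map(str, members)) & universe
        if not members_in:
            warnings.warn(f"gene set {name!r} is disjoint from the GRN universe; skipped")
            continue
        overlap = len(top_genes & members_in)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe,
                                     len(members_in), k_top))
        rows.append((name, overlap, len(members_in), k_top, p))
    if not rows:
        raise ValueError("no gene set overlaps the GRN universe")
    table = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                        "top_n", "p"])
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["p_adj"] < p_threshold
    return table.sort_values("p").reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets
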