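"""Descriptive assemblage analyses: site clustering and indicator species.

Hierarchical clustering groups sites either by their (scaled) water
chemistry or by their (transformed) assemblages; indicator-value analysis
(IndVal) scores each taxon's association with site groups — e.g. 1 degC
temperature classes — as the geometric mean of specificity (A, the share
of the taxon's across-group mean abundance found in the group) and
fidelity (B, the fraction of the group's sites where the taxon occurs),
with permutation-based significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import AbundanceMatrix, DataError, EnvTable

__all__ = ["ClusterResult", "cluster_sites", "indval", "temperature_classes"]


@dataclass
class ClusterResult:
    """Agglomerative tree plus a flat cut into k groups."""

    linkage_matrix: np.ndarray
    assignments: pd.Series
    metric: str
    method: str
    k: int
    silhouette: float

    def to_newick(self) -> str:
        """Export the dendrogram as a newick string (heights as lengths)."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        labels = list(self.assignments.index)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def cluster_sites(
    matrix: EnvTable | AbundanceMatrix,
    k: int,
    metric: str = "euclidean",
    method: str = "ward",
) -> ClusterResult:
    """Hierarchically cluster sites and cut the tree into ``k`` groups.

    Euclidean distance on a scaled environment table or on a
    Hellinger-transformed assemblage matrix are the intended pairings
    (the latter is the Hellinger distance the ordination already uses).
    """
    values = matrix.values
    n = values.shape[0]
    if n < 2:
        raise DataError("clustering needs at least 2 sites")
    if k > n or k < 1:
        raise DataError(f"cannot cut {n} sites into {k} clusters")
    dist = pdist(values.to_numpy(dtype=float), metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    sil = np.nan
    if 1 < k < n and len(set(labels)) > 1:
        from sklearn.metrics import silhouette_score

        sil = float(silhouette_score(values.to_numpy(dtype=float), labels, metric=metric))
    return ClusterResult(Z, pd.Series(labels, index=values.index, name="cluster"), metric, method, k, sil)


def temperature_classes(x, width: float = 1.0) -> pd.Series:
    """Label sites by equal-width (default 1 degC) bins of the gradient."""
    xv = np.asarray(x, dtype=float)
    lo = np.floor(xv.min() / width) * width
    bins = np.floor((xv - lo) / width).astype(int)
    labels = [f"[{lo + b * width:g},{lo + (b + 1) * width:g})" for b in bins]
    return pd.Series(labels, name="class")


def _indval_stats(Y: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A (specificity) and B (fidelity) per taxon x group."""
    g_mean = np.stack([Y[groups == g].mean(axis=0) for g in uniq])  # groups x taxa
    denom = g_mean.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, g_mean / denom, 0.0)
    B = np.stack([(Y[groups == g] > 0).mean(axis=0) for g in uniq])
    return A, B


def indval(
    species: AbundanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    with_combinations: bool = False,
) -> pd.DataFrame:
    """Indicator-value analysis of every taxon against site groups.

    stat = sqrt(A x B) where A is specificity and B fidelity; the best
    group (optionally the best union of groups) is the argmax.  The
    p-value permutes site labels and compares the permuted best stat with
    the observed one: p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm).
    With ``with_combinations`` unions of groups are scored with
    A = mean(C) / (mean(C) + sum of means of the groups outside C).
    """
    g = pd.Series(groups)
    if len(g) != len(species.sites):
        raise DataError("group labels must match site count")
    uniq = np.array(sorted(g.unique()))
    if len(uniq) < 2:
        raise DataError("indval needs at least 2 groups")
    counts = g.value_counts()
    if (counts < 1).any():
        raise DataError("every group needs at least one site")
    rng = np.random.default_rng(seed)
    Y = species.values.to_numpy(dtype=float)
    garr = g.to_numpy()

    combos: list[tuple] = [(u,) for u in uniq]
    if with_combinations:
        from itertools import combinations

        for r in range(2, len(uniq)):
            combos.extend(combinations(uniq, r))

    def best_stats(Yp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        A1, B1 = _indval_stats(Yp, garr, uniq)
        g_mean = np.stack([Yp[garr == u].mean(axis=0) for u in uniq])
        best_s = np.zeros(Yp.shape[1])
        best_A = np.zeros(Yp.shape[1])
        best_B = np.zeros(Yp.shape[1])
        best_c = np.zeros(Yp.shape[1], dtype=int)
        for ci, combo in enumerate(combos):
            if len(combo) == 1:
                gi = int(np.where(uniq == combo[0])[0][0])
                A, B = A1[gi], B1[gi]
            else:
                mask = np.isin(garr, combo)
                mean_c = Yp[mask].mean(axis=0)
                out_means = g_mean[~np.isin(uniq, combo)].sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    A = np.where(mean_c + out_means > 0, mean_c / (mean_c + out_means), 0.0)
                B = (Yp[mask] > 0).mean(axis=0)
            s = np.sqrt(A * B)
            upd = s > best_s
            best_s[upd] = s[upd]
            best_A[upd] = A[upd]
            best_B[upd] = B[upd]
            best_c[upd] = ci
        return best_s, best_A, best_B, best_c

    obs_s, obs_A, obs_B, obs_c = best_stats(Y)
    exceed = np.zeros(Y.shape[1])
    for _ in range(n_perm):
        Yp = Y[rng.permutation(Y.shape[0])]
        perm_s, *_ = best_stats(Yp)
        exceed += perm_s >= obs_s
    pvals = (1 + exceed) / (1 + n_perm)
    group_labels = ["+".join(str(u) for u in combos[c]) for c in obs_c]
    return pd.DataFrame(
        {
            "group": group_labels,
            "A": obs_A,
            "B": obs_B,
            "stat": obs_s,
            "p": pvals,
        },
        index=pd.Index(species.taxa, name="taxon"),
    )
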