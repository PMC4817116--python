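"""Ward hierarchical clustering of datasets (1 - Delta) and pockets.

Dataset clustering uses the chemical-space overlap as a similarity, turned
into a dissimilarity d = 1 - Delta; pocket clustering uses Euclidean
distances between whole-pocket vectors.  Because such dissimilarities need
not be Euclidean, the agglomeration follows the "Ward.D2" convention
(squared dissimilarities inside the Lance-Williams update, merge heights on
the original scale), with the plain-"Ward.D" variant available behind a
flag.  Ties in the minimum-dissimilarity search are broken by the
lexicographically smallest pair of cluster indices so results are fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

logger = logging.getLogger(__name__)


def overlap_to_distance(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise d = 1 - Delta with the diagonal forced to zero."""
    v = values.to_numpy(dtype=float)
    if v.min() < 0 or v.max() > 1:
        raise ValueError("overlap scores must lie in [0, 1]")
    d = 1.0 - v
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=values.index, columns=values.columns)


@dataclass
class ClusterTree:
    """Merge history of an agglomerative clustering.

    ``merge_history`` lists (node_a, node_b, height) in merge order, using
    the usual convention: leaves are 0..n-1, the k-th merge creates node
    n + k.  Heights are nondecreasing for Ward linkage.
    """

    merge_history: list[tuple[int, int, float]]
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1) x 4 linkage matrix."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((n - 1, 4))
        for k, (a, b, h) in enumerate(self.merge_history):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            z[k] = [a, b, h, size]
        return z

    def leaf_order(self) -> list[str]:
        """Dendrogram leaf order (used to reorder heat-map rows/columns)."""
        from scipy.cluster.hierarchy import leaves_list

        return [self.leaf_labels[i] for i in leaves_list(self.to_linkage())]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_labels[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merge_history):
            la = h - height[a]
            lb = h - height[b]
            node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + k] = h
        return node[n + len(self.merge_history) - 1] + ";"


def ward_cluster(
    d: pd.DataFrame | np.ndarray,
    labels: list[str] | None = None,
    variant: str = "D2",
) -> ClusterTree:
    """Ward minimum-variance agglomeration of a dissimilarity matrix.

    ``variant="D2"`` (default) squares the dissimilarities inside the
    Lance-Williams recurrence and reports heights on the original scale;
    ``variant="D"`` applies the recurrence to the dissimilarities directly.
    """
    if isinstance(d, pd.DataFrame):
        if labels is None:
            labels = [str(l) for l in d.index]
        d = d.to_numpy(dtype=float)
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if np.isnan(d).any():
        raise ValueError("dissimilarity matrix contains NaN")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if (d < 0).any() or np.abs(np.diag(d)).max() > 0:
        raise ValueError("dissimilarities must be nonnegative with a zero diagonal")
    if variant not in {"D", "D2"}:
        raise ValueError(f"unknown Ward variant {variant!r}")

    # work on squared dissimilarities for D2, raw for D
    w = d**2 if variant == "D2" else d.copy()
    np.fill_diagonal(w, np.inf)
    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> size
    pos = {i: i for i in range(n)}  # node id -> row in w
    rev = {i: i for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        ids = sorted(active)
        # lexicographically smallest pair among the minima
        best = None
        for ii, a_id in enumerate(ids):
            for b_id in ids[ii + 1 :]:
                val = w[pos[a_id], pos[b_id]]
                if best is None or val < best[0] - 1e-15:
                    best = (val, a_id, b_id)
        val, a_id, b_id = best
        height = float(np.sqrt(val)) if variant == "D2" else float(val)
        new_id = n + step
        na, nb = active[a_id], active[b_id]
        ra, rb = pos[a_id], pos[b_id]
        # Lance-Williams update for Ward linkage
        for c_id in ids:
            if c_id in (a_id, b_id):
                continue
            rc = pos[c_id]
            nc = active[c_id]
            upd = (
                (na + nc) * w[ra, rc] + (nb + nc) * w[rb, rc] - nc * val
            ) / (na + nb + nc)
            w[ra, rc] = w[rc, ra] = upd
        w[rb, :] = np.inf
        w[:, rb] = np.inf
        del active[a_id], active[b_id], pos[a_id], pos[b_id]
        active[new_id] = na + nb
        pos[new_id] = ra
        merges.append((a_id, b_id, height))
    return ClusterTree(merge_history=merges, leaf_labels=list(labels))


def cut_tree(tree: ClusterTree, k: int) -> pd.Series:
    """Assignments for exactly ``k`` clusters (labelled 0..k-1 by first
    appearance in leaf order)."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    member: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, _h) in enumerate(tree.merge_history[: n - k]):
        new_id = n + step
        member[new_id] = member.pop(a) + member.pop(b)
    assign = np.empty(n, dtype=int)
    # stable numbering: order clusters by their smallest leaf index
    roots = sorted(member.values(), key=min)
    for c, leaves in enumerate(roots):
        for leaf in leaves:
            assign[leaf] = c
    return pd.Series(assign, index=tree.leaf_labels, name="cluster")


def characterize_clusters(
    assignments: pd.Series,
    table: pd.DataFrame,
    descriptors: list[str],
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Descriptors that single out each cluster against all the others.

    For each cluster with at least 5 members and each descriptor, a
    Kruskal-Wallis omnibus is followed by pairwise Mann-Whitney-Wilcoxon
    tests of that cluster against every remaining cluster; the descriptor is
    reported for the cluster iff every pairwise comparison is significant at
    ``alpha``, together with the direction of the difference ("higher" or
    "lower" by median).  Undersized clusters are skipped and logged.
    """
    clusters = sorted(assignments.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    groups = {c: table.loc[assignments[assignments == c].index] for c in clusters}
    usable = []
    for c in clusters:
        if len(groups[c]) < _stats.MIN_GROUP_SIZE:
            logger.info("cluster %r skipped: only %d members", c, len(groups[c]))
        else:
            usable.append(c)
    rows = []
    for d in descriptors:
        samples = {c: groups[c][d].to_numpy(dtype=float) for c in usable}
        res = _stats.anova_posthoc(samples, alpha=alpha)
        if res.omnibus_p >= alpha:
            continue
        for c in usable:
            others = [o for o in usable if o != c]
            if all(res.pairwise.loc[c, o] < alpha for o in others):
                med_c = np.median(samples[c])
                med_rest = np.median(np.concatenate([samples[o] for o in others]))
                rows.append(
                    {
                        "cluster": c,
                        "descriptor": d,
                        "direction": "higher" if med_c > med_rest else "lower",
                        "max_pairwise_p": max(res.pairwise.loc[c, o] for o in others),
                    }
                )
    return pd.DataFrame(rows, columns=["cluster", "descriptor", "direction", "max_pairwise_p"])
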