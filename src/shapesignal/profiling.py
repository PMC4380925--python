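"""Well aggregation, PCA morphospace, line clustering and feature selection.

Cells are averaged to wells, features are Z-scored ((value − mean)/SD with
population SD), wells/lines are embedded with PCA (first 8 PCs by default)
and grouped by hierarchical clustering with centered-correlation distance
and centroid linkage.  The discriminative subset for the network stage is
chosen by voting: within each line/condition, cells are split into high vs
low TF log-ratio groups and each line votes for every feature that differs
at P < 0.01 (Welch t-test); features are ranked by vote count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .catalog import TF_NODE

__all__ = [
    "well_profiles",
    "pca_scores",
    "MorphospaceModel",
    "cluster_lines",
    "ClusterResult",
    "select_discriminative_features",
]

WELL_KEYS = ["well_id", "line_id", "medium", "treatment"]


def well_profiles(
    cells: pd.DataFrame,
    feature_columns: list[str],
    group_keys: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well feature means and the Z-scored well matrix.

    Z-scoring uses the population SD (ddof=0).  Zero-variance columns cannot
    be scaled; they are excluded from the Z matrix with a warning.
    """
    group_keys = group_keys or [k for k in WELL_KEYS if k in cells.columns]
    if not group_keys:
        raise ValueError("no grouping keys present in the cell table")
    grouped = cells.groupby(group_keys, sort=True, observed=True)
    means = grouped[feature_columns].mean()
    means["n_cells"] = grouped.size()
    kept = []
    z = {}
    for col in feature_columns:
        mu = means[col].mean()
        sd = means[col].std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"feature {col!r} has zero variance across wells; excluded from Z matrix")
            continue
        z[col] = (means[col] - mu) / sd
        kept.append(col)
    zmat = pd.DataFrame(z, index=means.index)[kept]
    return means.reset_index(), zmat


@dataclass
class MorphospaceModel:
    """PCA of the Z-scored well matrix."""

    scores: pd.DataFrame
    loadings: pd.DataFrame          # features × components, orthonormal columns
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray
    feature_names: list[str] = field(default_factory=list)


def pca_scores(zmat: pd.DataFrame, k: int = 8) -> MorphospaceModel:
    """First ``k`` principal components of the Z matrix (covariance PCA).

    Component signs are fixed deterministically (largest-magnitude loading
    positive).  ``k`` greater than the matrix rank is truncated with a
    warning.
    """
    if len(zmat) < 2:
        raise ValueError("PCA needs at least 2 rows")
    X = zmat.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; truncated")
        k = rank
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features × k
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    return MorphospaceModel(
        scores=pd.DataFrame(scores, index=zmat.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=zmat.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_=pca.mean_,
        feature_names=list(zmat.columns),
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    flat_clusters: dict[str, int]
    distance_matrix: pd.DataFrame

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def _centered_correlation_distance(X: np.ndarray) -> np.ndarray:
    """Condensed 1 − Pearson distance over mean-centred row vectors."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms == 0):
        raise ValueError("constant row: correlation undefined")
    C = (Xc / norms[:, None]) @ (Xc / norms[:, None]).T
    D = 1.0 - np.clip(C, -1.0, 1.0)
    iu = np.triu_indices(len(X), k=1)
    return D[iu]


def cluster_lines(
    scores: pd.DataFrame, n_clusters: int | None = None, height: float | None = None
) -> ClusterResult:
    """Hierarchical clustering of score vectors (centered correlation, centroid linkage).

    Rows with constant score vectors (undefined correlation) are excluded
    with a warning.  Flat clusters come from ``n_clusters`` or a cut
    ``height``; with neither, a 4-group cut is used.
    """
    if len(scores) < 2:
        raise ValueError("clustering needs at least 2 rows")
    X = scores.to_numpy(dtype=float)
    keep = np.ptp(X - X.mean(axis=1, keepdims=True), axis=1) > 0
    if not keep.all():
        dropped = [str(i) for i in scores.index[~keep]]
        warnings.warn(f"constant rows excluded from clustering: {dropped}")
    X = X[keep]
    labels = ["|".join(map(str, i)) if isinstance(i, tuple) else str(i) for i in scores.index[keep]]
    dist = _centered_correlation_distance(X)
    Z = hierarchy.linkage(dist, method="centroid")
    if n_clusters is None and height is None:
        n_clusters = min(4, len(labels))
    if n_clusters is not None:
        flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    D = np.zeros((n, n))
    D[iu] = dist
    D += D.T
    return ClusterResult(
        linkage=Z,
        labels=labels,
        flat_clusters=dict(zip(labels, (int(c) for c in flat))),
        distance_matrix=pd.DataFrame(D, index=labels, columns=labels),
    )


def select_discriminative_features(
    cells: pd.DataFrame,
    feature_columns: list[str],
    k: int = 17,
    target: str = TF_NODE,
    group_keys: list[str] | None = None,
    alpha: float = 0.01,
    min_group: int = 10,
) -> tuple[list[str], pd.DataFrame]:
    """Rank features by how many line/conditions separate high vs low TF cells.

    Within each group, cells in the upper vs lower quartile of the TF
    log-ratio are compared per feature with a Welch t-test; a group "votes"
    for the feature when P < ``alpha``.  Returns the top-``k`` features by
    vote count (ties broken by mean |t| then name) and the full vote map.
    """
    group_keys = group_keys or [k_ for k_ in ("line_id", "treatment") if k_ in cells.columns]
    n_groups = 0
    votes = {f: 0 for f in feature_columns}
    tsum = {f: 0.0 for f in feature_columns}
    records = []
    for key, grp in cells.groupby(group_keys, sort=True, observed=True):
        lo_cut, hi_cut = grp[target].quantile([0.25, 0.75])
        lo = grp[grp[target] <= lo_cut]
        hi = grp[grp[target] >= hi_cut]
        if len(lo) < min_group or len(hi) < min_group:
            warnings.warn(f"group {key}: high/low groups too small; skipped")
            continue
        n_groups += 1
        for f in feature_columns:
            a, b = hi[f].to_numpy(), lo[f].to_numpy()
            if np.var(a) == 0 and np.var(b) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            significant = bool(p < alpha)
            votes[f] += significant
            tsum[f] += abs(float(t))
            records.append({"group": str(key), "feature": f, "t": float(t),
                            "p": float(p), "significant": significant})
    if n_groups < 2:
        raise ValueError("need at least 2 usable line/condition groups")
    order = sorted(
        feature_columns,
        key=lambda f: (-votes[f], -tsum[f] / n_groups, f),
    )
    selected = order[: min(k, len(order))]
    return selected, pd.DataFrame(records)
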