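"""Agglomerative clustering of scat compositions with bootstrap uncertainty.

Scats are clustered on the scaled composition matrix with the Ward.D2
criterion on Euclidean distances (Murtagh & Legendre variant, as implemented
by :func:`scipy.cluster.hierarchy.linkage` with ``method='ward'``). The
number of clusters is chosen by majority vote over an internal-validity
index panel, with a fixed-k override. Composition and scat-distribution
percentages carry bootstrap 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .diet import FUNCTIONAL_GROUPS, composition_values

__all__ = [
    "ClusterResult",
    "ward_cluster",
    "select_k",
    "cluster_composition",
    "bootstrap_ci",
    "scat_distribution",
    "tree_to_newick",
    "DEFAULT_YEAR_CLASSES",
]

#: Default 3-year sampling-period bins.
DEFAULT_YEAR_CLASSES = (
    (2002, 2004),
    (2005, 2007),
    (2008, 2010),
    (2011, 2013),
    (2014, 2016),
    (2017, 2019),
)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    k: int
    labels: np.ndarray  # values in 1..k, aligned with matrix rows
    votes: dict[int, dict[str, int]] | None = None


def ward_cluster(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward.D2 agglomerative clustering cut at ``k`` clusters.

    Returns ``(labels, linkage)`` with labels in 1..k. Deterministic for a
    given row order (scipy's nearest-neighbor chain breaks ties by index).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    Z = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        total += ((block - block.mean(axis=0)) ** 2).sum()
    return total


def select_k(
    X: np.ndarray,
    k_range: range | tuple[int, int] = (2, 10),
    fixed_k: int | None = None,
) -> tuple[int, dict]:
    """Choose a cluster number by majority vote over an index panel.

    Panel: silhouette (max), Calinski-Harabasz (max), Davies-Bouldin (min)
    and a within-SS elbow (max second difference of total within-cluster
    sum of squares). Ties break toward smaller k. ``fixed_k`` bypasses the
    vote entirely and is echoed in the report.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if fixed_k is not None:
        return int(fixed_k), {"fixed_k": int(fixed_k)}
    if isinstance(k_range, tuple):
        ks = list(range(k_range[0], k_range[1] + 1))
    else:
        ks = list(k_range)
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("empty candidate k range")
    Z = hierarchy.linkage(X, method="ward")
    all_labels = {k: hierarchy.fcluster(Z, t=k, criterion="maxclust") for k in ks}

    sil = {k: silhouette_score(X, all_labels[k]) for k in ks}
    ch = {k: calinski_harabasz_score(X, all_labels[k]) for k in ks}
    db = {k: davies_bouldin_score(X, all_labels[k]) for k in ks}
    wss = {k: _within_ss(X, all_labels[k]) for k in ks}
    # elbow: largest curvature of the within-SS profile (interior ks only)
    elbow_scores = {}
    for i, k in enumerate(ks):
        if 0 < i < len(ks) - 1:
            elbow_scores[k] = wss[ks[i - 1]] - 2 * wss[k] + wss[ks[i + 1]]
    votes = {
        "silhouette": min(ks, key=lambda k: (-sil[k], k)),
        "calinski_harabasz": min(ks, key=lambda k: (-ch[k], k)),
        "davies_bouldin": min(ks, key=lambda k: (db[k], k)),
    }
    if elbow_scores:
        votes["elbow"] = min(elbow_scores, key=lambda k: (-elbow_scores[k], k))
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    best = min(tally, key=lambda k: (-tally[k], k))
    report = {"votes": votes, "tally": tally, "indices": {"silhouette": sil, "ch": ch, "db": db}}
    return int(best), report


def cluster_composition(
    labels: np.ndarray, matrix: pd.DataFrame, bootstrap: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Percent of total prey mass by functional group, per cluster x species.

    Uses the unscaled composition matrix. For every cluster and species the
    member scats' group masses are summed and divided by their total
    (x100). Bootstrap CI95 resamples member scats with replacement
    ``bootstrap`` times. Empty cluster x species cells are reported as NaN.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    X = composition_values(matrix)
    species = matrix["species"].to_numpy()
    rows = []
    for lab in np.unique(labels):
        for sp in np.unique(species):
            mask = (labels == lab) & (species == sp)
            block = X[mask]
            for gi, group in enumerate(FUNCTIONAL_GROUPS):
                if block.shape[0] == 0:
                    rows.append(
                        {"cluster": int(lab), "species": sp, "group": group,
                         "pct_mass": np.nan, "lo": np.nan, "hi": np.nan, "n_scats": 0}
                    )
                    continue
                point = 100.0 * block[:, gi].sum() / block.sum()
                if bootstrap:
                    stats = np.empty(bootstrap)
                    n = block.shape[0]
                    for b in range(bootstrap):
                        idx = rng.integers(0, n, size=n)
                        res = block[idx]
                        stats[b] = 100.0 * res[:, gi].sum() / res.sum()
                    lo, hi = np.percentile(stats, [2.5, 97.5])
                else:
                    lo = hi = np.nan
                rows.append(
                    {"cluster": int(lab), "species": sp, "group": group,
                     "pct_mass": point, "lo": lo, "hi": hi, "n_scats": int(block.shape[0])}
                )
    return pd.DataFrame(rows)


def bootstrap_ci(
    values: np.ndarray,
    statistic,
    B: int = 1000,
    seed: int | None = None,
    return_samples: bool = False,
):
    """Percentile-bootstrap CI95 of ``statistic`` over rows of ``values``.

    Resamples the N rows with replacement B times, recomputes the statistic
    each time, and returns the empirical 2.5/97.5 percentiles per component.
    """
    values = np.asarray(values)
    n = values.shape[0]
    if n < 1:
        raise ValueError("need at least one observation")
    rng = np.random.default_rng(seed)
    samples = np.array([statistic(values[rng.integers(0, n, size=n)]) for _ in range(B)])
    lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
    if return_samples:
        return lo, hi, samples
    return lo, hi


def scat_distribution(
    labels: np.ndarray,
    matrix: pd.DataFrame,
    by_stratum: bool = False,
    year_classes=DEFAULT_YEAR_CLASSES,
    min_scats: int = 8,
    bootstrap: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Percent of scats per cluster (per species), with bootstrap CI95.

    With ``by_stratum=True`` the percentages are computed per
    species x season x year-class stratum and strata with fewer than
    ``min_scats`` scats are suppressed (with a notice).
    """
    labels = np.asarray(labels)
    k_levels = np.unique(labels)
    rng = np.random.default_rng(seed)
    df = matrix.copy()
    df["_label"] = labels
    if by_stratum:
        years = pd.to_datetime(df["date"]).dt.year
        yc = pd.Series("", index=df.index, dtype=object)
        for lo, hi in year_classes:
            yc[(years >= lo) & (years <= hi)] = f"{lo}-{hi}"
        df["_stratum_year"] = yc
        group_cols = ["species", "season", "_stratum_year"]
    else:
        group_cols = ["species"]

    rows = []
    for key, block in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(block)
        if by_stratum and n < min_scats:
            warnings.warn(
                f"stratum {key} suppressed: {n} scats < {min_scats}", stacklevel=2
            )
            continue
        labs = block["_label"].to_numpy()

        def pct_per_cluster(resampled_labels):
            return np.array(
                [100.0 * (resampled_labels == lab).mean() for lab in k_levels]
            )

        point = pct_per_cluster(labs)
        if bootstrap:
            lo, hi = bootstrap_ci(labs, pct_per_cluster, B=bootstrap, seed=rng.integers(2**31))
        else:
            lo = hi = np.full(len(k_levels), np.nan)
        for lab, p, l, h in zip(k_levels, point, lo, hi):
            row = dict(zip([c.lstrip("_") for c in group_cols], key))
            row.update({"cluster": int(lab), "pct_scats": p, "lo": l, "hi": h, "n_scats": n})
            rows.append(row)
    return pd.DataFrame(rows)


def tree_to_newick(Z: np.ndarray, leaf_names=None) -> str:
    """Newick text export of a scipy linkage tree (branch lengths = merge
    height differences)."""
    tree = hierarchy.to_tree(Z)
    n = tree.get_count()
    if leaf_names is None:
        leaf_names = [f"scat{i}" for i in range(n)]

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.get_left(), tree.dist)},{render(tree.get_right(), tree.dist)});"
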