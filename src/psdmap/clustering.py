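"""Replicate-aware k-means clustering of expression profiles.

Genes are clustered on their condition-mean profiles with the Pearson
correlation distance d = 1 - r.  Profiles are standardized to zero mean and
unit norm across conditions, under which d equals half the squared
Euclidean distance, so a spherical k-means (centroids re-standardized every
iteration) minimizes the total Pearson dispersion directly.  Biological
replicates enter as optional per-gene weights proportional to the inverse
mean within-condition variance: noisier genes pull centroids less.

k is user-chosen; :func:`scan_k` reports dispersion and silhouette over a
range to support that choice but never auto-selects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

__all__ = [
    "ProfileSet",
    "Clustering",
    "build_profiles",
    "cluster_profiles",
    "scan_k",
    "summarize_clusters",
    "plot_cluster_profiles",
]


@dataclass
class ProfileSet:
    """Per-gene condition-mean profiles with replicate information."""

    genes: list[str]
    conditions: list[str]
    means: pd.DataFrame  # genes x conditions
    se: pd.DataFrame  # standard error of each condition mean
    standardized: pd.DataFrame  # zero-mean unit-norm rows (clusterable genes)
    weights: pd.Series  # inverse mean within-condition variance
    flagged_constant: list[str]  # genes with zero variance across conditions

    def __len__(self) -> int:
        return len(self.genes)


def build_profiles(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
) -> ProfileSet:
    """Condition means, standard errors and standardized profiles.

    Genes whose profile is constant across conditions cannot be
    standardized; they are flagged (``flagged_constant``) and excluded from
    ``standardized``, never silently dropped from the profile tables.
    """
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in matrix.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        matrix = matrix.loc[list(gene_subset)]
    conditions = list(dict.fromkeys(design["condition"]))
    means = {}
    ses = {}
    within_var = {}
    for cond in conditions:
        samples = design.loc[design["condition"] == cond, "sample"]
        if len(samples) == 0:
            raise ValueError(f"condition {cond!r} has zero replicates")
        block = matrix[list(samples)]
        means[cond] = block.mean(axis=1)
        ses[cond] = block.std(axis=1, ddof=1) / np.sqrt(len(samples)) \
            if len(samples) > 1 else pd.Series(0.0, index=matrix.index)
        within_var[cond] = block.var(axis=1, ddof=1) if len(samples) > 1 \
            else pd.Series(0.0, index=matrix.index)
    means_df = pd.DataFrame(means)[conditions]
    se_df = pd.DataFrame(ses)[conditions]
    mean_var = pd.DataFrame(within_var)[conditions].mean(axis=1)
    floor = max(float(mean_var[mean_var > 0].min()) if (mean_var > 0).any()
                else 1.0, 1e-12)
    weights = 1.0 / mean_var.clip(lower=floor)

    centered = means_df.sub(means_df.mean(axis=1), axis=0)
    norms = np.sqrt((centered**2).sum(axis=1))
    ok = norms > 1e-12
    standardized = centered.loc[ok].div(norms[ok], axis=0)
    flagged = list(means_df.index[~ok])
    return ProfileSet(
        genes=list(matrix.index),
        conditions=conditions,
        means=means_df,
        se=se_df,
        standardized=standardized,
        weights=weights,
        flagged_constant=flagged,
    )


@dataclass
class Clustering:
    """A k-means partition of standardized profiles."""

    k: int
    assignment: pd.Series  # gene -> cluster id (0..k-1)
    centroids: pd.DataFrame  # k x conditions, standardized
    dispersion: float  # total weighted within-cluster Pearson distance
    seed: int
    n_restarts: int

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def _kmeans_once(
    X: np.ndarray,
    w: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    if init is None:
        centroids = X[rng.choice(n, size=k, replace=False)].copy()
    else:
        centroids = init.copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        D = 1.0 - X @ centroids.T  # Pearson distance to each centroid
        new_labels = D.argmin(axis=1)
        # re-seed empty clusters at the worst-fit point
        for j in range(k):
            if not (new_labels == j).any():
                worst = (D[np.arange(n), new_labels]).argmax()
                centroids[j] = X[worst]
                new_labels[worst] = j
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            members = labels == j
            centroids[j] = np.average(X[members], axis=0,
                                      weights=w[members])
        centroids = _standardize_rows(centroids)
    D = 1.0 - X @ centroids.T
    dispersion = float((w * D[np.arange(n), labels]).sum())
    return labels, centroids, dispersion


def cluster_profiles(
    profiles: ProfileSet,
    k: int,
    seed: int = 0,
    weighted: bool = True,
    n_init: int = 50,
    max_iter: int = 100,
    _extra_init: np.ndarray | None = None,
) -> Clustering:
    """Best-of-restarts spherical k-means under the Pearson distance.

    Deterministic given ``seed``; ``weighted=False`` ignores replicate
    variances and weighs all genes equally.
    """
    X = profiles.standardized.to_numpy(dtype=float)
    genes = list(profiles.standardized.index)
    n = len(genes)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in 1..{n}")
    w = (
        profiles.weights.loc[genes].to_numpy(dtype=float)
        if weighted
        else np.ones(n)
    )
    rng = np.random.default_rng(seed)
    best = None
    inits: list[np.ndarray | None] = [None] * n_init
    if _extra_init is not None:
        inits.append(_extra_init)
    for init in inits:
        labels, centroids, disp = _kmeans_once(X, w, k, rng, max_iter, init)
        if best is None or disp < best[2] - 1e-12:
            best = (labels, centroids, disp)
    labels, centroids, disp = best
    return Clustering(
        k=k,
        assignment=pd.Series(labels, index=genes, name="cluster"),
        centroids=pd.DataFrame(centroids, columns=profiles.conditions),
        dispersion=disp,
        seed=seed,
        n_restarts=len(inits),
    )


def scan_k(
    profiles: ProfileSet,
    k_range: Sequence[int],
    seed: int = 0,
    weighted: bool = True,
    n_init: int = 50,
) -> pd.DataFrame:
    """Dispersion and mean silhouette for each k in ``k_range``.

    Each k is additionally warm-started from the previous best solution
    (its centroids plus the worst-fit profile), which makes the reported
    best dispersion non-increasing in k.  The table guides the user's
    choice of k; nothing is auto-selected.
    """
    ks = sorted(set(int(k) for k in k_range))
    X = profiles.standardized.to_numpy(dtype=float)
    n = X.shape[0]
    D = np.clip(1.0 - X @ X.T, 0.0, None)
    np.fill_diagonal(D, 0.0)
    rows = []
    prev: Clustering | None = None
    for k in ks:
        extra = None
        if prev is not None and prev.k < k <= n:
            labels = prev.assignment.to_numpy()
            cent = prev.centroids.to_numpy()
            d_own = 1.0 - np.einsum("ij,ij->i", X, cent[labels])
            extra_pts = X[np.argsort(-d_own)[: k - prev.k]]
            extra = np.vstack([cent, extra_pts])
        clu = cluster_profiles(
            profiles, k, seed=seed, weighted=weighted, n_init=n_init,
            _extra_init=extra,
        )
        if 2 <= k <= n - 1:
            sil = float(silhouette_score(
                D, clu.assignment.to_numpy(), metric="precomputed"
            ))
        else:
            sil = float("nan")
        rows.append({"k": k, "dispersion": clu.dispersion,
                     "silhouette": sil})
        prev = clu
    return pd.DataFrame(rows).set_index("k")


def summarize_clusters(
    clustering: Clustering, profiles: ProfileSet
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Per-cluster mean +/- sd of the condition-mean profiles.

    Returns a tidy table (cluster, condition, mean, sd, n_genes) and the
    member gene names per cluster.  The sd is the population spread of
    member profiles (ddof=0), so a singleton cluster has sd 0.
    """
    rows = []
    members: dict[int, list[str]] = {}
    for cid in sorted(clustering.assignment.unique()):
        genes = list(clustering.assignment.index[clustering.assignment == cid])
        members[int(cid)] = genes
        block = profiles.means.loc[genes]
        for cond in profiles.conditions:
            rows.append({
                "cluster": int(cid),
                "condition": cond,
                "mean": float(block[cond].mean()),
                "sd": float(block[cond].std(ddof=0)),
                "n_genes": len(genes),
            })
    return pd.DataFrame(rows), members


def plot_cluster_profiles(
    clustering: Clustering, profiles: ProfileSet, path: str
) -> str:
    """Ribbon plot (mean +/- sd per condition) for every cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary, members = summarize_clusters(clustering, profiles)
    k = clustering.k
    ncol = min(4, k)
    nrow = (k + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             squeeze=False, sharex=True)
    x = np.arange(len(profiles.conditions))
    for cid, ax in zip(sorted(members), axes.ravel()):
        sub = summary[summary["cluster"] == cid]
        ax.plot(x, sub["mean"], marker="o", lw=1.5)
        ax.fill_between(x, sub["mean"] - sub["sd"], sub["mean"] + sub["sd"],
                        alpha=0.3)
        ax.set_title(f"cluster {cid} (n={len(members[cid])})", fontsize=8)
        ax.set_xticks(x, profiles.conditions, rotation=60, fontsize=6)
    for ax in axes.ravel()[len(members):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
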