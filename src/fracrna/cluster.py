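"""K-means clustering of log2 expression-ratio profiles.

Genes detected in every relevant library are represented by their log2
differential-expression ratios (condition vs a reference such as the wild
type), clustered by K-means under Euclidean dissimilarity (k-means++
initialisation, best of several restarts), with the Davies-Bouldin index
used to choose the number of clusters and single-gene clusters merged into
the nearest remaining cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Labels (1-based, Series over gene ids), centroids (K x features),
    the Davies-Bouldin index of the partition, and a merge log."""

    labels: pd.Series
    centroids: np.ndarray
    k: int
    davies_bouldin: float
    inertia: float
    merge_log: list = field(default_factory=list)


def log2_ratio_matrix(rpkm: pd.DataFrame, conditions: list[str],
                      reference: str, min_rpkm: float = 1.0) -> pd.DataFrame:
    """log2(RPKM_condition / RPKM_reference) over genes detected everywhere.

    A gene is kept only if its RPKM reaches ``min_rpkm`` in the reference
    and in every condition library.
    """
    if reference not in rpkm.columns:
        raise KeyError(f"reference {reference!r} not in RPKM table")
    cols = [reference] + [c for c in conditions if c != reference]
    detected = (rpkm[cols] >= min_rpkm).all(axis=1)
    if not detected.any():
        raise ValueError("no gene detected in all relevant libraries")
    sub = rpkm.loc[detected]
    out = pd.DataFrame(
        {c: np.log2(sub[c] / sub[reference]) for c in conditions},
        index=sub.index,
    )
    return out


def kmeans_cluster(matrix: pd.DataFrame, k: int = 5, seed: int = 0,
                   n_restarts: int = 20) -> ClusterResult:
    """Lloyd's K-means under Euclidean distance, k-means++, best of restarts."""
    x = np.asarray(matrix, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(x):
        raise ValueError(f"k={k} exceeds the {len(x)} genes available")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed).fit(x)
    labels = pd.Series(km.labels_ + 1, index=matrix.index, name="cluster")
    db = davies_bouldin(matrix, labels)
    return ClusterResult(labels, km.cluster_centers_, k, db,
                         float(km.inertia_))


def davies_bouldin(matrix: pd.DataFrame, labels: pd.Series) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (S_i + S_j) / M_ij, with S the mean intra-cluster distance to the
    centroid and M the Euclidean centroid separation.

    Two coincident centroids make the index +inf (degenerate partition).
    """
    x = np.asarray(matrix, float)
    lab = np.asarray(labels)
    names = np.unique(lab)
    if len(names) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    cents, scatters = [], []
    for c in names:
        pts = x[lab == c]
        if len(pts) == 0:
            raise ValueError(f"cluster {c} is empty")
        mu = pts.mean(axis=0)
        cents.append(mu)
        scatters.append(np.linalg.norm(pts - mu, axis=1).mean())
    cents = np.asarray(cents)
    k = len(names)
    worst = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            m = np.linalg.norm(cents[i] - cents[j])
            r = np.inf if m == 0 else (scatters[i] + scatters[j]) / m
            worst[i] = max(worst[i], r)
    return float(worst.mean())


def select_k(matrix: pd.DataFrame, k_range=range(2, 11), seed: int = 0,
             n_restarts: int = 20) -> tuple[int, pd.DataFrame]:
    """Choose K as the smallest local minimum of the Davies-Bouldin profile.

    Automates the usual manual inspection: K at an interior local minimum
    of DB(K), the smallest such K; a monotonically decreasing profile
    yields the largest K in range, flagged in the log. The full profile is
    returned so a user can override the choice.
    """
    ks = list(k_range)
    profile = []
    for k in ks:
        res = kmeans_cluster(matrix, k=k, seed=seed, n_restarts=n_restarts)
        profile.append(res.davies_bouldin)
    chosen = choose_k_from_profile(ks, profile)
    return chosen, pd.DataFrame({"k": ks, "davies_bouldin": profile})


def choose_k_from_profile(ks: list[int], profile: list[float]) -> int:
    """Smallest K at a local minimum of the DB profile.

    A local minimum must improve on its left neighbour and not be worse
    than its right one; a monotone decreasing profile has no interior
    minimum and yields the largest K, flagged in the log.
    """
    chosen = None
    for i, k in enumerate(ks):
        interior_min = 0 < i and profile[i] < profile[i - 1] and \
            (i == len(ks) - 1 or profile[i] < profile[i + 1])
        if interior_min:
            chosen = k
            break
    if chosen is None:
        chosen = ks[int(np.argmin(profile))]
    if np.all(np.diff(profile) < 0):
        logger.warning("DB profile monotone decreasing: taking largest k=%d",
                       chosen)
    return chosen


def merge_singletons(result: ClusterResult, matrix: pd.DataFrame) -> ClusterResult:
    """Merge every single-gene cluster into the nearest-centroid cluster.

    Ties go to the lower-numbered cluster and are logged. Labels are
    renumbered 1..K'; centroids and the Davies-Bouldin index are
    recomputed. Raises if every cluster is a singleton.
    """
    labels = result.labels.copy()
    sizes = labels.value_counts()
    singles = sorted(sizes[sizes == 1].index)
    if len(singles) == len(sizes):
        raise ValueError("all clusters are singletons: no merge target")
    x = np.asarray(matrix, float)
    log = list(result.merge_log)
    for c in singles:
        others = sorted(set(labels.unique()) - {c})
        gene = labels.index[labels == c][0]
        point = x[matrix.index.get_loc(gene)]
        cents = {o: x[np.asarray(labels) == o].mean(axis=0) for o in others}
        dists = {o: np.linalg.norm(point - cents[o]) for o in others}
        best = min(dists, key=lambda o: (dists[o], o))
        tied = [o for o in others if np.isclose(dists[o], dists[best])]
        if len(tied) > 1:
            logger.info("singleton %s equidistant to clusters %s: merging into %d",
                        gene, tied, best)
        log.append({"gene": str(gene), "from": int(c), "into": int(best),
                    "distance": float(dists[best])})
        labels.loc[gene] = best
    remaining = sorted(labels.unique())
    remap = {old: new for new, old in enumerate(remaining, start=1)}
    labels = labels.map(remap)
    k = len(remaining)
    cents = np.vstack([x[np.asarray(labels) == c].mean(axis=0)
                       for c in range(1, k + 1)])
    wcss = sum(
        float(((x[np.asarray(labels) == c] - cents[c - 1]) ** 2).sum())
        for c in range(1, k + 1)
    )
    db = davies_bouldin(matrix, labels) if k >= 2 else float("nan")
    return ClusterResult(labels, cents, k, db, wcss, log)
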