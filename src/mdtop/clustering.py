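"""Conformational clustering of RMSD matrices and internal validation.

Three clustering routes operate directly on a pairwise RMSD matrix:

* **k-medoids (PAM)** — random initial medoids, assignment to the nearest
  medoid, then repeated best-improving medoid/non-medoid swaps until the
  medoid set is stable; the cost is the within-cluster sum of squared
  member→medoid distances (variance-like), and the best of several seeded
  restarts is kept.
* **GROMOS peeling** — the frame with the most neighbours within a distance
  cutoff becomes the next cluster centroid and is removed from the pool with
  all its neighbours; the cluster count is not fixed and singletons are
  allowed.
* **average linkage** — agglomerative merging by mean inter-cluster distance
  until no pair lies below the cutoff.

Validation of a cluster-count scan uses the elbow (WSS), the Dunn index
(minimal inter-centroid separation over maximal intra-cluster diameter;
maximum marks the best count) and the Davies-Bouldin index (mean worst-case
dispersion-to-separation ratio; minimum marks the best count).  Because only
the distance matrix is available, all "centroid" distances are medoid-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import UsageError
from .superpose import DistanceMatrix

__all__ = [
    "ClusterModel",
    "kmedoids",
    "gromos_cluster",
    "average_linkage",
    "wss",
    "dunn_index",
    "davies_bouldin",
    "ValidationScores",
    "scan_k",
    "contingency",
    "count_transitions",
]


@dataclass(eq=False)
class ClusterModel:
    """Frame→cluster labels plus a medoid frame per cluster."""

    labels: np.ndarray  # (n,) cluster ids 0..k-1
    medoids: np.ndarray  # (k,) frame index per cluster
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.medoids = np.asarray(self.medoids, dtype=int)
        for c, m in enumerate(self.medoids):
            if self.labels[m] != c:
                raise UsageError(f"medoid {m} is not a member of cluster {c}")

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def to_frame(self, provenance: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"frame": np.arange(len(self.labels)), "cluster": self.labels}
        )
        if provenance is not None:
            df = pd.concat([df, provenance.reset_index(drop=True)], axis=1)
        return df


def _matrix(matrix) -> np.ndarray:
    if isinstance(matrix, DistanceMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def _sorted_by_size(labels: np.ndarray, medoids: np.ndarray) -> ClusterModel:
    """Relabel clusters by decreasing size (ties: lower medoid index first)."""
    sizes = np.bincount(labels, minlength=len(medoids))
    order = sorted(range(len(medoids)), key=lambda c: (-sizes[c], medoids[c]))
    remap = {old: new for new, old in enumerate(order)}
    new_labels = np.array([remap[c] for c in labels])
    new_medoids = np.array([medoids[c] for c in order])
    return new_labels, new_medoids


def _pam_single(D2: np.ndarray, k: int, rng: np.random.Generator):
    """One PAM run on a squared-distance matrix; returns (medoids, cost)."""
    n = D2.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    while True:
        dist = D2[:, medoids]  # (n, k)
        nearest = np.argmin(dist, axis=1)
        d1 = dist[np.arange(n), nearest]
        cost = d1.sum()
        if k > 1:
            part = np.partition(dist, 1, axis=1)
            d2 = part[:, 1]
        else:
            d2 = np.full(n, np.inf)
        best = (cost, None)
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        for mi in range(k):
            base = np.where(nearest == mi, d2, d1)
            cand_cost = np.minimum(base[:, None], D2).sum(axis=0)
            cand_cost[in_medoids] = np.inf
            h = int(np.argmin(cand_cost))
            if cand_cost[h] < best[0] - 1e-12:
                best = (cand_cost[h], (mi, h))
        if best[1] is None:
            return medoids, cost
        mi, h = best[1]
        medoids = np.sort(np.concatenate([np.delete(medoids, mi), [h]]))


def kmedoids(
    matrix, k: int, seed: int = 0, restarts: int = 10
) -> ClusterModel:
    """PAM k-medoids on an RMSD matrix, best of ``restarts`` seeded runs."""
    D = _matrix(matrix)
    n = D.shape[0]
    if not 2 <= k <= n:
        raise UsageError(f"k={k} outside [2, {n}]")
    D2 = D**2
    root = np.random.SeedSequence(seed)
    best_cost, best_medoids = np.inf, None
    for child in root.spawn(restarts):
        medoids, cost = _pam_single(D2, k, np.random.default_rng(child))
        if cost < best_cost - 1e-12:
            best_cost, best_medoids = cost, medoids
    labels_raw = np.argmin(D2[:, best_medoids], axis=1)
    # medoids belong to their own cluster even under distance ties
    labels_raw[best_medoids] = np.arange(k)
    labels, medoids = _sorted_by_size(labels_raw, best_medoids)
    return ClusterModel(
        labels=labels,
        medoids=medoids,
        method="kmedoids",
        params={"k": k, "seed": seed, "restarts": restarts, "cost": best_cost},
    )


def gromos_cluster(matrix, cutoff: float) -> ClusterModel:
    """GROMOS neighbour-peeling clustering.

    Neighbourhood uses a strict ``distance < cutoff`` criterion; ties on
    neighbour counts break to the lowest frame index.  Clusters are labelled
    in extraction order (largest first by construction of the greedy step).
    """
    if cutoff <= 0:
        raise UsageError("cutoff must be positive")
    D = _matrix(matrix)
    n = D.shape[0]
    adj = (D < cutoff) & ~np.eye(n, dtype=bool)
    remaining = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    medoids = []
    cluster = 0
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))
        members = np.flatnonzero((adj[center] & remaining) | (np.arange(n) == center))
        labels[members] = cluster
        medoids.append(center)
        remaining[members] = False
        cluster += 1
    return ClusterModel(
        labels=labels,
        medoids=np.array(medoids),
        method="gromos",
        params={"cutoff": cutoff},
    )


def _medoid_of(D: np.ndarray, members: np.ndarray) -> int:
    sub = D[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])


def average_linkage(matrix, cutoff: float) -> ClusterModel:
    """Agglomerative average-linkage clustering cut at a distance threshold."""
    if cutoff <= 0:
        raise UsageError("cutoff must be positive")
    D = _matrix(matrix)
    n = D.shape[0]
    Z = linkage(squareform(D, checks=False), method="average")
    flat = fcluster(Z, t=cutoff, criterion="distance") - 1
    ids = np.unique(flat)
    medoids_raw = np.array([_medoid_of(D, np.flatnonzero(flat == c)) for c in ids])
    labels_raw = np.searchsorted(ids, flat)
    labels, medoids = _sorted_by_size(labels_raw, medoids_raw)
    return ClusterModel(
        labels=labels,
        medoids=medoids,
        method="average_linkage",
        params={"cutoff": cutoff},
    )


def wss(matrix, model: ClusterModel) -> float:
    """Within-cluster sum of squared member→medoid distances."""
    D = _matrix(matrix)
    total = 0.0
    for c in range(model.n_clusters):
        total += float((D[model.members(c), model.medoids[c]] ** 2).sum())
    return total


def dunn_index(matrix, model: ClusterModel) -> float:
    """Minimal inter-centroid separation / maximal intra-cluster diameter.

    Higher is better; a maximum over a cluster-count scan marks the most
    probable count.  If every cluster has zero diameter but separations are
    positive the partition is perfectly separated and +inf is returned.
    """
    D = _matrix(matrix)
    k = model.n_clusters
    if k < 2:
        raise UsageError("Dunn index needs at least 2 clusters")
    seps = [
        D[model.medoids[i], model.medoids[j]]
        for i in range(k)
        for j in range(i + 1, k)
    ]
    diams = []
    for c in range(k):
        m = model.members(c)
        diams.append(float(D[np.ix_(m, m)].max()) if m.size > 1 else 0.0)
    min_sep, max_diam = min(seps), max(diams)
    if max_diam == 0.0:
        return np.inf if min_sep > 0 else 0.0
    return float(min_sep / max_diam)


def davies_bouldin(matrix, model: ClusterModel) -> float:
    """Mean over clusters of the worst (d_i + d_j) / d_ij ratio.

    d_i is the mean member→medoid distance of cluster i and d_ij the
    medoid-to-medoid distance; lower is better.
    """
    D = _matrix(matrix)
    k = model.n_clusters
    if k < 2:
        raise UsageError("Davies-Bouldin index needs at least 2 clusters")
    d = np.array(
        [D[model.members(c), model.medoids[c]].mean() for c in range(k)]
    )
    total = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            sep = D[model.medoids[i], model.medoids[j]]
            if sep == 0.0:
                raise UsageError(
                    f"coincident medoids for clusters {i} and {j}"
                )
            worst = max(worst, (d[i] + d[j]) / sep)
        total += worst
    return float(total / k)


@dataclass(eq=False)
class ValidationScores:
    """Scan results: one row per candidate cluster count."""

    table: pd.DataFrame  # columns: k, wss, dunn, davies_bouldin, sizes
    models: dict[int, ClusterModel]

    def best_by_dunn(self) -> int:
        return int(self.table.loc[self.table["dunn"].idxmax(), "k"])

    def best_by_davies_bouldin(self) -> int:
        return int(self.table.loc[self.table["davies_bouldin"].idxmin(), "k"])

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["sizes"] = df["sizes"].map(lambda s: ",".join(map(str, s)))
        df.to_csv(path, sep="\t", index=False)


def scan_k(
    matrix, k_range, seed: int = 0, restarts: int = 10
) -> ValidationScores:
    """k-medoids scan over candidate cluster counts with WSS/DI/DBI per k."""
    D = _matrix(matrix)
    rows, models = [], {}
    for k in k_range:
        model = kmedoids(D, k, seed=seed, restarts=restarts)
        rows.append(
            {
                "k": k,
                "wss": wss(D, model),
                "dunn": dunn_index(D, model),
                "davies_bouldin": davies_bouldin(D, model),
                "sizes": tuple(int(s) for s in model.sizes()),
            }
        )
        models[k] = model
    return ValidationScores(table=pd.DataFrame(rows), models=models)


def contingency(model: ClusterModel, provenance: pd.DataFrame) -> pd.DataFrame:
    """System × cluster frame-count table."""
    if len(provenance) != len(model.labels):
        raise UsageError("provenance does not cover all frames")
    return pd.crosstab(
        provenance["system"], pd.Series(model.labels, name="cluster")
    )


def count_transitions(
    model: ClusterModel, provenance: pd.DataFrame
) -> np.ndarray:
    """Cluster×cluster transition counts between consecutive frames.

    Transitions are counted only between time-consecutive frames of the same
    (system, source) pair — never across concatenation boundaries.  Diagonal
    entries count frames that stayed in their cluster.
    """
    if len(provenance) != len(model.labels):
        raise UsageError("provenance does not cover all frames")
    k = model.n_clusters
    trans = np.zeros((k, k), dtype=int)
    df = provenance.reset_index(drop=True).copy()
    df["label"] = model.labels
    for _, group in df.groupby(["system", "source"], sort=False):
        lab = group.sort_values("time_ps")["label"].to_numpy()
        for a, b in zip(lab[:-1], lab[1:]):
            trans[a, b] += 1
    return trans
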