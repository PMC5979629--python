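"""Oceanographic barrier detection by connectivity-constrained clustering.

Partially isolated clusters are found by greedy agglomerative merging on a
(max-)symmetrized dispersal matrix: starting from a fine partition,
repeatedly merge the cluster pair with the highest mean inter-cluster
connectivity while that mean still exceeds the allowed between-cluster
threshold.  The returned partition is the first one at which every
remaining inter-cluster mean connectivity is at or below the threshold;
cluster boundaries between adjacent cells then trace the dispersal
barriers.

For large systems an optional spectral embedding (top eigenvectors of the
normalized connectivity graph, k-means initialized from the embedding)
provides the fine starting partition; by default every element starts in
its own cluster, which is exact and deterministic on the site-level
matrices this is typically applied to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from seaconn.lagrangian import DispersalMatrix

__all__ = ["ClusterPartition", "cluster_barriers"]


@dataclass
class ClusterPartition:
    """Cluster labels with within/between connectivity diagnostics."""

    labels: list[str]
    cluster: np.ndarray  # int id per label
    threshold: float
    within_mean: float
    between_mean: float

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lab, c in zip(self.labels, self.cluster):
            out.setdefault(int(c), []).append(lab)
        return out

    def as_sets(self) -> list[frozenset]:
        return [frozenset(v) for v in self.members().values()]


def _pair_mean(S: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return float(S[np.ix_(a, b)].mean())


def _spectral_fine_partition(S: np.ndarray, k: int, seed: int | None) -> np.ndarray:
    """k-means on the top eigenvectors of the symmetrically normalized
    connectivity matrix; deterministic for a seed."""
    d = S.sum(axis=1)
    d[d == 0] = 1.0
    Dn = 1.0 / np.sqrt(d)
    A = Dn[:, None] * S * Dn[None, :]
    w, v = np.linalg.eigh(A)
    emb = v[:, -k:] * np.abs(w[-k:])  # eigenvalue weighting favours coarse structure
    rng = np.random.default_rng(seed)
    # k-means++ seeding keeps well-separated embedding clusters apart
    centers = [emb[rng.integers(len(emb))]]
    for _ in range(k - 1):
        d2 = np.min(
            [((emb - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        if d2.sum() == 0:
            centers.append(emb[rng.integers(len(emb))])
            continue
        centers.append(emb[rng.choice(len(emb), p=d2 / d2.sum())])
    centers = np.array(centers)
    assign = np.zeros(len(emb), dtype=int)
    for _ in range(50):
        dist = ((emb[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new = dist.argmin(axis=1)
        if (new == assign).all():
            break
        assign = new
        for c in range(k):
            if (assign == c).any():
                centers[c] = emb[assign == c].mean(axis=0)
    # compact ids
    _, assign = np.unique(assign, return_inverse=True)
    return assign


def cluster_barriers(
    M: DispersalMatrix | np.ndarray,
    between_threshold: float = 0.004,
    seed: int | None = None,
    labels: list[str] | None = None,
    init_clusters: int | None = None,
) -> ClusterPartition:
    """Partition into clusters whose mutual mean connectivity is at most
    ``between_threshold``.

    Connectivity in either direction counts, so the directed matrix is
    symmetrized with the elementwise maximum before clustering; the reported
    within/between means are computed on the input matrix.  A uniform,
    fully connected matrix collapses to a single cluster (with a notice).
    """
    if between_threshold <= 0:
        raise ValueError("between_threshold must be positive")
    if isinstance(M, DispersalMatrix):
        values = M.values
        labels = list(M.labels)
    else:
        values = np.asarray(M, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(values.shape[0])]
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if np.nanmin(values) < 0:
        raise ValueError("matrix must be non-negative")
    values = np.nan_to_num(values, nan=0.0)
    n = values.shape[0]
    S = np.maximum(values, values.T)

    if init_clusters is not None and init_clusters < n:
        assign = _spectral_fine_partition(S, init_clusters, seed)
    else:
        assign = np.arange(n)

    clusters: dict[int, np.ndarray] = {
        c: np.flatnonzero(assign == c) for c in np.unique(assign)
    }
    while len(clusters) > 1:
        ids = sorted(clusters)
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                m = _pair_mean(S, clusters[a], clusters[b])
                if best is None or m > best[0]:
                    best = (m, a, b)
        assert best is not None
        if best[0] <= between_threshold:
            break
        _, a, b = best
        clusters[a] = np.concatenate([clusters[a], clusters[b]])
        del clusters[b]

    if len(clusters) == 1:
        warnings.warn("matrix is fully connected above the threshold; single cluster")

    cluster_ids = np.empty(n, dtype=int)
    for new_id, (_, members) in enumerate(sorted(clusters.items())):
        cluster_ids[members] = new_id

    off = ~np.eye(n, dtype=bool)
    same = cluster_ids[:, None] == cluster_ids[None, :]
    within_vals = values[off & same]
    between_vals = values[off & ~same]
    within_mean = float(within_vals.mean()) if within_vals.size else float("nan")
    between_mean = float(between_vals.mean()) if between_vals.size else float("nan")
    return ClusterPartition(
        labels=labels,
        cluster=cluster_ids,
        threshold=between_threshold,
        within_mean=within_mean,
        between_mean=between_mean,
    )
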