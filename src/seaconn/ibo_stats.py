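"""Isolation by distance and by oceanography: sea distances and Mantel tests.

``sea_distance`` measures the shortest over-water path between sites on the
seascape lattice (8-connected Dijkstra, diagonal steps cost sqrt(2) times
the cell size), so land is never crossed.  ``mantel`` correlates two
symmetric labelled matrices over their off-diagonal pairs with a
row/column-permutation null; ``asymmetric_mantel`` does the same for
directed matrices, keeping A_ij and A_ji as distinct observations under a
joint permutation of both axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from seaconn.genotypes import DistanceMatrix
from seaconn.seascape_sim import KM_PER_DEG_LAT, SeascapeGrid

__all__ = ["MantelResult", "sea_distance", "mantel", "asymmetric_mantel"]


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    transform: str = ""
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("correlation out of range")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")


# ---------------------------------------------------------------------------
# sea distance
# ---------------------------------------------------------------------------


def _lonlat_to_cell(grid: SeascapeGrid, lon: float, lat: float) -> tuple[float, float]:
    iy = (lat - grid.lat0) * KM_PER_DEG_LAT / grid.cell_size_km - 0.5
    ix = (lon - grid.lon0) * KM_PER_DEG_LAT * np.cos(np.deg2rad(lat)) / grid.cell_size_km - 0.5
    return iy, ix


def _sea_graph(grid: SeascapeGrid):
    """Sparse 8-connected graph over sea cells; returns (graph, cell->node)."""
    ny, nx = grid.ny, grid.nx
    node = -np.ones((ny, nx), dtype=int)
    ys, xs = np.nonzero(grid.sea_mask)
    node[ys, xs] = np.arange(len(ys))
    rows, cols, data = [], [], []
    steps = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    for dy, dx, w in steps:
        y2, x2 = ys + dy, xs + dx
        ok = (y2 >= 0) & (y2 < ny) & (x2 >= 0) & (x2 < nx)
        ok[ok] &= grid.sea_mask[y2[ok], x2[ok]]
        rows.extend(node[ys[ok], xs[ok]])
        cols.extend(node[y2[ok], x2[ok]])
        data.extend([w * grid.cell_size_km] * int(ok.sum()))
    n = len(ys)
    graph = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return graph, node


def sea_distance(
    grid: SeascapeGrid,
    coords: dict[str, tuple[float, float]],
    snap_radius: int = 2,
    overrides: dict[tuple[str, str], float] | None = None,
) -> DistanceMatrix:
    """Shortest at-sea path (km) between sites given as site -> (lon, lat).

    Sites are snapped to the nearest sea cell within ``snap_radius`` cells
    (error otherwise).  ``overrides`` lets the caller pin individual pairs
    manually (applied symmetrically) when the lattice path needs adjusting.
    """
    labels = list(coords)
    graph, node = _sea_graph(grid)
    start_nodes = []
    for name in labels:
        lon, lat = coords[name]
        fy, fx = _lonlat_to_cell(grid, lon, lat)
        iy, ix = int(round(fy)), int(round(fx))
        best = None
        for dy in range(-snap_radius, snap_radius + 1):
            for dx in range(-snap_radius, snap_radius + 1):
                y2, x2 = iy + dy, ix + dx
                if 0 <= y2 < grid.ny and 0 <= x2 < grid.nx and grid.sea_mask[y2, x2]:
                    d2 = (fy - y2) ** 2 + (fx - x2) ** 2
                    if best is None or d2 < best[0]:
                        best = (d2, y2, x2)
        if best is None:
            raise ValueError(f"site {name!r} is on land beyond the snap radius")
        start_nodes.append(int(node[best[1], best[2]]))
    dist = dijkstra(graph, directed=False, indices=start_nodes)
    n = len(labels)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = dist[a, start_nodes[b]]
            if not np.isfinite(d):
                raise ValueError(
                    f"no at-sea path between {labels[a]!r} and {labels[b]!r}"
                )
            values[a, b] = values[b, a] = d
    if overrides:
        for (sa, sb), d in overrides.items():
            ia, ib = labels.index(sa), labels.index(sb)
            values[ia, ib] = values[ib, ia] = float(d)
    return DistanceMatrix(labels=labels, values=values, metric="sea_km")


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


def _as_labelled(mat, labels):
    if isinstance(mat, DistanceMatrix):
        return np.asarray(mat.values, dtype=float), list(mat.labels)
    return np.asarray(mat, dtype=float), labels


def _mantel_core(
    A: np.ndarray,
    B: np.ndarray,
    permutations: int,
    seed: int | None,
    alternative: str,
    transform: str,
) -> MantelResult:
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    a = A[off]
    b = B[off]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")
    a_std = (a - a.mean()) / a.std()
    r_obs = float(np.mean(a_std * (b - b.mean()) / b.std()))
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 2000
    done = 0
    flat_off = np.flatnonzero(off.ravel())
    while done < permutations:
        m = min(chunk, permutations - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        Bp = B[perms[:, :, None], perms[:, None, :]].reshape(m, n * n)[:, flat_off]
        mu = Bp.mean(axis=1, keepdims=True)
        sd = Bp.std(axis=1)
        sd[sd == 0] = np.inf
        r_perm = ((Bp - mu) @ a_std) / (len(a) * sd)
        if alternative == "two-sided":
            hits += int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        elif alternative == "greater":
            hits += int(np.sum(r_perm >= r_obs - 1e-12))
        elif alternative == "less":
            hits += int(np.sum(r_perm <= r_obs + 1e-12))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        done += m
    p = (1 + hits) / (1 + permutations)
    return MantelResult(
        r=r_obs, p=p, permutations=permutations, transform=transform, alternative=alternative
    )


def mantel(
    A,
    B,
    permutations: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    labels: list[str] | None = None,
    transform: str = "",
) -> MantelResult:
    """Mantel test between two symmetric labelled matrices.

    The statistic is the Pearson correlation over off-diagonal pairs; the
    null permutes rows and columns of B jointly.  p is computed as
    ``(1 + hits) / (1 + permutations)`` so it can never be zero.
    """
    Av, la = _as_labelled(A, labels)
    Bv, lb = _as_labelled(B, labels)
    if la is not None and lb is not None and la != lb:
        raise ValueError("matrix labels differ or are ordered differently")
    for M in (Av, Bv):
        if M.shape != Av.shape or M.shape[0] != M.shape[1]:
            raise ValueError("matrices must be square and congruent")
        if not np.allclose(M, M.T, equal_nan=True):
            raise ValueError("mantel requires symmetric matrices; see asymmetric_mantel")
    return _mantel_core(Av, Bv, permutations, seed, alternative, transform)


def asymmetric_mantel(
    A,
    B,
    permutations: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    labels: list[str] | None = None,
    transform: str = "",
) -> MantelResult:
    """Mantel variant for directed matrices.

    All ordered off-diagonal pairs enter as distinct observations, so
    directional structure is preserved; the null applies one permutation to
    both axes of B, keeping its row/column coupling intact.
    """
    Av, la = _as_labelled(A, labels)
    Bv, lb = _as_labelled(B, labels)
    if la is not None and lb is not None and la != lb:
        raise ValueError("matrix labels differ or are ordered differently")
    if Av.shape != Bv.shape or Av.shape[0] != Av.shape[1]:
        raise ValueError("matrices must be square and congruent")
    return _mantel_core(Av, Bv, permutations, seed, alternative, transform)
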