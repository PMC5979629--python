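"""Threshold connectivity networks over genetic or oceanographic matrices.

The edge-inclusion cutoff is picked by scanning all candidate thresholds
between the value at which the graph stops being complete and the
percolation value at which it fragments; the selected threshold is the
midpoint of that informative window (arithmetic for distance matrices,
geometric for probability matrices).  Networks keep isolated nodes (flagged)
so that populations dropping out of the connected component remain visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["ThresholdScan", "select_threshold", "build_network", "graph_to_edge_csv"]


@dataclass
class ThresholdScan:
    thresholds: np.ndarray
    n_edges: np.ndarray
    n_components: np.ndarray
    giant_size: np.ndarray
    t_fragmenting: float
    t_informative: float
    selected: float
    mode: str = "distance"


def _edges_at(values: np.ndarray, t: float, mode: str) -> np.ndarray:
    if mode == "distance":
        keep = values < t
    else:
        keep = values > t
    np.fill_diagonal(keep, False)
    return keep


def _graph_stats(keep: np.ndarray) -> tuple[int, int, int]:
    n = keep.shape[0]
    g = nx.from_numpy_array(keep.astype(int))
    comps = list(nx.connected_components(g))
    giant = max(len(c) for c in comps)
    return int(keep.sum() // 2), len(comps), giant


def select_threshold(M, mode: str = "distance", labels: list[str] | None = None) -> ThresholdScan:
    """Scan the informative threshold window of a symmetric matrix.

    For distances, edges are pairs with value below the threshold: the
    informative end is the largest candidate at which the graph is not yet
    complete, the fragmenting end the largest at which it has already broken
    into more than one component, and the selected threshold is their
    midpoint (so component structure is revealed without collapsing into
    isolated dust).  Probability matrices work in the opposite direction
    (edges above the threshold, geometric midpoint).  A constant matrix has
    no window and is an error.
    """
    values = np.asarray(M.values if hasattr(M, "values") and not isinstance(M, np.ndarray) else M, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(values, values.T, equal_nan=True):
        raise ValueError("threshold scan needs a symmetric matrix")
    if mode not in ("distance", "probability"):
        raise ValueError("mode must be 'distance' or 'probability'")
    n = values.shape[0]
    off = values[~np.eye(n, dtype=bool)]
    uniq = np.unique(off)
    if len(uniq) < 2:
        raise ValueError("degenerate constant matrix: no informative window")
    cand = (uniq[:-1] + uniq[1:]) / 2.0  # midpoints between consecutive values
    n_edges = np.empty(len(cand), dtype=int)
    n_comp = np.empty(len(cand), dtype=int)
    giant = np.empty(len(cand), dtype=int)
    complete = np.empty(len(cand), dtype=bool)
    connected = np.empty(len(cand), dtype=bool)
    full = n * (n - 1) // 2
    for k, t in enumerate(cand):
        keep = _edges_at(values, t, mode)
        e, c, gsize = _graph_stats(keep)
        n_edges[k], n_comp[k], giant[k] = e, c, gsize
        complete[k] = e == full
        connected[k] = c == 1
    # the informative regime sits between total fragmentation and a complete
    # graph: its endpoints are the last fragmented candidate and the last
    # non-complete candidate (mirrored for probability matrices, where
    # tightening means raising the threshold)
    if mode == "distance":
        info_cands = cand[~complete]
        frag_cands = cand[~connected]
        if info_cands.size == 0 or frag_cands.size == 0:
            raise ValueError("no informative threshold window")
        t_informative = float(info_cands.max())
        t_fragmenting = float(frag_cands.max())
        if t_fragmenting > t_informative:
            raise ValueError("no informative threshold window")
        selected = 0.5 * (t_informative + t_fragmenting)
    else:
        info_cands = cand[~complete]
        frag_cands = cand[~connected]
        if info_cands.size == 0 or frag_cands.size == 0:
            raise ValueError("no informative threshold window")
        t_informative = float(info_cands.min())
        t_fragmenting = float(frag_cands.min())
        if t_fragmenting < t_informative:
            raise ValueError("no informative threshold window")
        if t_informative > 0 and t_fragmenting > 0:
            selected = float(np.sqrt(t_informative * t_fragmenting))
        else:
            selected = 0.5 * (t_informative + t_fragmenting)
    return ThresholdScan(
        thresholds=cand,
        n_edges=n_edges,
        n_components=n_comp,
        giant_size=giant,
        t_fragmenting=t_fragmenting,
        t_informative=t_informative,
        selected=selected,
        mode=mode,
    )


def build_network(
    M,
    threshold: float,
    mode: str = "distance",
    node_attrs: dict[str, dict] | None = None,
    labels: list[str] | None = None,
    drop_isolated: bool = False,
) -> nx.Graph:
    """Build the thresholded graph: distance mode keeps pairs with value
    below the threshold, probability mode pairs above it.

    ``node_attrs`` maps node label -> attribute dict (e.g. allelic richness,
    cluster id, coords); unknown labels are skipped with a warning.  Isolated
    nodes stay in the graph flagged ``isolated=True`` unless
    ``drop_isolated``.
    """
    if hasattr(M, "labels") and labels is None:
        labels = list(M.labels)
    values = np.asarray(M.values if hasattr(M, "values") and not isinstance(M, np.ndarray) else M, dtype=float)
    n = values.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    keep = _edges_at(values, threshold, mode)
    g = nx.Graph(mode=mode, threshold=float(threshold))
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if keep[i, j]:
                g.add_edge(labels[i], labels[j], weight=float(values[i, j]))
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree[node] == 0
    if node_attrs:
        for name, attrs in node_attrs.items():
            if name not in g.nodes:
                warnings.warn(f"node attribute for unknown label {name!r} skipped")
                continue
            g.nodes[name].update(attrs)
    if drop_isolated:
        g.remove_nodes_from([v for v in list(g.nodes) if g.degree[v] == 0])
    return g


def graph_to_edge_csv(g: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", np.nan)}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
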