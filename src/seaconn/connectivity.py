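"""Multigeneration stepping-stone connectivity from single-generation
dispersal matrices.

Connectivity over g generations is the g-th power of the single-generation
matrix restricted to habitat cells, i.e. the summed probability over all
habitat-respecting paths of length g.  Helpers symmetrize by the elementwise
minimum (for correlation against symmetric distances) and log10-transform
with a small offset so zero probabilities stay finite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from seaconn.lagrangian import DispersalMatrix

__all__ = [
    "multigeneration_connectivity",
    "symmetrize_min",
    "log_transform_matrix",
    "aggregate_to_sites",
]


def _matrix_power(values: np.ndarray, generations: int) -> np.ndarray:
    """Dense matrix power by repeated squaring."""
    result = np.eye(values.shape[0])
    base = values.copy()
    g = generations
    while g > 0:
        if g & 1:
            result = result @ base
        base = base @ base
        g >>= 1
    return result


def multigeneration_connectivity(
    P: DispersalMatrix,
    generations: int = 32,
    habitat_mask: Sequence[str] | None = None,
) -> DispersalMatrix:
    """Stepping-stone connectivity: (P restricted to habitat)^generations.

    ``habitat_mask`` lists the labels through which multi-step paths are
    allowed; rows and columns outside it are dropped.  ``generations=1``
    returns the restricted single-generation matrix.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    labels = list(P.labels)
    if habitat_mask is not None:
        mask = [l for l in labels if l in set(habitat_mask)]
        if not mask:
            raise ValueError("habitat mask shares no labels with the matrix")
        idx = [labels.index(l) for l in mask]
        values = P.values[np.ix_(idx, idx)]
        labels = mask
    else:
        values = P.values.copy()
    powered = _matrix_power(np.nan_to_num(values, nan=0.0), generations)
    tag = "multi_historic" if P.generation == "multi_historic" else "multi_extant"
    return DispersalMatrix(labels=labels, values=powered, generation=tag)


def symmetrize_min(M: DispersalMatrix | np.ndarray) -> np.ndarray:
    """Elementwise minimum of M and its transpose (symmetric by
    construction); accepts a DispersalMatrix or a bare array."""
    values = M.values if isinstance(M, DispersalMatrix) else np.asarray(M, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    return np.minimum(values, values.T)


def log_transform_matrix(M: DispersalMatrix | np.ndarray, offset: float) -> np.ndarray:
    """Elementwise log10(M + offset); zeros map to log10(offset)."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    values = M.values if isinstance(M, DispersalMatrix) else np.asarray(M, dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("matrix entries must be non-negative")
    return np.log10(values + offset)


def aggregate_to_sites(
    M: DispersalMatrix,
    site_cells: dict[str, Sequence[str]],
    source_rule: str = "mean",
) -> DispersalMatrix:
    """Aggregate a cell-level matrix to site level.

    Destination cells are summed (a propagule arriving anywhere in the site
    polygon counts); source cells are averaged by default so the entry stays
    a per-propagule probability (``source_rule='sum'`` gives total flux).
    """
    if source_rule not in ("mean", "sum"):
        raise ValueError("source_rule must be 'mean' or 'sum'")
    labels = list(M.labels)
    pos = {l: i for i, l in enumerate(labels)}
    site_names = list(site_cells)
    n = len(site_names)
    out = np.zeros((n, n))
    for a, sa in enumerate(site_names):
        rows = [pos[c] for c in site_cells[sa] if c in pos]
        if not rows:
            out[a, :] = np.nan
            continue
        block = M.values[rows, :]
        for b, sb in enumerate(site_names):
            cols = [pos[c] for c in site_cells[sb] if c in pos]
            if not cols:
                out[a, b] = np.nan
                continue
            flux = np.nansum(block[:, cols], axis=1)  # per source cell
            out[a, b] = np.mean(flux) if source_rule == "mean" else np.sum(flux)
    return DispersalMatrix(labels=site_names, values=out, generation=M.generation)
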