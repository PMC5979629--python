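"""Lagrangian tracking of buoyant shoots and dispersal-matrix construction.

Particles are released from habitat cells following a seasonal release
schedule (monthly proportions, a mixture of drift durations, one cohort per
simulated year), advected through the surface velocity field with 4th-order
Runge-Kutta stepping, bilinear spatial and linear temporal interpolation,
and an optional seeded sub-grid random walk.  A particle whose next step
would land ashore stops and strands in its last sea cell; one leaving the
domain is flagged lost.

Trajectory endpoints are then counted into a source -> destination
probability matrix, normalized by the number of particles released per
source; endings outside habitat contribute to loss, so row sums can be
below one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seaconn.seascape_sim import SeascapeGrid, VelocityField

__all__ = [
    "ReleaseSchedule",
    "TrajectoryEndpoints",
    "DispersalMatrix",
    "track_particles",
    "build_dispersal_matrix",
]

# season starts July 1; month offsets in days within the simulated season
_MONTH_STARTS = {"July": 0, "August": 31, "September": 62}
_MONTH_LENGTHS = {"July": 31, "August": 31, "September": 30}


@dataclass
class ReleaseSchedule:
    """When, how many and for how long particles drift."""

    month_weights: dict[str, float] = field(
        default_factory=lambda: {"July": 0.20, "August": 0.50, "September": 0.30}
    )
    duration_mixture: dict[float, float] = field(
        default_factory=lambda: {5.0: 0.05, 10.0: 0.10, 20.0: 0.20, 30.0: 0.65}
    )
    particles_per_cell: int = 10
    years: list[int] = field(default_factory=lambda: list(range(8)))

    def __post_init__(self) -> None:
        for name, weights in (("month_weights", self.month_weights), ("duration_mixture", self.duration_mixture)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if any(d <= 0 for d in self.duration_mixture):
            raise ValueError("durations must be positive")
        if self.particles_per_cell < 1:
            raise ValueError("particles_per_cell must be >= 1")


@dataclass
class TrajectoryEndpoints:
    """Per-particle release/end bookkeeping (cell indices, times, year)."""

    source_iy: np.ndarray
    source_ix: np.ndarray
    end_iy: np.ndarray
    end_ix: np.ndarray
    lost: np.ndarray
    release_hours: np.ndarray
    duration_hours: np.ndarray
    year: np.ndarray

    @property
    def n_particles(self) -> int:
        return len(self.source_iy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_iy": self.source_iy,
                "source_ix": self.source_ix,
                "end_iy": self.end_iy,
                "end_ix": self.end_ix,
                "lost": self.lost,
                "release_hours": self.release_hours,
                "duration_hours": self.duration_hours,
                "year": self.year,
            }
        )


@dataclass
class DispersalMatrix:
    """Source x destination probabilities from trajectory counts."""

    labels: list[str]
    values: np.ndarray
    generation: str = "single"  # single | multi_extant | multi_historic
    total_released: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-9):
            raise ValueError("dispersal probabilities must lie in [0, 1]")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        with open(path, "w") as fh:
            fh.write(f"# dispersal matrix (rows=source, cols=destination), generation={self.generation}\n")
            df.to_csv(fh, index_label="label")

    @classmethod
    def from_csv(cls, path) -> "DispersalMatrix":
        with open(path) as fh:
            first = fh.readline()
            generation = "single"
            if first.startswith("#"):
                if "generation=" in first:
                    generation = first.rsplit("generation=", 1)[1].strip()
                df = pd.read_csv(fh, index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(), generation=generation)


def _bilinear(field2d: np.ndarray, x_km: np.ndarray, y_km: np.ndarray, cell_km: float) -> np.ndarray:
    """Sample a (ny, nx) field at km positions; values live at cell centres."""
    ny, nx = field2d.shape
    fx = np.clip(x_km / cell_km - 0.5, 0.0, nx - 1.0)
    fy = np.clip(y_km / cell_km - 0.5, 0.0, ny - 1.0)
    ix0 = np.clip(fx.astype(int), 0, nx - 2)
    iy0 = np.clip(fy.astype(int), 0, ny - 2)
    wx = fx - ix0
    wy = fy - iy0
    f00 = field2d[iy0, ix0]
    f01 = field2d[iy0, ix0 + 1]
    f10 = field2d[iy0 + 1, ix0]
    f11 = field2d[iy0 + 1, ix0 + 1]
    return (1 - wy) * ((1 - wx) * f00 + wx * f01) + wy * ((1 - wx) * f10 + wx * f11)


def track_particles(
    grid: SeascapeGrid,
    fieldv: VelocityField,
    schedule: ReleaseSchedule,
    seed: int | None = None,
    dt_minutes: float = 15.0,
    diffusivity_m2s: float = 10.0,
    habitat: str = "extant",
) -> TrajectoryEndpoints:
    """Advect ``particles_per_cell`` particles per habitat cell and year.

    Release day is uniform within the sampled month; drift duration follows
    the schedule's mixture.  ``diffusivity_m2s`` sets the sub-grid random
    walk (0 disables it).  Deterministic for a seed.
    """
    sources = grid.habitat_cells(habitat)
    if not sources:
        raise ValueError("no habitat cells to release from")
    for iy, ix in sources:
        if not grid.sea_mask[iy, ix]:
            raise ValueError(f"release cell ({iy},{ix}) is on land")
    rng = np.random.default_rng(seed)
    cell = grid.cell_size_km
    dt_h = dt_minutes / 60.0
    dt_s = dt_minutes * 60.0
    season_h = float(fieldv.times_hours[-1])
    months = list(schedule.month_weights)
    month_p = np.array([schedule.month_weights[m] for m in months])
    durations = np.array(list(schedule.duration_mixture))
    duration_p = np.array([schedule.duration_mixture[d] for d in durations])

    n_per_year = len(sources) * schedule.particles_per_cell
    src = np.repeat(np.arange(len(sources)), schedule.particles_per_cell)
    src_iy = np.array([s[0] for s in sources])[src]
    src_ix = np.array([s[1] for s in sources])[src]

    all_frames: list[dict[str, np.ndarray]] = []
    for year in schedule.years:
        if year not in fieldv.years:
            raise ValueError(f"year {year} not covered by the velocity field")
        m_idx = rng.choice(len(months), size=n_per_year, p=month_p)
        day = np.array(
            [
                _MONTH_STARTS[months[k]] + rng.uniform(0, _MONTH_LENGTHS[months[k]])
                for k in m_idx
            ]
        )
        release_h = day * 24.0
        dur_h = durations[rng.choice(len(durations), size=n_per_year, p=duration_p)] * 24.0
        dur_h = np.minimum(dur_h, season_h - release_h)  # cannot outlive the season
        end_h = release_h + dur_h

        x = (src_ix + rng.uniform(0.25, 0.75, n_per_year)) * cell
        y = (src_iy + rng.uniform(0.25, 0.75, n_per_year)) * cell
        done = np.zeros(n_per_year, dtype=bool)
        lost = np.zeros(n_per_year, dtype=bool)

        t = float(release_h.min())
        t_end = float(end_h.max())
        yidx = fieldv.years.index(year)
        u0, v0 = fieldv.velocities_at(yidx, t)
        while t < t_end - 1e-9:
            u1, v1 = fieldv.velocities_at(yidx, t + dt_h)
            um, vm = 0.5 * (u0 + u1), 0.5 * (v0 + v1)
            active = ~done & ~lost & (release_h <= t) & (end_h > t)
            if active.any():
                xa, ya = x[active], y[active]
                k1x = _bilinear(u0, xa, ya, cell)
                k1y = _bilinear(v0, xa, ya, cell)
                px, py = xa + k1x * dt_s / 2000.0, ya + k1y * dt_s / 2000.0
                k2x = _bilinear(um, px, py, cell)
                k2y = _bilinear(vm, px, py, cell)
                px, py = xa + k2x * dt_s / 2000.0, ya + k2y * dt_s / 2000.0
                k3x = _bilinear(um, px, py, cell)
                k3y = _bilinear(vm, px, py, cell)
                px, py = xa + k3x * dt_s / 1000.0, ya + k3y * dt_s / 1000.0
                k4x = _bilinear(u1, px, py, cell)
                k4y = _bilinear(v1, px, py, cell)
                dx = (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0 * dt_s / 1000.0
                dy = (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0 * dt_s / 1000.0
                if diffusivity_m2s > 0:
                    sigma_km = np.sqrt(2 * diffusivity_m2s * dt_s) / 1000.0
                    dx = dx + rng.normal(0, sigma_km, size=dx.shape)
                    dy = dy + rng.normal(0, sigma_km, size=dy.shape)
                nx_km, ny_km = xa + dx, ya + dy
                out = (
                    (nx_km < 0)
                    | (ny_km < 0)
                    | (nx_km >= grid.nx * cell)
                    | (ny_km >= grid.ny * cell)
                )
                cix = np.clip((nx_km / cell).astype(int), 0, grid.nx - 1)
                ciy = np.clip((ny_km / cell).astype(int), 0, grid.ny - 1)
                ashore = ~out & ~grid.sea_mask[ciy, cix]
                move = ~out & ~ashore
                idx = np.flatnonzero(active)
                x[idx[move]] = nx_km[move]
                y[idx[move]] = ny_km[move]
                done[idx[ashore]] = True  # beached: stays in its last sea cell
                lost[idx[out]] = True
            t += dt_h
            u0, v0 = u1, v1

        end_ix = np.clip((x / cell).astype(int), 0, grid.nx - 1)
        end_iy = np.clip((y / cell).astype(int), 0, grid.ny - 1)
        all_frames.append(
            {
                "source_iy": src_iy.copy(),
                "source_ix": src_ix.copy(),
                "end_iy": end_iy,
                "end_ix": end_ix,
                "lost": lost,
                "release_hours": release_h,
                "duration_hours": dur_h,
                "year": np.full(n_per_year, year),
            }
        )

    cat = {k: np.concatenate([f[k] for f in all_frames]) for k in all_frames[0]}
    return TrajectoryEndpoints(**cat)


def build_dispersal_matrix(
    endpoints: TrajectoryEndpoints,
    grid: SeascapeGrid,
    level: str = "cell",
    habitat: str = "extant",
) -> DispersalMatrix:
    """Count endpoints into P_ij = trajectories(i -> j) / released(i).

    ``level='cell'`` uses habitat cells as labels; ``level='site'`` uses the
    grid's site polygons (particles released outside any polygon are
    ignored).  Destinations outside habitat (or outside any site polygon),
    beached on bare coast, or lost contribute to the loss fraction, so rows
    sum to at most one.
    """
    if endpoints.n_particles == 0:
        raise ValueError("no trajectory endpoints")
    if level == "cell":
        cells = grid.habitat_cells(habitat)
        labels = [grid.cell_label(iy, ix) for iy, ix in cells]
        index = {c: k for k, c in enumerate(cells)}
        src_key = list(zip(endpoints.source_iy.tolist(), endpoints.source_ix.tolist()))
        dst_key = list(zip(endpoints.end_iy.tolist(), endpoints.end_ix.tolist()))
        src_lab = [index.get(c, -1) for c in src_key]
        dst_lab = [index.get(c, -1) for c in dst_key]
    elif level == "site":
        labels = list(grid.site_polygons)
        cell_site: dict[tuple[int, int], int] = {}
        for k, name in enumerate(labels):
            for c in grid.site_polygons[name]:
                cell_site[c] = k
        src_lab = [
            cell_site.get((iy, ix), -1)
            for iy, ix in zip(endpoints.source_iy.tolist(), endpoints.source_ix.tolist())
        ]
        dst_lab = [
            cell_site.get((iy, ix), -1)
            for iy, ix in zip(endpoints.end_iy.tolist(), endpoints.end_ix.tolist())
        ]
    else:
        raise ValueError("level must be 'cell' or 'site'")

    n = len(labels)
    counts = np.zeros((n, n))
    released = np.zeros(n)
    lost = np.asarray(endpoints.lost, dtype=bool)
    for p, (s, d) in enumerate(zip(src_lab, dst_lab)):
        if s < 0:
            continue
        released[s] += 1
        if d >= 0 and not lost[p]:
            counts[s, d] += 1
    values = np.full((n, n), np.nan)
    nonzero = released > 0
    values[nonzero] = counts[nonzero] / released[nonzero, None]
    if (~nonzero).any():
        warnings.warn(f"{int((~nonzero).sum())} sources released no particles; rows set to NA")
    return DispersalMatrix(
        labels=labels, values=values, generation="single", total_released=released
    )
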