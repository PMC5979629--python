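"""Synthetic seascapes, analytic surface currents and forward-time genotypes.

Everything here is a pure function of a configuration and a seed, so the
whole analysis pipeline can be exercised without any external ocean-model or
field data:

* :func:`make_seascape` builds a coastline-bounded grid with disjoint
  habitat archipelagos along the coast and an offshore historic-habitat
  annulus that is absent from the extant habitat.
* :func:`make_velocity_field` composes a divergence-free flow from a
  coastal boundary-current streamfunction, a periodically perturbed double
  gyre and seeded smooth noise, modulated year-by-year by an NAO-like
  circulation multiplier.
* :func:`simulate_genotypes` runs a Wright-Fisher model with migration
  sampled from a known dispersal matrix, strict stepwise microsatellite
  mutation and partial clonality, and returns a ramet-level genotype table
  (clones included) for the genetics pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from seaconn.genotypes import GenotypeTable

__all__ = [
    "SeascapeConfig",
    "FlowConfig",
    "SimulationConfig",
    "SeascapeGrid",
    "VelocityField",
    "make_seascape",
    "make_velocity_field",
    "simulate_genotypes",
]

KM_PER_DEG_LAT = 111.2


@dataclass
class SeascapeConfig:
    nx: int = 100
    ny: int = 80
    cell_size_km: float = 4.0
    seed: int = 0
    n_archipelagos: int = 4
    archipelago_radius: int = 3
    historic_fraction: float = 0.15  # 0 disables the historic annulus
    coast_base: int = 12
    coast_amplitude: float = 5.0
    lon0: float = 8.0
    lat0: float = 54.0


@dataclass
class FlowConfig:
    boundary_speed: float = 0.15  # m/s alongshore jet peak
    boundary_width_km: float = 30.0
    counter_fraction: float = 0.5  # offshore return-flow peak relative to jet
    counter_offset_km: float = 75.0  # distance of the return-flow core offshore
    gyre_speed: float = 0.05
    noise_speed: float = 0.03
    uniform_u: float = 0.0
    uniform_v: float = 0.0
    direction: int = 1  # +1 = northward alongshore transport
    n_years: int = 8
    nao_amplitude: float = 0.35
    season_days: int = 122  # July 1 .. October 31
    snapshot_interval_hours: float = 6.0
    seed: int = 0


@dataclass
class SimulationConfig:
    seed: int = 0
    deme_size: int = 100
    n_loci: int = 10
    mutation_rate: float = 1e-3  # per gamete per locus, stepwise
    clonality: float = 0.0
    generations: int = 100
    n_samples: int | None = None  # ramets sampled per deme (default min(40, deme))
    init_alleles: int = 5
    allele_base: int = 100

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "clonality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("deme_size", "n_loci", "generations", "init_alleles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SeascapeGrid:
    """Regular coastal grid: land/sea mask, habitat layers, site polygons."""

    nx: int
    ny: int
    cell_size_km: float
    sea_mask: np.ndarray  # (ny, nx) bool
    habitat_extant: np.ndarray
    habitat_historic: np.ndarray  # superset of extant when an annulus exists
    site_polygons: dict[str, list[tuple[int, int]]]  # site -> [(iy, ix), ...]
    lon0: float = 8.0
    lat0: float = 54.0

    def cell_label(self, iy: int, ix: int) -> str:
        return f"c{iy}_{ix}"

    def parse_label(self, label: str) -> tuple[int, int]:
        iy, ix = label[1:].split("_")
        return int(iy), int(ix)

    def centroid_lonlat(self, iy: int, ix: int) -> tuple[float, float]:
        lat = self.lat0 + (iy + 0.5) * self.cell_size_km / KM_PER_DEG_LAT
        lon = self.lon0 + (ix + 0.5) * self.cell_size_km / (
            KM_PER_DEG_LAT * np.cos(np.deg2rad(lat))
        )
        return lon, lat

    def habitat_cells(self, kind: str = "extant") -> list[tuple[int, int]]:
        mask = self.habitat_extant if kind == "extant" else self.habitat_historic
        ys, xs = np.nonzero(mask)
        return list(zip(ys.tolist(), xs.tolist()))

    def site_coords(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name, cells in self.site_polygons.items():
            iy = int(round(np.mean([c[0] for c in cells])))
            ix = int(round(np.mean([c[1] for c in cells])))
            out[name] = self.centroid_lonlat(iy, ix)
        return out

    def validate(self) -> None:
        if ((self.habitat_extant | self.habitat_historic) & ~self.sea_mask).any():
            raise ValueError("habitat must lie within the sea mask")
        union = self.habitat_extant | self.habitat_historic
        for name, cells in self.site_polygons.items():
            for iy, ix in cells:
                if not union[iy, ix]:
                    raise ValueError(f"site {name} cell ({iy},{ix}) outside habitat")


def make_seascape(config: SeascapeConfig) -> SeascapeGrid:
    """Deterministic synthetic seascape for a seed.

    Land occupies the western margin bounded by a smooth wavy coastline;
    ``n_archipelagos`` disjoint coastal habitat patches are laid out from
    south to north, each hosting one named site polygon, and (when
    ``historic_fraction > 0``) an offshore annulus of historic-only habitat
    sits in the middle of the domain.
    """
    if config.nx < 20 or config.ny < 20:
        raise ValueError("grid must be at least 20x20")
    if config.n_archipelagos < 2:
        raise ValueError("need at least two habitat archipelagos")
    rng = np.random.default_rng(config.seed)
    ny, nx = config.ny, config.nx
    ys = np.arange(ny)
    wobble = rng.normal(0, 1, size=4)
    coast = (
        config.coast_base
        + config.coast_amplitude * np.sin(2 * np.pi * ys / ny + wobble[0])
        + 2.0 * np.sin(6 * np.pi * ys / ny + wobble[1])
    )
    coast = np.clip(np.round(coast).astype(int), 2, nx // 2)
    sea = np.ones((ny, nx), dtype=bool)
    for iy in range(ny):
        sea[iy, : coast[iy]] = False

    extant = np.zeros((ny, nx), dtype=bool)
    sites: dict[str, list[tuple[int, int]]] = {}
    r = config.archipelago_radius
    centers_y = np.linspace(0.12 * ny, 0.88 * ny, config.n_archipelagos).astype(int)
    for k, cy in enumerate(centers_y):
        cx = coast[cy] + r + 1
        patch: list[tuple[int, int]] = []
        for iy in range(max(0, cy - r), min(ny, cy + r + 1)):
            for ix in range(max(0, cx - r), min(nx, cx + r + 1)):
                if sea[iy, ix] and (iy - cy) ** 2 + (ix - cx) ** 2 <= r * r:
                    extant[iy, ix] = True
                    patch.append((iy, ix))
        if not patch:
            raise ValueError(f"archipelago {k} has no sea cells; adjust coastline")
        sites[f"S{k + 1}"] = patch

    historic = extant.copy()
    if config.historic_fraction > 0:
        cy, cx = int(0.5 * ny), int(min(nx - 5, np.max(coast) + 0.35 * nx))
        r_out = max(3.0, config.historic_fraction * min(ny, nx) / 2.0)
        r_in = 0.55 * r_out
        yy, xx = np.mgrid[0:ny, 0:nx]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        annulus = (d2 <= r_out**2) & (d2 >= r_in**2) & sea & ~extant
        historic |= annulus

    if not extant.any():
        raise ValueError("habitat fraction is zero")
    grid = SeascapeGrid(
        nx=nx,
        ny=ny,
        cell_size_km=config.cell_size_km,
        sea_mask=sea,
        habitat_extant=extant,
        habitat_historic=historic,
        site_polygons=sites,
        lon0=config.lon0,
        lat0=config.lat0,
    )
    grid.validate()
    return grid


@dataclass
class VelocityField:
    """Seasonal surface currents on a grid with interannual modulation.

    ``u``/``v`` (m/s, shape ``(n_snapshots, ny, nx)``) hold one season of
    3-to-6-hourly snapshots; year ``y`` scales them by ``year_multiplier[y]``
    and adds a stationary per-year anomaly field, emulating NAO-driven
    interannual circulation variability.
    """

    grid: SeascapeGrid
    times_hours: np.ndarray
    u: np.ndarray
    v: np.ndarray
    snapshot_interval_hours: float
    years: list[int]
    year_multiplier: np.ndarray
    year_anomaly_u: np.ndarray  # (n_years, ny, nx)
    year_anomaly_v: np.ndarray
    uniform_u: float = 0.0  # background flow, not scaled by the NAO index
    uniform_v: float = 0.0

    def velocities_at(self, year_index: int, t_hours: float) -> tuple[np.ndarray, np.ndarray]:
        """Linearly time-interpolated (u, v) snapshot for one year."""
        t = float(np.clip(t_hours, self.times_hours[0], self.times_hours[-1]))
        k = int(np.clip(np.searchsorted(self.times_hours, t) - 1, 0, len(self.times_hours) - 2))
        w = (t - self.times_hours[k]) / (self.times_hours[k + 1] - self.times_hours[k])
        m = self.year_multiplier[year_index]
        u = m * ((1 - w) * self.u[k] + w * self.u[k + 1]) + self.year_anomaly_u[year_index]
        v = m * ((1 - w) * self.v[k] + w * self.v[k + 1]) + self.year_anomaly_v[year_index]
        if self.uniform_u or self.uniform_v:
            u = u + self.uniform_u
            v = v + self.uniform_v
            u[~self.grid.sea_mask] = 0.0
            v[~self.grid.sea_mask] = 0.0
        return u, v


def _streamfunction_velocities(psi: np.ndarray, dx_m: float) -> tuple[np.ndarray, np.ndarray]:
    """u = -dpsi/dy, v = dpsi/dx (central differences) — divergence-free."""
    dpsi_dy, dpsi_dx = np.gradient(psi, dx_m, dx_m)
    return -dpsi_dy, dpsi_dx


def make_velocity_field(grid: SeascapeGrid, config: FlowConfig) -> VelocityField:
    """Analytic seasonal flow: coastal jet + double gyre + seeded noise.

    All rotational components derive from streamfunctions, so the interior
    divergence is numerically small; velocities are zeroed on land.
    """
    rng = np.random.default_rng(config.seed)
    ny, nx = grid.ny, grid.nx
    dx_m = grid.cell_size_km * 1000.0
    n_snap = int(config.season_days * 24 / config.snapshot_interval_hours) + 1
    times = np.arange(n_snap) * config.snapshot_interval_hours

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    coast_x = np.array([np.argmax(grid.sea_mask[iy]) for iy in range(ny)], dtype=float)
    dist_off = (xx - coast_x[:, None]) * grid.cell_size_km  # km offshore
    width = config.boundary_width_km
    # coastal jet (alongshore speed V0 at the coast, decaying offshore) plus
    # an opposing return-flow band centred counter_offset_km offshore; both
    # enter through the streamfunction so the flow stays non-divergent
    d_off = np.clip(dist_off, 0, None)
    psi_jet = -config.direction * config.boundary_speed * (width * 1000.0) * np.exp(-d_off / width)
    if config.counter_fraction > 0:
        from scipy.special import erf

        z = (d_off - config.counter_offset_km) / (np.sqrt(2.0) * width)
        psi_jet -= (
            config.direction
            * config.boundary_speed
            * config.counter_fraction
            * (width * 1000.0)
            * np.sqrt(np.pi / 2.0)
            * erf(z)
        )

    Lx, Ly = nx * dx_m, ny * dx_m
    amp_gyre = config.gyre_speed * Ly / np.pi
    phases = rng.uniform(0, 2 * np.pi, size=3)
    # seeded smooth noise modes (stationary shapes, slow time phase)
    modes = []
    for _ in range(3):
        kx, ky = rng.integers(1, 4, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        modes.append((kx, ky, ph1, ph2))
    amp_noise = config.noise_speed * Ly / np.pi

    u = np.empty((n_snap, ny, nx), dtype=np.float32)
    v = np.empty((n_snap, ny, nx), dtype=np.float32)
    for k, t in enumerate(times):
        eps = 0.25 * np.sin(2 * np.pi * t / (24 * 30) + phases[0])  # ~monthly sway
        xg = xx / nx + eps * np.sin(np.pi * xx / nx)
        psi_gyre = amp_gyre * np.sin(np.pi * xg) * np.sin(2 * np.pi * yy / ny + phases[1])
        psi_noise = np.zeros((ny, nx))
        for kx, ky, ph1, ph2 in modes:
            psi_noise += np.sin(2 * np.pi * (kx * xx / nx) + ph1 + 2 * np.pi * t / (24 * 60)) * np.sin(
                2 * np.pi * (ky * yy / ny) + ph2
            )
        psi = psi_jet + psi_gyre + amp_noise * psi_noise / 3.0
        uk, vk = _streamfunction_velocities(psi, dx_m)
        u[k] = uk
        v[k] = vk
        u[k][~grid.sea_mask] = 0.0
        v[k][~grid.sea_mask] = 0.0

    mults = np.clip(1.0 + config.nao_amplitude * rng.standard_normal(config.n_years), 0.2, None)
    anom_u = np.zeros((config.n_years, ny, nx), dtype=np.float32)
    anom_v = np.zeros((config.n_years, ny, nx), dtype=np.float32)
    for y in range(config.n_years):
        if config.noise_speed > 0:
            kx, ky = rng.integers(1, 3, size=2)
            ph = rng.uniform(0, 2 * np.pi)
            psi_y = (0.5 * amp_noise) * np.sin(2 * np.pi * kx * xx / nx + ph) * np.sin(
                2 * np.pi * ky * yy / ny
            )
            au, av = _streamfunction_velocities(psi_y, dx_m)
            anom_u[y], anom_v[y] = au, av
            anom_u[y][~grid.sea_mask] = 0.0
            anom_v[y][~grid.sea_mask] = 0.0

    return VelocityField(
        grid=grid,
        times_hours=times.astype(float),
        u=u,
        v=v,
        snapshot_interval_hours=config.snapshot_interval_hours,
        years=list(range(config.n_years)),
        year_multiplier=mults,
        year_anomaly_u=anom_u,
        year_anomaly_v=anom_v,
        uniform_u=config.uniform_u,
        uniform_v=config.uniform_v,
    )


# ---------------------------------------------------------------------------
# forward-time genotype simulation
# ---------------------------------------------------------------------------


def _backward_migration(values: np.ndarray) -> np.ndarray:
    """Column-normalize a source->destination dispersal matrix into the
    probability that a recruit in deme j has its parent in deme i."""
    col = values.sum(axis=0)
    n = values.shape[0]
    B = np.zeros((n, n))
    for j in range(n):
        if col[j] > 0:
            B[:, j] = values[:, j] / col[j]
        else:
            warnings.warn(f"deme {j} receives no propagules; treated as isolated")
            B[j, j] = 1.0
    return B.T  # B[j, i] = P(parent deme = i | recruit deme = j)


def simulate_genotypes(dispersal, config: SimulationConfig) -> GenotypeTable:
    """Wright-Fisher genotypes along a known dispersal matrix.

    Each generation every deme is refilled with ``deme_size`` recruits whose
    parent demes are drawn from the column-normalized dispersal matrix
    (source rows -> destination columns).  A recruit is clonal with
    probability ``clonality`` (an exact copy of one parent, no mutation) and
    sexual otherwise (one gamete from each of two independently drawn
    parents, strict stepwise mutation at ``mutation_rate`` per gamete and
    locus).  Returns a ramet-level table of ``n_samples`` shoots per deme,
    clones included, so the clone-discrimination stage sees realistic input.
    """
    values = np.asarray(dispersal.values, dtype=float)
    labels = list(dispersal.labels)
    if values.min() < 0 or values.max() > 1:
        raise ValueError("dispersal entries must be probabilities")
    if (values.sum(axis=1) == 0).any():
        warnings.warn("dispersal matrix has all-zero rows (pure sink demes)")
    rng = np.random.default_rng(config.seed)
    D = len(labels)
    N = config.deme_size
    L = config.n_loci
    B = _backward_migration(values)

    # shared ancestral polymorphism: same allele pool in every deme
    pool_freqs = rng.dirichlet(np.ones(config.init_alleles), size=L)
    pop = np.empty((D, N, L, 2), dtype=np.int16)
    for j in range(L):
        draws = rng.choice(config.init_alleles, size=(D, N, 2), p=pool_freqs[j])
        pop[:, :, j, :] = config.allele_base + draws

    for _ in range(config.generations):
        parent_deme1 = np.empty((D, N), dtype=np.int64)
        parent_deme2 = np.empty((D, N), dtype=np.int64)
        for j in range(D):
            parent_deme1[j] = rng.choice(D, size=N, p=B[j])
            parent_deme2[j] = rng.choice(D, size=N, p=B[j])
        idx1 = rng.integers(N, size=(D, N))
        idx2 = rng.integers(N, size=(D, N))
        par1 = pop[parent_deme1, idx1]  # (D, N, L, 2)
        par2 = pop[parent_deme2, idx2]
        gam1 = np.take_along_axis(
            par1, rng.integers(2, size=(D, N, L, 1)), axis=3
        )[..., 0]
        gam2 = np.take_along_axis(
            par2, rng.integers(2, size=(D, N, L, 1)), axis=3
        )[..., 0]
        if config.mutation_rate > 0:
            for gam in (gam1, gam2):
                mut = rng.random((D, N, L)) < config.mutation_rate
                steps = rng.choice([-1, 1], size=(D, N, L)).astype(np.int16)
                gam += np.where(mut, steps, 0).astype(np.int16)
        sexual = np.stack([gam1, gam2], axis=3)
        new_pop = sexual
        if config.clonality > 0:
            clonal_mask = rng.random((D, N)) < config.clonality
            new_pop = np.where(clonal_mask[:, :, None, None], par1, sexual)
        pop = np.ascontiguousarray(new_pop)

    n_samp = config.n_samples if config.n_samples is not None else min(40, N)
    if n_samp > N:
        raise ValueError("cannot sample more ramets than the deme holds")
    ramet_ids: list[str] = []
    sites: list[str] = []
    rows = []
    for j, lab in enumerate(labels):
        take = rng.choice(N, size=n_samp, replace=False)
        for r, i in enumerate(take):
            ramet_ids.append(f"{lab}_r{r}")
            sites.append(str(lab))
            rows.append(pop[j, i])
    return GenotypeTable(
        ramet_ids=ramet_ids,
        sites=sites,
        alleles=np.asarray(rows, dtype=np.int64),
        locus_names=[f"L{j + 1}" for j in range(L)],
    )
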