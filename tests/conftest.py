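"""Shared fixtures: hand-built genotype tables, synthetic grids and one
session-scoped stepping-stone simulation reused by several test modules."""

from __future__ import annotations

import numpy as np
import pytest

from seaconn.genotypes import GenotypeTable, reduce_to_genets, shared_allele_distance
from seaconn.lagrangian import DispersalMatrix
from seaconn.seascape_sim import (
    FlowConfig,
    SeascapeConfig,
    SeascapeGrid,
    SimulationConfig,
    make_seascape,
    make_velocity_field,
    simulate_genotypes,
)


def make_hw_table(
    n_per_site: int = 40,
    n_sites: int = 2,
    n_loci: int = 10,
    n_alleles: int = 4,
    seed: int = 0,
    shared_freqs: bool = True,
) -> GenotypeTable:
    """Random-mating genotypes drawn from Dirichlet allele frequencies."""
    rng = np.random.default_rng(seed)
    rows, sites, ids = [], [], []
    base = rng.dirichlet(np.ones(n_alleles) * 2, size=n_loci)
    for s in range(n_sites):
        freqs = base if shared_freqs else rng.dirichlet(np.ones(n_alleles) * 2, size=n_loci)
        for i in range(n_per_site):
            g = np.array([rng.choice(n_alleles, size=2, p=freqs[j]) for j in range(n_loci)])
            rows.append(g + 100)
            sites.append(f"s{s}")
            ids.append(f"s{s}_r{i}")
    return GenotypeTable(ids, sites, np.asarray(rows), [f"L{j}" for j in range(n_loci)])


@pytest.fixture
def two_site_table() -> GenotypeTable:
    """2 sites x 3 ramets x 2 loci, all distinct genotypes."""
    alleles = np.array(
        [
            [[101, 102], [110, 110]],
            [[101, 101], [110, 112]],
            [[102, 102], [112, 112]],
            [[103, 104], [114, 114]],
            [[103, 103], [114, 116]],
            [[104, 104], [116, 116]],
        ]
    )
    return GenotypeTable(
        ramet_ids=[f"r{i}" for i in range(6)],
        sites=["north"] * 3 + ["south"] * 3,
        alleles=alleles,
        locus_names=["locA", "locB"],
        coords={"north": (11.0, 58.0), "south": (11.2, 57.0)},
    )


@pytest.fixture(scope="session")
def open_grid() -> SeascapeGrid:
    """All-sea 20x40 grid with one small habitat blob (closed-form tests)."""
    ny, nx = 20, 40
    sea = np.ones((ny, nx), dtype=bool)
    hab = np.zeros((ny, nx), dtype=bool)
    hab[8:12, 3:6] = True
    return SeascapeGrid(
        nx=nx,
        ny=ny,
        cell_size_km=4.0,
        sea_mask=sea,
        habitat_extant=hab,
        habitat_historic=hab,
        site_polygons={"S1": [(9, 4), (10, 4)]},
    )


@pytest.fixture(scope="session")
def demo_grid() -> SeascapeGrid:
    return make_seascape(SeascapeConfig(nx=60, ny=48, n_archipelagos=3, seed=7))


@pytest.fixture(scope="session")
def demo_field(demo_grid):
    return make_velocity_field(
        demo_grid,
        FlowConfig(n_years=2, season_days=45, snapshot_interval_hours=6.0, seed=8),
    )


def chain_dispersal(n: int = 8, retention: float = 0.4, north: float = 0.25, south: float = 0.05) -> DispersalMatrix:
    """1-D stepping-stone chain with northward bias (rows = source)."""
    P = np.zeros((n, n))
    for i in range(n):
        P[i, i] = retention
        if i + 1 < n:
            P[i, i + 1] = north
        if i - 1 >= 0:
            P[i, i - 1] = south
    return DispersalMatrix(labels=[f"d{i}" for i in range(n)], values=P)


@pytest.fixture(scope="session")
def chain_sim():
    """Stepping-stone chain genotypes plus derived matrices, computed once."""
    disp = chain_dispersal()
    table = simulate_genotypes(
        disp,
        SimulationConfig(
            seed=11,
            deme_size=100,
            n_loci=15,
            mutation_rate=5e-4,
            clonality=0.0,
            generations=150,
            n_samples=30,
        ),
    )
    genets = reduce_to_genets(table)
    dps = shared_allele_distance(genets)
    return {"dispersal": disp, "table": table, "genets": genets, "dps": dps}


@pytest.fixture(scope="session")
def block_sim():
    """Two isolated 3-deme blocks with strong within-block migration."""
    n = 6
    P = np.zeros((n, n))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                P[i, j] = 0.3 if i != j else 0.4
    disp = DispersalMatrix(labels=[f"d{i}" for i in range(n)], values=P)
    table = simulate_genotypes(
        disp,
        SimulationConfig(seed=21, deme_size=80, n_loci=12, mutation_rate=5e-4, generations=150, n_samples=25),
    )
    genets = reduce_to_genets(table)
    return {"dispersal": disp, "genets": genets, "dps": shared_allele_distance(genets)}
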