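"""Synthetic seascape generator, analytic flow and genotype simulator."""

import numpy as np
import pytest

from seaconn.genotypes import reduce_to_genets, shared_allele_distance
from seaconn.lagrangian import DispersalMatrix, ReleaseSchedule, track_particles
from seaconn.seascape_sim import (
    FlowConfig,
    SeascapeConfig,
    SimulationConfig,
    make_seascape,
    make_velocity_field,
    simulate_genotypes,
)


class TestMakeSeascape:
    def test_determinism(self):
        a = make_seascape(SeascapeConfig(seed=3))
        b = make_seascape(SeascapeConfig(seed=3))
        assert np.array_equal(a.sea_mask, b.sea_mask)
        assert np.array_equal(a.habitat_extant, b.habitat_extant)
        assert a.site_polygons == b.site_polygons

    def test_zero_historic_fraction(self):
        g = make_seascape(SeascapeConfig(historic_fraction=0.0, seed=1))
        assert np.array_equal(g.habitat_historic, g.habitat_extant)

    def test_historic_annulus_absent_from_extant(self):
        g = make_seascape(SeascapeConfig(seed=2))
        extra = g.habitat_historic & ~g.habitat_extant
        assert extra.sum() > 0
        assert not (extra & g.habitat_extant).any()

    def test_sites_within_habitat_and_sea(self):
        g = make_seascape(SeascapeConfig(seed=4))
        union = g.habitat_extant | g.habitat_historic
        for cells in g.site_polygons.values():
            assert len(cells) > 0
            for iy, ix in cells:
                assert union[iy, ix] and g.sea_mask[iy, ix]

    def test_disjoint_archipelagos(self):
        g = make_seascape(SeascapeConfig(seed=5, n_archipelagos=4))
        polys = list(g.site_polygons.values())
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert not set(polys[i]) & set(polys[j])

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="20x20"):
            make_seascape(SeascapeConfig(nx=10, ny=10))

    def test_sea_region_connected(self):
        from scipy.ndimage import label

        g = make_seascape(SeascapeConfig(seed=6))
        _, n = label(g.sea_mask)
        assert n == 1


class TestVelocityField:
    def test_still_field(self, open_grid):
        cfg = FlowConfig(boundary_speed=0, gyre_speed=0, noise_speed=0, n_years=1, season_days=10)
        f = make_velocity_field(open_grid, cfg)
        u, v = f.velocities_at(0, 24.0)
        assert np.all(u == 0) and np.all(v == 0)

    def test_uniform_flow_value(self, open_grid):
        cfg = FlowConfig(
            boundary_speed=0, gyre_speed=0, noise_speed=0, uniform_u=0.1, n_years=1, season_days=10
        )
        f = make_velocity_field(open_grid, cfg)
        u, v = f.velocities_at(0, 12.0)
        assert np.allclose(u[open_grid.sea_mask], 0.1)
        assert np.allclose(v, 0.0)

    def test_zero_on_land(self):
        g = make_seascape(SeascapeConfig(seed=7))
        f = make_velocity_field(g, FlowConfig(n_years=1, season_days=10, seed=1))
        u, v = f.velocities_at(0, 0.0)
        assert np.all(u[~g.sea_mask] == 0)
        assert np.all(v[~g.sea_mask] == 0)

    def test_interior_divergence_small(self):
        g = make_seascape(SeascapeConfig(seed=8))
        f = make_velocity_field(g, FlowConfig(n_years=1, season_days=10, seed=2))
        u, v = f.velocities_at(0, 48.0)
        dx = g.cell_size_km * 1000
        div = np.gradient(u, dx, axis=1) + np.gradient(v, dx, axis=0)
        # interior sea cells far from the coast: divergence tiny vs shear scale
        interior = g.sea_mask.copy()
        interior[:, : g.nx // 2] = False
        speed = np.hypot(u, v)[interior].mean()
        assert np.abs(div[interior]).mean() < 1e-3 * speed / dx * 100

    def test_interannual_variability(self, open_grid):
        cfg = FlowConfig(n_years=3, season_days=20, seed=3)
        f = make_velocity_field(open_grid, cfg)
        sch = ReleaseSchedule(
            month_weights={"July": 1.0},
            duration_mixture={5.0: 1.0},
            particles_per_cell=4,
            years=[0, 1, 2],
        )
        ep = track_particles(open_grid, f, sch, seed=4, diffusivity_m2s=0)
        # same source cells each year; end positions must differ across years
        ends = {
            y: set(zip(ep.end_iy[ep.year == y].tolist(), ep.end_ix[ep.year == y].tolist()))
            for y in (0, 1, 2)
        }
        assert len(ends[0] ^ ends[1]) + len(ends[1] ^ ends[2]) > 0


class TestSimulateGenotypes:
    def test_drift_increases_dps(self):
        disp = DispersalMatrix(labels=["a", "b"], values=np.eye(2))
        cfgs = [
            SimulationConfig(seed=s, deme_size=60, n_loci=10, mutation_rate=0, generations=g, n_samples=30)
            for s in (1, 2, 3)
            for g in (20, 200)
        ]
        short, long = [], []
        for cfg in cfgs:
            table = simulate_genotypes(disp, cfg)
            d = shared_allele_distance(reduce_to_genets(table)).values[0, 1]
            (short if cfg.generations == 20 else long).append(d)
        assert np.mean(long) > np.mean(short)

    def test_panmixia_low_dps(self):
        n = 4
        disp = DispersalMatrix(labels=[f"d{i}" for i in range(n)], values=np.full((n, n), 1 / n))
        table = simulate_genotypes(
            disp, SimulationConfig(seed=5, deme_size=80, n_loci=10, generations=100, n_samples=30)
        )
        d = shared_allele_distance(reduce_to_genets(table)).values
        off = d[~np.eye(n, dtype=bool)]
        # small residual reflects finite-sample frequency noise only
        assert off.max() < 0.2

    def test_clonality_reduces_richness(self):
        disp = DispersalMatrix(labels=["a", "b"], values=np.eye(2))
        cfg = SimulationConfig(
            seed=6, deme_size=100, n_loci=10, clonality=0.9, generations=60, n_samples=40
        )
        table = simulate_genotypes(disp, cfg)
        from seaconn.genotypes import genotypic_richness, identify_clones

        per_site = identify_clones(table).genets_per_site()
        for site, mlg in per_site.items():
            assert genotypic_richness(40, mlg) < 0.8

    def test_determinism(self):
        disp = DispersalMatrix(labels=["a", "b"], values=np.eye(2))
        cfg = SimulationConfig(seed=7, deme_size=30, n_loci=4, generations=10, n_samples=10)
        assert simulate_genotypes(disp, cfg) == simulate_genotypes(disp, cfg)

    def test_isolated_deme_warning(self):
        values = np.array([[0.5, 0.0], [0.0, 0.0]])  # deme b receives nothing
        disp = DispersalMatrix(labels=["a", "b"], values=values)
        cfg = SimulationConfig(seed=8, deme_size=20, n_loci=3, generations=5, n_samples=5)
        with pytest.warns(UserWarning):
            table = simulate_genotypes(disp, cfg)
        assert table.n_ramets == 10

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(clonality=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(deme_size=0)
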