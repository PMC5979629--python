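"""Particle tracking and dispersal-matrix construction."""

import numpy as np
import pytest

from seaconn.lagrangian import (
    DispersalMatrix,
    ReleaseSchedule,
    TrajectoryEndpoints,
    build_dispersal_matrix,
    track_particles,
)
from seaconn.seascape_sim import FlowConfig, SeascapeGrid, make_velocity_field


def _schedule(**kw):
    base = dict(
        month_weights={"July": 1.0},
        duration_mixture={5.0: 1.0},
        particles_per_cell=5,
        years=[0],
    )
    base.update(kw)
    return ReleaseSchedule(**base)


class TestReleaseSchedule:
    def test_defaults_valid(self):
        s = ReleaseSchedule()
        assert sum(s.month_weights.values()) == pytest.approx(1.0)
        assert sum(s.duration_mixture.values()) == pytest.approx(1.0)

    def test_bad_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ReleaseSchedule(month_weights={"July": 0.5})
        with pytest.raises(ValueError, match="positive"):
            ReleaseSchedule(duration_mixture={-5.0: 1.0})
        with pytest.raises(ValueError, match="particles_per_cell"):
            ReleaseSchedule(particles_per_cell=0)


class TestTrackParticles:
    def test_still_field_stays_put(self, open_grid):
        f = make_velocity_field(
            open_grid,
            FlowConfig(boundary_speed=0, gyre_speed=0, noise_speed=0, n_years=1, season_days=40),
        )
        ep = track_particles(open_grid, f, _schedule(), seed=1, diffusivity_m2s=0)
        assert np.array_equal(ep.end_iy, ep.source_iy)
        assert np.array_equal(ep.end_ix, ep.source_ix)
        assert not ep.lost.any()

    def test_uniform_flow_closed_form(self, open_grid):
        # u = 0.1 m/s for 5 days = 43.2 km east = 10.8 cells of 4 km
        f = make_velocity_field(
            open_grid,
            FlowConfig(
                boundary_speed=0, gyre_speed=0, noise_speed=0, uniform_u=0.1, n_years=1, season_days=40
            ),
        )
        ep = track_particles(open_grid, f, _schedule(), seed=2, diffusivity_m2s=0)
        dx_cells = ep.end_ix - ep.source_ix
        assert np.all(np.abs(dx_cells - 10.8) <= 1.0)
        assert np.array_equal(ep.end_iy, ep.source_iy)

    def test_determinism(self, demo_grid, demo_field):
        sch = _schedule(particles_per_cell=2)
        a = track_particles(demo_grid, demo_field, sch, seed=5)
        b = track_particles(demo_grid, demo_field, sch, seed=5)
        assert np.array_equal(a.end_iy, b.end_iy)
        assert np.array_equal(a.end_ix, b.end_ix)
        assert np.array_equal(a.lost, b.lost)

    def test_beached_particles_end_in_sea(self, demo_grid, demo_field):
        ep = track_particles(demo_grid, demo_field, _schedule(particles_per_cell=3), seed=6)
        kept = ~ep.lost
        assert demo_grid.sea_mask[ep.end_iy[kept], ep.end_ix[kept]].all()

    def test_westward_flow_beaches_on_coast(self, demo_grid):
        f = make_velocity_field(
            demo_grid,
            FlowConfig(
                boundary_speed=0, gyre_speed=0, noise_speed=0, uniform_u=-0.2, n_years=1, season_days=40
            ),
        )
        ep = track_particles(demo_grid, f, _schedule(particles_per_cell=2), seed=7, diffusivity_m2s=0)
        kept = ~ep.lost
        assert demo_grid.sea_mask[ep.end_iy[kept], ep.end_ix[kept]].all()
        # pushed against the coast: no particle drifted east
        assert np.all(ep.end_ix[kept] <= ep.source_ix[kept])

    def test_release_on_land_rejected(self, open_grid):
        bad = SeascapeGrid(
            nx=open_grid.nx,
            ny=open_grid.ny,
            cell_size_km=4.0,
            sea_mask=open_grid.sea_mask.copy(),
            habitat_extant=open_grid.habitat_extant.copy(),
            habitat_historic=open_grid.habitat_historic.copy(),
            site_polygons=open_grid.site_polygons,
        )
        bad.sea_mask[9, 4] = False  # habitat cell now on land
        f = make_velocity_field(bad, FlowConfig(n_years=1, season_days=10))
        with pytest.raises(ValueError, match="on land"):
            track_particles(bad, f, _schedule(), seed=1)

    def test_unknown_year_rejected(self, open_grid):
        f = make_velocity_field(open_grid, FlowConfig(n_years=1, season_days=10))
        with pytest.raises(ValueError, match="year"):
            track_particles(open_grid, f, _schedule(years=[3]), seed=1)


class TestBuildDispersalMatrix:
    def _endpoints(self, pairs, lost=None):
        src = np.array([p[0] for p in pairs])
        dst = np.array([p[1] for p in pairs])
        n = len(pairs)
        return TrajectoryEndpoints(
            source_iy=src[:, 0],
            source_ix=src[:, 1],
            end_iy=dst[:, 0],
            end_ix=dst[:, 1],
            lost=np.zeros(n, dtype=bool) if lost is None else np.asarray(lost),
            release_hours=np.zeros(n),
            duration_hours=np.full(n, 120.0),
            year=np.zeros(n, dtype=int),
        )

    def _grid(self):
        sea = np.ones((6, 6), dtype=bool)
        hab = np.zeros((6, 6), dtype=bool)
        hab[1, 1] = hab[4, 4] = True  # cells A and B
        return SeascapeGrid(
            nx=6,
            ny=6,
            cell_size_km=4.0,
            sea_mask=sea,
            habitat_extant=hab,
            habitat_historic=hab,
            site_polygons={"A": [(1, 1)], "B": [(4, 4)]},
        )

    def test_hand_counted_probabilities(self):
        grid = self._grid()
        A, B, coast = (1, 1), (4, 4), (0, 5)
        pairs = [(A, B)] * 4 + [(A, A)] * 2 + [(A, coast)] * 4
        P = build_dispersal_matrix(self._endpoints(pairs), grid, level="cell")
        ia, ib = P.labels.index("c1_1"), P.labels.index("c4_4")
        assert P.values[ia, ib] == pytest.approx(0.4)
        assert P.values[ia, ia] == pytest.approx(0.2)
        assert np.nansum(P.values[ia]) == pytest.approx(0.6)

    def test_all_retained_identity(self):
        grid = self._grid()
        pairs = [((1, 1), (1, 1))] * 5 + [((4, 4), (4, 4))] * 5
        P = build_dispersal_matrix(self._endpoints(pairs), grid, level="cell")
        assert np.allclose(P.values, np.eye(2))

    def test_lost_particles_are_loss(self):
        grid = self._grid()
        pairs = [((1, 1), (4, 4))] * 2
        P = build_dispersal_matrix(
            self._endpoints(pairs, lost=[False, True]), grid, level="cell"
        )
        ia, ib = P.labels.index("c1_1"), P.labels.index("c4_4")
        assert P.values[ia, ib] == pytest.approx(0.5)

    def test_zero_release_row_is_nan(self):
        grid = self._grid()
        pairs = [((1, 1), (1, 1))] * 3  # nothing released from B
        with pytest.warns(UserWarning, match="released no particles"):
            P = build_dispersal_matrix(self._endpoints(pairs), grid, level="cell")
        ib = P.labels.index("c4_4")
        assert np.isnan(P.values[ib]).all()

    def test_site_aggregation_matches_direct_counting(self, demo_grid, demo_field):
        from seaconn.connectivity import aggregate_to_sites

        ep = track_particles(demo_grid, demo_field, _schedule(particles_per_cell=4), seed=9)
        siteP = build_dispersal_matrix(ep, demo_grid, level="site")
        cellP = build_dispersal_matrix(ep, demo_grid, level="cell")
        site_cells = {
            name: [demo_grid.cell_label(iy, ix) for iy, ix in cells]
            for name, cells in demo_grid.site_polygons.items()
        }
        agg = aggregate_to_sites(cellP, site_cells)
        a = agg.values[[agg.labels.index(s) for s in siteP.labels]][
            :, [agg.labels.index(s) for s in siteP.labels]
        ]
        assert np.allclose(a, siteP.values, equal_nan=True)

    def test_row_sums_at_most_one(self, demo_grid, demo_field):
        ep = track_particles(demo_grid, demo_field, _schedule(particles_per_cell=3), seed=10)
        P = build_dispersal_matrix(ep, demo_grid, level="cell")
        sums = np.nansum(P.values, axis=1)
        assert np.all(sums <= 1 + 1e-9)
        # probability conservation: arrivals + losses = releases per source
        released = P.total_released
        arrivals = np.nansum(P.values * released[:, None], axis=1)
        assert np.all(arrivals <= released + 1e-9)

    def test_empty_endpoints_rejected(self, open_grid):
        ep = TrajectoryEndpoints(*[np.array([])] * 8)
        with pytest.raises(ValueError, match="no trajectory"):
            build_dispersal_matrix(ep, open_grid)


def test_monte_carlo_error_scales_with_particles(open_grid):
    """SE of P_ij shrinks roughly like 1/sqrt(n) when releasing more."""
    f = make_velocity_field(
        open_grid,
        FlowConfig(boundary_speed=0, gyre_speed=0.06, noise_speed=0.04, n_years=1, season_days=20, seed=3),
    )

    def retention_samples(ppc, seeds):
        out = []
        for s in seeds:
            sch = _schedule(particles_per_cell=ppc, duration_mixture={10.0: 1.0})
            ep = track_particles(open_grid, f, sch, seed=s, diffusivity_m2s=50)
            P = build_dispersal_matrix(ep, open_grid, level="site")
            out.append(P.values[0, 0])
        return np.std(out, ddof=1)

    se_small = retention_samples(8, range(8))
    se_big = retention_samples(64, range(8))
    assert se_big < se_small  # 8x particles must cut the noise
    assert se_small / max(se_big, 1e-9) > 1.4  # consistent with ~sqrt(8) = 2.8
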