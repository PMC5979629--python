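"""Sea distance on the lattice and (asymmetric) Mantel tests."""

import networkx as nx
import numpy as np
import pytest

from seaconn.ibo_stats import asymmetric_mantel, mantel, sea_distance
from seaconn.seascape_sim import KM_PER_DEG_LAT, SeascapeGrid


def _grid_from_mask(sea, cell_km=1.0):
    sea = np.asarray(sea, dtype=bool)
    hab = sea.copy()
    return SeascapeGrid(
        nx=sea.shape[1],
        ny=sea.shape[0],
        cell_size_km=cell_km,
        sea_mask=sea,
        habitat_extant=hab,
        habitat_historic=hab,
        site_polygons={},
        lon0=0.0,
        lat0=0.0,
    )


def _cell_coords(grid, iy, ix):
    return grid.centroid_lonlat(iy, ix)


class TestSeaDistance:
    def test_open_water_straight_line(self):
        grid = _grid_from_mask(np.ones((9, 9)))
        coords = {
            "a": _cell_coords(grid, 4, 1),
            "b": _cell_coords(grid, 4, 7),
        }
        d = sea_distance(grid, coords)
        assert d.values[0, 1] == pytest.approx(6.0, abs=1e-6)

    def test_diagonal_cost(self):
        grid = _grid_from_mask(np.ones((9, 9)))
        coords = {"a": _cell_coords(grid, 1, 1), "b": _cell_coords(grid, 5, 5)}
        d = sea_distance(grid, coords)
        assert d.values[0, 1] == pytest.approx(4 * np.sqrt(2), abs=1e-6)

    def test_peninsula_forces_detour(self):
        sea = np.ones((9, 9), dtype=bool)
        sea[0:7, 4] = False  # wall from the top, gap at the bottom
        grid = _grid_from_mask(sea)
        coords = {"a": _cell_coords(grid, 2, 1), "b": _cell_coords(grid, 2, 7)}
        d = sea_distance(grid, coords)
        assert d.values[0, 1] > 6.0

    def test_matches_graph_oracle_on_l_wall(self):
        sea = np.ones((5, 5), dtype=bool)
        sea[1, 1:4] = False
        sea[2, 3] = False  # L-shaped wall
        grid = _grid_from_mask(sea)
        coords = {"a": _cell_coords(grid, 0, 0), "b": _cell_coords(grid, 3, 2)}
        d = sea_distance(grid, coords)
        # independent oracle: networkx Dijkstra over the same lattice
        g = nx.Graph()
        for iy in range(5):
            for ix in range(5):
                if not sea[iy, ix]:
                    continue
                for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    y2, x2 = iy + dy, ix + dx
                    if 0 <= y2 < 5 and 0 <= x2 < 5 and sea[y2, x2]:
                        w = np.sqrt(2) if dy and dx else 1.0
                        g.add_edge((iy, ix), (y2, x2), weight=w)
        oracle = nx.dijkstra_path_length(g, (0, 0), (3, 2))
        assert d.values[0, 1] == pytest.approx(oracle, abs=1e-9)

    def test_site_on_land_errors_with_name(self):
        sea = np.ones((9, 9), dtype=bool)
        sea[3:6, 3:6] = False
        grid = _grid_from_mask(sea)
        coords = {"ok": _cell_coords(grid, 0, 0), "landlocked": _cell_coords(grid, 4, 4)}
        with pytest.raises(ValueError, match="landlocked"):
            sea_distance(grid, coords, snap_radius=0)

    def test_snap_to_nearest_sea(self):
        sea = np.ones((9, 9), dtype=bool)
        sea[4, 4] = False
        grid = _grid_from_mask(sea)
        coords = {"a": _cell_coords(grid, 4, 4), "b": _cell_coords(grid, 0, 0)}
        d = sea_distance(grid, coords, snap_radius=2)
        assert np.isfinite(d.values[0, 1])

    def test_override_pins_pair(self):
        grid = _grid_from_mask(np.ones((9, 9)))
        coords = {"a": _cell_coords(grid, 4, 1), "b": _cell_coords(grid, 4, 7)}
        d = sea_distance(grid, coords, overrides={("a", "b"): 123.0})
        assert d.values[0, 1] == d.values[1, 0] == 123.0

    def test_exceeds_great_circle(self):
        grid = _grid_from_mask(np.ones((20, 20)), cell_km=4.0)
        coords = {"a": _cell_coords(grid, 2, 2), "b": _cell_coords(grid, 15, 11)}
        d = sea_distance(grid, coords)
        dy = (15 - 2) * 4.0
        dx = (11 - 2) * 4.0
        assert d.values[0, 1] >= np.hypot(dx, dy) - 1e-6


def _random_sym(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    return A


class TestMantel:
    def test_self_correlation_is_one(self):
        A = _random_sym(8, 0)
        res = mantel(A, A, permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        A = _random_sym(8, 2)
        res = mantel(A, -A, permutations=99, seed=1)
        assert res.r == pytest.approx(-1.0)

    def test_linear_rescaling_invariance(self):
        A, B = _random_sym(9, 3), _random_sym(9, 4)
        r1 = mantel(A, B, permutations=9, seed=0).r
        r2 = mantel(A * 3.5 + 2.0, B, permutations=9, seed=0).r
        assert r1 == pytest.approx(r2)

    def test_determinism(self):
        A, B = _random_sym(9, 5), _random_sym(9, 6)
        a = mantel(A, B, permutations=999, seed=7)
        b = mantel(A, B, permutations=999, seed=7)
        assert a.r == b.r and a.p == b.p

    def test_constant_matrix_rejected(self):
        A = _random_sym(5, 8)
        with pytest.raises(ValueError, match="constant"):
            mantel(A, np.zeros((5, 5)), permutations=9)

    def test_label_mismatch_rejected(self):
        from seaconn.genotypes import DistanceMatrix

        A = DistanceMatrix(["a", "b", "c"], _random_sym(3, 9))
        B = DistanceMatrix(["a", "c", "b"], _random_sym(3, 10))
        with pytest.raises(ValueError, match="labels"):
            mantel(A, B, permutations=9)

    def test_asymmetric_input_rejected(self):
        A = _random_sym(5, 11)
        B = np.random.default_rng(1).random((5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            mantel(A, B, permutations=9)

    def test_p_never_zero_and_detects_signal(self):
        rng = np.random.default_rng(12)
        A = _random_sym(12, 13)
        B = A + 0.01 * _random_sym(12, 14)
        res = mantel(A, B, permutations=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_quick_calibration(self):
        rejections = 0
        reps = 100
        for i in range(reps):
            res = mantel(_random_sym(10, 2 * i), _random_sym(10, 2 * i + 1), permutations=200, seed=i)
            rejections += res.p < 0.05
        assert 0 <= rejections / reps < 0.13


class TestAsymmetricMantel:
    def test_self_correlation(self):
        A = np.random.default_rng(0).random((7, 7))
        res = asymmetric_mantel(A, A, permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_transpose_sensitivity(self):
        rng = np.random.default_rng(1)
        A = np.triu(rng.random((8, 8)), 1)  # strongly asymmetric
        res = asymmetric_mantel(A, A.T, permutations=99, seed=0)
        assert res.r < 1.0

    def test_chain_directionality_recovery(self, chain_sim):
        from seaconn.connectivity import log_transform_matrix
        from seaconn.migration import directional_relative_migration

        mig = directional_relative_migration(chain_sim["genets"], bootstraps=0)
        directed = log_transform_matrix(chain_sim["dispersal"].values, 1e-10)
        res = asymmetric_mantel(
            np.nan_to_num(mig.values), directed, permutations=5000, seed=2
        )
        assert res.r > 0
        assert res.p < 0.05

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="square"):
            asymmetric_mantel(np.ones((2, 3)), np.ones((2, 3)), permutations=9)
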