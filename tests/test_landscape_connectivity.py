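"""Cost surfaces, circuit solves, geographic distances, range-shift flags."""

import numpy as np
import pandas as pd
import pytest

from climvuln import (DistanceMatrix, build_cost_surface, connectivity_change,
                      cumulative_current, euclidean_matrix,
                      resistance_distance)
from climvuln.landscape_connectivity import build_network
from climvuln.raster import Grid

UNIT = lambda a: np.ones_like(a)  # noqa: E731


class TestCostSurface:
    def test_suitability_rule_endpoints(self):
        g = Grid(np.array([[1.0, 0.0], [0.5, 1.0]]))
        surf = build_cost_surface(g, "suitability")
        assert surf.cost[0, 0] == 1.0
        assert surf.cost[0, 1] == 100.0
        assert surf.cost[1, 0] == pytest.approx(50.5)

    def test_sea_override_and_alternative_cost(self):
        g = Grid(np.ones((2, 2)))
        sea = np.array([[True, False], [False, False]])
        s200 = build_cost_surface(g, "suitability", sea, 200.0)
        s120 = build_cost_surface(g, "suitability", sea, 120.0)
        assert s200.cost[0, 0] == 200.0
        assert s120.cost[0, 0] == 120.0
        assert np.array_equal(s200.cost[~sea], s120.cost[~sea])

    def test_categorical_rule_and_unmapped_error(self):
        g = Grid(np.array([[1.0, 2.0], [3.0, 1.0]]))
        surf = build_cost_surface(g, {1.0: 1, 2.0: 50, 3.0: 100})
        assert surf.cost[1, 0] == 100
        with pytest.raises(ValueError, match=r"unmapped.*3"):
            build_cost_surface(g, {1.0: 1, 2.0: 50})

    def test_out_of_range_cost_rejected(self):
        g = Grid(np.ones((2, 2)))
        with pytest.raises(ValueError, match=r"\[1, 100\]"):
            build_cost_surface(g, lambda a: 150 * a)


class TestResistance:
    def test_series_law_1x3(self):
        surf = build_cost_surface(Grid(np.ones((1, 3))), UNIT)
        r = resistance_distance(surf, [(0, 0), (0, 2)], neighbors=4)
        assert r.values[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_parallel_paths_2x2(self):
        surf = build_cost_surface(Grid(np.ones((2, 2))), UNIT)
        r = resistance_distance(surf, [(0, 0), (1, 1)], neighbors=4)
        assert r.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_cost_scaling_linearity(self, rng):
        cost = rng.uniform(1, 50, size=(6, 7))
        base = build_cost_surface(Grid(cost), lambda a: a)
        doubled = build_cost_surface(Grid(2 * cost), lambda a: np.clip(a, 1, 100))
        nodes = [(0, 0), (5, 6), (2, 3)]
        r1 = resistance_distance(base, nodes)
        r2 = resistance_distance(doubled, nodes)
        assert np.allclose(r2.values, 2 * r1.values, atol=1e-9)

    def test_matches_dense_pseudoinverse_oracle(self, rng):
        """Effective resistance equals the Laplacian pseudo-inverse
        quadratic form on random grids, and is a metric."""
        for trial in range(3):
            cost = rng.uniform(1, 80, size=(7, 8))
            surf = build_cost_surface(Grid(cost), lambda a: a)
            net = build_network(surf, neighbors=8)
            L = net.laplacian.toarray()
            Lp = np.linalg.pinv(L, hermitian=True)
            nodes = [(0, 0), (6, 7), (3, 4), (0, 7)]
            r = resistance_distance(surf, nodes)
            node_ids = [net.node_of_cell[rc] for rc in nodes]
            for i in range(4):
                for j in range(i + 1, 4):
                    e = np.zeros(L.shape[0])
                    e[node_ids[i]] += 1
                    e[node_ids[j]] -= 1
                    assert r.values[i, j] == pytest.approx(e @ Lp @ e,
                                                           abs=1e-9)
            # metric: symmetry, zero diagonal, triangle inequality
            assert np.allclose(r.values, r.values.T)
            for a in range(4):
                for b in range(4):
                    for c in range(4):
                        assert r.values[a, b] <= (r.values[a, c]
                                                  + r.values[c, b] + 1e-9)

    def test_lower_cost_cell_weakly_lowers_resistance(self, rng):
        cost = rng.uniform(10, 60, size=(5, 5))
        surf1 = build_cost_surface(Grid(cost), lambda a: a)
        cost2 = cost.copy()
        cost2[2, 2] = 1.0
        surf2 = build_cost_surface(Grid(cost2), lambda a: a)
        nodes = [(0, 0), (4, 4)]
        r1 = resistance_distance(surf1, nodes)
        r2 = resistance_distance(surf2, nodes)
        assert r2.values[0, 1] <= r1.values[0, 1] + 1e-12

    def test_disconnected_pair_infinite(self):
        cost = np.ones((1, 5))
        cost[0, 2] = np.nan
        surf = build_cost_surface(Grid(cost), lambda a: a)
        r = resistance_distance(surf, [(0, 0), (0, 4)], neighbors=4)
        assert np.isinf(r.values[0, 1])

    def test_focal_on_nodata_rejected(self):
        cost = np.ones((2, 2))
        cost[0, 0] = np.nan
        surf = build_cost_surface(Grid(cost), lambda a: a)
        with pytest.raises(ValueError, match="no-data"):
            resistance_distance(surf, [(0, 0), (1, 1)])


class TestCurrent:
    def test_1x3_conservation(self):
        surf = build_cost_surface(Grid(np.ones((1, 3))), UNIT)
        cur = cumulative_current(surf, [(0, 0), (0, 2)], neighbors=4)
        assert cur.data[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert cur.data[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_two_parallel_paths_split_evenly(self):
        cost = np.ones((3, 3))
        cost[1, 1] = np.nan           # block the centre: two mirror paths
        surf = build_cost_surface(Grid(cost), lambda a: a)
        cur = cumulative_current(surf, [(1, 0), (1, 2)], neighbors=4)
        assert cur.data[0, 1] == pytest.approx(0.5, abs=1e-9)
        assert cur.data[2, 1] == pytest.approx(0.5, abs=1e-9)

    def test_interior_node_conservation(self, rng):
        """Signed branch currents sum to ~0 at every non-focal node."""
        cost = rng.uniform(1, 40, size=(6, 6))
        surf = build_cost_surface(Grid(cost), lambda a: a)
        net = build_network(surf, neighbors=8)
        from climvuln.landscape_connectivity import _ComponentSolver

        sol = _ComponentSolver(net, 0)
        a = int(net.node_of_cell[0, 0])
        b = int(net.node_of_cell[5, 5])
        v_local = sol.potentials(a, b)
        v = np.zeros(len(net.cells))
        v[sol.nodes] = v_local
        i_edge = (v[net.edges[:, 0]] - v[net.edges[:, 1]]) * net.conductance
        net_flow = np.zeros(len(net.cells))
        np.add.at(net_flow, net.edges[:, 0], -i_edge)
        np.add.at(net_flow, net.edges[:, 1], i_edge)
        interior = np.ones(len(net.cells), bool)
        interior[[a, b]] = False
        assert np.abs(net_flow[interior]).max() < 1e-9
        assert net_flow[a] == pytest.approx(-1.0, abs=1e-9)
        assert net_flow[b] == pytest.approx(1.0, abs=1e-9)

    def test_currents_nonnegative_nan_on_nodata(self, rng):
        cost = rng.uniform(1, 20, size=(5, 5))
        cost[0, 3] = np.nan
        surf = build_cost_surface(Grid(cost), lambda a: a)
        cur = cumulative_current(surf, [(0, 0), (4, 4), (4, 0)])
        assert np.isnan(cur.data[0, 3])
        assert np.nanmin(cur.data) >= 0


class TestEuclidean:
    def test_planar_3_4_5(self):
        pops = pd.DataFrame({"pop": ["a", "b"], "x": [0.0, 3.0],
                             "y": [0.0, 4.0]})
        d = euclidean_matrix(pops)
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_permutation_equivariance(self, rng):
        pops = pd.DataFrame({"pop": list("abcd"),
                             "x": rng.random(4), "y": rng.random(4)})
        d = euclidean_matrix(pops)
        perm = [2, 0, 3, 1]
        d2 = euclidean_matrix(pops.iloc[perm].reset_index(drop=True))
        assert np.allclose(d2.values,
                           d.values[np.ix_(perm, perm)])

    def test_greatcircle_sane(self):
        pops = pd.DataFrame({"pop": ["eq", "pole"], "x": [0.0, 0.0],
                             "y": [0.0, 90.0]})
        d = euclidean_matrix(pops, mode="greatcircle")
        assert d.values[0, 1] == pytest.approx(10007.5, rel=0.01)

    def test_missing_coordinates_rejected(self):
        pops = pd.DataFrame({"pop": ["a", "b"], "x": [0.0, np.nan],
                             "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            euclidean_matrix(pops)


class TestConnectivityChange:
    def _pops(self):
        return pd.DataFrame({
            "pop": ["P1", "P2"], "row": [1, 3], "col": [1, 3],
            "suitable_future": [True, True],
        })

    def test_identical_maps_all_positive(self):
        cur = Grid(np.full((5, 5), 2.0))
        flags = connectivity_change(cur, cur, self._pops(), buffer_radius=1)
        assert (flags["range_shift"] == "+").all()

    def test_collapsed_future_current_flags_negative(self):
        now = Grid(np.full((5, 5), 2.0))
        fut_data = np.full((5, 5), 2.0)
        fut_data[2:, 2:] = 0.01            # P2's neighbourhood collapses
        flags = connectivity_change(now, Grid(fut_data), self._pops(),
                                    buffer_radius=1, tau=0.5)
        assert flags.set_index("pop").loc["P2", "range_shift"] == "-"
        assert flags.set_index("pop").loc["P1", "range_shift"] == "+"

    def test_corridors_to_unsuitable_only(self):
        cur = Grid(np.full((5, 5), 2.0))
        pops = self._pops()
        pops["suitable_future"] = [True, False]
        rn = DistanceMatrix(["P1", "P2"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        flags = connectivity_change(cur, cur, pops, buffer_radius=1,
                                    resistance_now=rn, resistance_future=rn)
        # P1's only corridor ends in a future-unsuitable population
        assert flags.set_index("pop").loc["P1", "range_shift"] == "-"
        assert flags.set_index("pop").loc["P2", "range_shift"] == "+"

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            connectivity_change(Grid(np.ones((4, 4))), Grid(np.ones((5, 5))),
                                self._pops())
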