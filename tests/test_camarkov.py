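"""Transition estimation, demand projection, and CA allocation."""

import numpy as np
import pytest

from lesim.camarkov import (
    CAConfig,
    CAState,
    TransitionMatrix,
    allocate_cycle,
    largest_remainder,
    neighborhood_factor,
    pair_demands,
    project_demand,
    simulate,
    transition_matrix,
)
from lesim.grids import LandUseMap, RasterGrid
from lesim.suitability import SuitabilityAtlas


def lumap(values, legend=None):
    vals = np.asarray(values, dtype=np.int32)
    return LandUseMap(RasterGrid(vals), legend or {1: "farmland", 2: "woodland"})


def naive_neighborhood(values, code, window):
    """Window-fraction oracle by explicit loops (edge-truncated)."""
    r, c = values.shape
    half = window // 2
    out = np.zeros((r, c))
    for i in range(r):
        for j in range(c):
            win = values[max(0, i - half) : i + half + 1, max(0, j - half) : j + half + 1]
            out[i, j] = np.mean(win == code)
    return out


class TestTransitionMatrix:
    def test_identical_maps_identity(self):
        m = lumap([[1, 2], [2, 1]])
        P = transition_matrix(m, m)
        np.testing.assert_allclose(P.P, np.eye(2))

    def test_single_cell_change_counted(self):
        a = lumap([[1, 1], [1, 1]], {1: "farmland", 2: "woodland"})
        b = lumap([[1, 1], [1, 2]], {1: "farmland", 2: "woodland"})
        P = transition_matrix(a, b)
        np.testing.assert_allclose(P.P[0], [0.75, 0.25])

    def test_rows_sum_to_one_and_absent_class_identity(self, world60):
        t0, t1 = world60
        P = transition_matrix(t0, t1)
        np.testing.assert_allclose(P.P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(P.P >= 0)

    def test_misaligned_maps_rejected(self):
        a = lumap([[1, 2]])
        b = lumap([[1], [2]])
        with pytest.raises(ValueError, match="aligned"):
            transition_matrix(a, b)


class TestDemand:
    def test_identity_matrix_keeps_base_counts(self):
        P = TransitionMatrix([1, 2], np.eye(2), [30, 70])
        np.testing.assert_array_equal(project_demand(P), [30, 70])

    def test_direct_product(self):
        P = TransitionMatrix([1, 2], [[0.9, 0.1], [0.0, 1.0]], [100, 0])
        np.testing.assert_array_equal(project_demand(P), [90, 10])

    def test_total_conserved_under_any_matrix(self):
        rng = np.random.default_rng(0)
        M = rng.random((4, 4))
        M /= M.sum(axis=1, keepdims=True)
        base = rng.integers(0, 1000, 4)
        P = TransitionMatrix([1, 2, 3, 4], M, base)
        assert project_demand(P).sum() == base.sum()

    def test_largest_remainder_conserves_and_orders(self):
        out = largest_remainder(np.array([1.4, 1.4, 1.2]), total=4)
        assert out.sum() == 4
        assert out.tolist() == [2, 1, 1]  # first of the tied largest remainders

    def test_pair_demands_match_row_budgets(self):
        P = TransitionMatrix([1, 2], [[0.8, 0.2], [0.3, 0.7]], [10, 10])
        pairs = pair_demands(P)
        assert pairs == {(1, 2): 2, (2, 1): 3}


class TestNeighborhood:
    def test_uniform_map_gives_one(self):
        m = lumap(np.ones((6, 6)))
        np.testing.assert_allclose(neighborhood_factor(m, 1, 5).values, 1.0)

    def test_isolated_interior_cell_is_one_twentyfifth(self):
        vals = np.ones((9, 9), dtype=np.int32)
        vals[4, 4] = 2
        m = lumap(vals)
        assert neighborhood_factor(m, 2, 5).values[4, 4] == pytest.approx(1 / 25)

    def test_absent_class_zero_everywhere(self):
        m = lumap(np.ones((4, 4)))
        assert np.all(neighborhood_factor(m, 2, 5).values == 0)

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_loop_oracle_with_edge_truncation(self, window):
        rng = np.random.default_rng(2)
        vals = rng.integers(1, 3, (7, 8)).astype(np.int32)
        m = lumap(vals)
        got = neighborhood_factor(m, 1, window).values
        np.testing.assert_allclose(got, naive_neighborhood(vals, 1, window))


def greedy_oracle(values, Q, quota_pairs, frozen, window=5, eps=0.01):
    """Independent greedy allocation on a small grid.

    Gaining classes in descending total demand; per gaining class, sources
    in descending demand; candidates ranked by Q*(eps+h) with h from the
    cycle-start state; ties by (row, col); one change per cell.
    """
    out = values.copy()
    locked = np.zeros(values.shape, dtype=bool)
    gains = sorted(
        {v for (_, v) in quota_pairs},
        key=lambda v: (-sum(q for (u, vv), q in quota_pairs.items() if vv == v), v),
    )
    h = {v: naive_neighborhood(values, v, window) for v in gains}
    for v in gains:
        srcs = sorted(
            [u for (u, vv) in quota_pairs if vv == v],
            key=lambda u: (-quota_pairs[(u, v)], u),
        )
        for u in srcs:
            score = Q[v] * (eps + h[v])
            cand = [
                (r, c)
                for r in range(values.shape[0])
                for c in range(values.shape[1])
                if out[r, c] == u and not frozen[r, c] and not locked[r, c] and Q[v][r, c] > 0
            ]
            cand.sort(key=lambda rc: (-score[rc], rc[0], rc[1]))
            for r, c in cand[: quota_pairs[(u, v)]]:
                out[r, c] = v
                locked[r, c] = True
    return out


class TestAllocateCycle:
    legend = {1: "farmland", 2: "woodland", 5: "construction"}

    def make_state(self, values):
        return CAState(lumap(values, self.legend), remaining={})

    def atlas_from(self, grid, Q_by_class):
        rasters = {}
        for code, q in Q_by_class.items():
            g = grid.with_values(np.asarray(q, dtype=float))
            rasters[code] = g
        return SuitabilityAtlas(rasters)

    def test_zero_demand_leaves_state_unchanged(self):
        vals = np.array([[1, 1], [1, 5]], dtype=np.int32)
        state = self.make_state(vals)
        atlas = self.atlas_from(state.landuse.grid, {1: np.ones((2, 2)), 5: np.ones((2, 2))})
        out = allocate_cycle(state, atlas, {}, CAConfig(cycles=1))
        np.testing.assert_array_equal(out.landuse.grid.values, vals)

    def test_dominant_candidate_converts(self):
        vals = np.array([[1, 1, 1], [1, 5, 1], [1, 1, 1]], dtype=np.int32)
        Q5 = np.full((3, 3), 0.1)
        Q5[0, 2] = 0.9  # strictly dominating suitability
        state = self.make_state(vals)
        atlas = self.atlas_from(state.landuse.grid, {5: Q5})
        out = allocate_cycle(state, atlas, {(1, 5): 1}, CAConfig(cycles=1))
        assert out.landuse.grid.values[0, 2] == 5
        assert (out.landuse.grid.values == 5).sum() == 2

    def test_matches_greedy_oracle_six_by_six(self):
        rng = np.random.default_rng(13)
        vals = rng.choice([1, 2, 5], size=(6, 6), p=[0.5, 0.3, 0.2]).astype(np.int32)
        Q = {5: rng.random((6, 6)), 2: rng.random((6, 6))}
        frozen = np.zeros((6, 6), dtype=bool)
        quota = {(1, 5): 4, (1, 2): 2}
        state = self.make_state(vals)
        atlas = self.atlas_from(state.landuse.grid, Q)
        got = allocate_cycle(state, atlas, quota, CAConfig(cycles=1, frozen=frozen))
        expect = greedy_oracle(vals, Q, quota, frozen)
        np.testing.assert_array_equal(got.landuse.grid.values, expect)

    def test_frozen_cells_never_change(self):
        vals = np.full((4, 4), 1, dtype=np.int32)
        frozen = np.zeros((4, 4), dtype=bool)
        frozen[0] = True
        state = self.make_state(vals)
        atlas = self.atlas_from(state.landuse.grid, {5: np.ones((4, 4))})
        out = allocate_cycle(
            state, atlas, {(1, 5): 16}, CAConfig(cycles=1, frozen=frozen)
        )
        assert np.all(out.landuse.grid.values[0] == 1)
        assert (out.landuse.grid.values == 5).sum() == 12


class TestSimulate:
    def test_identity_matrix_reproduces_base(self, world60):
        t0, _ = world60
        codes = t0.codes
        P = TransitionMatrix(
            codes, np.eye(len(codes)), [t0.class_counts()[c] for c in codes]
        )
        atlas = SuitabilityAtlas(
            {c: t0.grid.with_values(np.full(t0.grid.shape, 0.5)) for c in codes}
        )
        out, log = simulate(t0, P, atlas, CAConfig(cycles=5))
        np.testing.assert_array_equal(out.grid.values, t0.grid.values)

    def test_demand_met_and_counts_conserved(self, world60):
        t0, t1 = world60
        P = transition_matrix(t0, t1)
        rng = np.random.default_rng(1)
        atlas = SuitabilityAtlas(
            {c: t0.grid.with_values(rng.random(t0.grid.shape)) for c in t0.codes}
        )
        out, log = simulate(t1, P, atlas, CAConfig(cycles=10))
        assert sum(out.class_counts().values()) == sum(t1.class_counts().values())
        if not log["shortfalls"]:
            target = project_demand(P, [t1.class_counts()[c] for c in P.codes])
            got = [out.class_counts()[c] for c in P.codes]
            np.testing.assert_array_equal(got, target)

    def test_bit_identical_reruns(self, world60):
        t0, t1 = world60
        P = transition_matrix(t0, t1)
        rng = np.random.default_rng(2)
        atlas = SuitabilityAtlas(
            {c: t0.grid.with_values(rng.random(t0.grid.shape)) for c in t0.codes}
        )
        a, _ = simulate(t1, P, atlas, CAConfig(cycles=10, seed=5))
        b, _ = simulate(t1, P, atlas, CAConfig(cycles=10, seed=5))
        np.testing.assert_array_equal(a.grid.values, b.grid.values)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CAConfig(cycles=0)
        with pytest.raises(ValueError):
            CAConfig(filter_size=4)
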