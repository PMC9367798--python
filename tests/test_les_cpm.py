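"""Indicator standardization, entropy weights, CPM aggregation, adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesim import les_cpm as lc


def make_table(values: dict, attributes: dict) -> lc.IndicatorTable:
    return lc.IndicatorTable(pd.DataFrame(values), attributes)


class TestStandardize:
    def test_positive_indicator_direct_evaluation(self):
        t = lc.standardize(make_table({"a": [2.0, 4.0, 6.0]}, {"a": "positive"}))
        np.testing.assert_allclose(t.standardized["a"], [0.0, 0.5, 1.0])

    def test_column_max_maps_to_one_positive_zero_negative(self):
        t = make_table({"p": [1.0, 3.0], "n": [1.0, 3.0]}, {"p": "positive", "n": "negative"})
        s = lc.standardize(t).standardized
        assert s["p"].iloc[1] == 1.0
        assert s["n"].iloc[1] == 0.0

    def test_constant_column_raises(self):
        t = make_table({"a": [2.0, 2.0, 2.0]}, {"a": "positive"})
        with pytest.raises(ValueError, match="constant"):
            lc.standardize(t)


class TestEntropyWeights:
    def test_constant_column_gets_zero_weight(self):
        t = make_table(
            {"vary": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]},
            {"vary": "positive", "flat": "positive"},
        )
        # standardize would reject the flat column; feed H values directly
        h = pd.DataFrame({"vary": [0.0, 0.5, 1.0], "flat": [0.7, 0.7, 0.7]})
        t = lc.IndicatorTable(t.values, t.attributes, standardized=h)
        w = lc.entropy_weights(t)
        assert w["flat"] == pytest.approx(0.0, abs=1e-12)
        assert w["vary"] == pytest.approx(1.0)

    def test_duplicated_indicators_share_weight_equally(self):
        t = make_table(
            {"a": [1.0, 4.0, 9.0], "b": [1.0, 4.0, 9.0]},
            {"a": "positive", "b": "positive"},
        )
        w = lc.entropy_weights(lc.standardize(t))
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_matches_hand_computed_entropy_formula(self):
        # independent spreadsheet-style evaluation of p_ij, e_j, w_j
        rng = np.random.default_rng(5)
        x = rng.random((4, 3)) * 10
        t = lc.standardize(
            make_table(
                {f"i{j}": x[:, j] for j in range(3)},
                {f"i{j}": "positive" for j in range(3)},
            )
        )
        h = t.standardized.to_numpy()
        p = h / h.sum(axis=0)
        e = np.zeros(3)
        for j in range(3):
            s = 0.0
            for i in range(4):
                if p[i, j] > 0:
                    s += p[i, j] * np.log(p[i, j])
            e[j] = -s / np.log(4)
        expect = (1 - e) / (1 - e).sum()
        np.testing.assert_allclose(lc.entropy_weights(t).to_numpy(), expect)

    def test_weights_sum_to_one_and_unit_permutation_equivariant(self):
        rng = np.random.default_rng(2)
        x = rng.random((6, 4))
        cols = {f"i{j}": x[:, j] for j in range(4)}
        attrs = {f"i{j}": "positive" for j in range(4)}
        w1 = lc.entropy_weights(lc.standardize(make_table(cols, attrs)))
        assert w1.sum() == pytest.approx(1.0)
        perm = rng.permutation(6)
        cols2 = {k: v[perm] for k, v in cols.items()}
        w2 = lc.entropy_weights(lc.standardize(make_table(cols2, attrs)))
        np.testing.assert_allclose(w1, w2)


class TestRankChildren:
    def test_leaf_weights_rank_descending(self):
        h = lc.CPMHierarchy(
            lc.CPMNode("C1", [lc.CPMNode("D1"), lc.CPMNode("D2")])
        )
        ranked = lc.rank_children(h, {"D1": 0.005, "D2": 0.012})
        assert [c.name for c in ranked.root.children] == ["D2", "D1"]

    def test_equal_weights_keep_declaration_order(self):
        h = lc.CPMHierarchy(lc.CPMHierarchy(
            lc.CPMNode("n", [lc.CPMNode("x"), lc.CPMNode("y")])
        ).root)
        ranked = lc.rank_children(h, {"x": 0.5, "y": 0.5})
        assert [c.name for c in ranked.root.children] == ["x", "y"]

    def test_criteria_ranked_by_summed_descendant_weights(self):
        h = lc.default_psr_hierarchy()
        ranked = lc.rank_children(h, h.declared_weights())
        assert [c.name for c in ranked.root.children] == ["B2", "B3", "B1"]


class TestAggregate:
    def cusp(self):
        return lc.CPMHierarchy(lc.CPMNode("n", [lc.CPMNode("a"), lc.CPMNode("b")]))

    def test_extremes_propagate(self):
        h = lc.default_psr_hierarchy()
        assert lc.cpm_aggregate(h, 1.0) == pytest.approx(1.0)
        assert lc.cpm_aggregate(h, 0.0) == pytest.approx(0.0)

    def test_cusp_hand_evaluation(self):
        assert lc.cpm_aggregate(self.cusp(), {"a": 0.25, "b": 0.027}) == pytest.approx(0.4)

    def test_depth_one_fold_is_square_root(self):
        h = lc.CPMHierarchy(lc.CPMNode("n", [lc.CPMNode("a")]))
        for v in [0.0, 0.04, 0.5, 1.0]:
            assert lc.cpm_aggregate(h, {"a": v}) == pytest.approx(np.sqrt(v))

    def test_noncomplementary_is_min_and_below_complementary(self):
        comp = self.cusp()
        noncomp = lc.CPMHierarchy(
            lc.CPMNode("n", [lc.CPMNode("a"), lc.CPMNode("b")], principle="non-complementary")
        )
        vals = {"a": 0.25, "b": 0.027}
        lo = lc.cpm_aggregate(noncomp, vals)
        hi = lc.cpm_aggregate(comp, vals)
        assert lo == pytest.approx(0.3)  # min(sqrt(.25), cbrt(.027))
        assert lo <= hi

    def test_more_than_four_children_rejected(self):
        with pytest.raises(ValueError, match="at most 4"):
            lc.CPMNode("n", [lc.CPMNode(f"c{i}") for i in range(5)])

    def test_leaf_value_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            lc.cpm_aggregate(self.cusp(), {"a": 1.2, "b": 0.5})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        base=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        idx=st.integers(0, 2),
        bump=st.floats(0.001, 0.5),
    )
    def test_monotone_in_every_leaf(self, base, idx, bump):
        h = lc.CPMHierarchy(
            lc.CPMNode(
                "r",
                [
                    lc.CPMNode("f", [lc.CPMNode("a"), lc.CPMNode("b")]),
                    lc.CPMNode("c"),
                ],
            )
        )
        names = ["a", "b", "c"]
        lo = dict(zip(names, base))
        hi = dict(lo)
        hi[names[idx]] = min(1.0, lo[names[idx]] + bump)
        assert lc.cpm_aggregate(h, hi) >= lc.cpm_aggregate(h, lo) - 1e-12


class TestReferenceLevels:
    def test_boundaries_and_strict_monotonicity(self):
        h = lc.default_psr_hierarchy()
        ranked = lc.rank_children(h, h.declared_weights())
        lev = lc.reference_levels(ranked)
        assert lev[0] == 0.0 and lev[10] == pytest.approx(1.0)
        assert np.all(np.diff(lev) > 0)

    def test_cusp_midlevel_hand_value(self):
        h = lc.CPMHierarchy(lc.CPMNode("n", [lc.CPMNode("a"), lc.CPMNode("b")]))
        lev = lc.reference_levels(h)
        assert lev[5] == pytest.approx((np.sqrt(0.5) + 0.5 ** (1 / 3)) / 2, abs=1e-9)
        assert lev[5] == pytest.approx(0.7504, abs=5e-5)


class TestAdjustIndex:
    levels = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.85, 0.95, 0.97, 1.0])

    def test_interval_endpoints(self):
        # at n_i: monotone gives i*0.1, verbatim gives 0
        assert lc.adjust_index(0.85, self.levels, "monotone") == pytest.approx(0.7)
        assert lc.adjust_index(0.85, self.levels, "verbatim") == pytest.approx(0.0)
        # at the top level n_10 = 1: verbatim closes its interval at 0.1
        assert lc.adjust_index(1.0, self.levels, "verbatim") == pytest.approx(0.1)
        assert lc.adjust_index(1.0, self.levels, "monotone") == pytest.approx(1.0)

    def test_interior_hand_evaluation(self):
        assert lc.adjust_index(0.90, self.levels, "verbatim") == pytest.approx(0.05)
        assert lc.adjust_index(0.90, self.levels, "monotone") == pytest.approx(0.75)

    def test_monotone_variant_preserves_ordering(self):
        rng = np.random.default_rng(8)
        L = rng.random(200)
        adj = lc.adjust_index(L, self.levels, "monotone")
        order = np.argsort(L)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_raw_index_rejected(self):
        with pytest.raises(ValueError):
            lc.adjust_index(1.5, self.levels)


def test_yaml_hierarchy_roundtrip(tmp_path):
    text = """
name: root
children:
  - name: f1
    principle: non-complementary
    children: [a, b]
  - name: c
    weight: 0.2
"""
    p = tmp_path / "h.yaml"
    p.write_text(text)
    h = lc.load_hierarchy(p)
    assert h.leaf_names() == ["a", "b", "c"]
    assert h.root.children[0].principle == "non-complementary"
    assert h.root.children[0].model == "cusp"
    assert h.declared_weights() == {"c": 0.2}
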