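"""TOPSIS chain: normalisation, weighting, ideals, separations, closeness."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_decision_matrix
from vinecover import (
    CriterionSpec,
    apply_weights,
    ideal_solutions,
    make_decision_matrix,
    rank_alternatives,
    vector_normalize,
)
from vinecover.topsis import (
    BENEFIT,
    COST,
    DegeneracyWarning,
    DegenerateColumnError,
)


def brute_force_topsis(values, weights, directions):
    """Independent arithmetic oracle: plain-Python loops, no numpy."""
    n, m = len(values), len(values[0])
    norms = [math.sqrt(sum(values[i][j] ** 2 for i in range(n))) for j in range(m)]
    v = [[weights[j] * values[i][j] / norms[j] for j in range(m)] for i in range(n)]
    pis, nis = [], []
    for j in range(m):
        col = [v[i][j] for i in range(n)]
        if directions[j] == BENEFIT:
            pis.append(max(col)); nis.append(min(col))
        else:
            pis.append(min(col)); nis.append(max(col))
    d_star = [math.sqrt(sum((v[i][j] - pis[j]) ** 2 for j in range(m))) for i in range(n)]
    d_minus = [math.sqrt(sum((v[i][j] - nis[j]) ** 2 for j in range(m))) for i in range(n)]
    rc = [d_minus[i] / (d_star[i] + d_minus[i]) for i in range(n)]
    return d_star, d_minus, rc


def equal_weight_matrix(values, directions=None):
    values = np.asarray(values, float)
    m = values.shape[1]
    directions = directions or [BENEFIT] * m
    crits = [CriterionSpec(f"c{j}", directions[j], 1 / m) for j in range(m)]
    return make_decision_matrix(values, [f"a{i}" for i in range(len(values))], crits)


class TestNormalize:
    def test_3_4_5_triangle(self):
        dm = equal_weight_matrix([[3], [4]])
        np.testing.assert_allclose(
            vector_normalize(dm).r_values, [[0.6], [0.8]], atol=1e-12
        )

    def test_column_scale_cancels(self):
        dm1 = equal_weight_matrix([[7, 9], [8, 7], [9, 6]])
        dm2 = equal_weight_matrix([[7, 90], [8, 70], [9, 60]])
        np.testing.assert_allclose(
            vector_normalize(dm1).r_values, vector_normalize(dm2).r_values, atol=1e-12
        )

    def test_matches_arithmetic_oracle(self):
        vals = [[7, 9], [8, 7], [9, 6]]
        r = vector_normalize(equal_weight_matrix(vals)).r_values
        for j in range(2):
            norm = math.sqrt(sum(row[j] ** 2 for row in vals))
            for i in range(3):
                assert r[i, j] == pytest.approx(vals[i][j] / norm, abs=1e-12)

    def test_unit_column_norms(self):
        rng = np.random.default_rng(3)
        dm = random_decision_matrix(rng, n=6, m=4)
        r = vector_normalize(dm).r_values
        np.testing.assert_allclose(np.sqrt((r**2).sum(axis=0)), 1.0, atol=1e-9)

    def test_all_zero_column_rejected_at_construction(self):
        with pytest.raises(DegenerateColumnError, match="c1"):
            equal_weight_matrix([[1, 0], [2, 0]])


class TestApplyWeights:
    def test_equal_weights_divide_by_m(self):
        dm = equal_weight_matrix([[7, 9], [8, 7], [9, 6]])
        nm = vector_normalize(dm)
        v = apply_weights(nm, [0.5, 0.5]).v_values
        np.testing.assert_allclose(v, nm.r_values / 2, atol=1e-15)

    def test_zero_weight_zeroes_the_column(self):
        dm = equal_weight_matrix([[7, 9], [8, 7], [9, 6]])
        nm = apply_weights(vector_normalize(dm), [1.0, 0.0])
        assert (nm.v_values[:, 1] == 0).all()
        ideals = ideal_solutions(nm.v_values, dm.criteria)
        assert ideals.pis[1] == ideals.nis[1] == 0

    def test_dimension_mismatch(self):
        dm = equal_weight_matrix([[7, 9], [8, 7]])
        with pytest.raises(ValueError):
            apply_weights(vector_normalize(dm), [1.0])


class TestIdealSolutions:
    def test_benefit_column(self):
        ideals = ideal_solutions(
            np.array([[0.1], [0.3]]), [CriterionSpec("b", BENEFIT, 1.0)]
        )
        assert ideals.pis[0] == 0.3 and ideals.nis[0] == 0.1

    def test_cost_column(self):
        ideals = ideal_solutions(
            np.array([[0.1], [0.3]]), [CriterionSpec("c", COST, 1.0)]
        )
        assert ideals.pis[0] == 0.1 and ideals.nis[0] == 0.3

    def test_mixed_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, size=(3, 2))
        crits = [CriterionSpec("b", BENEFIT, 0.5), CriterionSpec("c", COST, 0.5)]
        ideals = ideal_solutions(v, crits)
        assert ideals.pis[0] == max(v[:, 0]) and ideals.nis[0] == min(v[:, 0])
        assert ideals.pis[1] == min(v[:, 1]) and ideals.nis[1] == max(v[:, 1])


class TestRankAlternatives:
    def test_toy_chain_matches_brute_force_oracle(self, toy_3x2):
        res = rank_alternatives(toy_3x2)
        d_star, d_minus, rc = brute_force_topsis(
            [[7, 2], [8, 3], [9, 1]], [0.6, 0.4], [BENEFIT, COST]
        )
        np.testing.assert_allclose(res.d_star, d_star, atol=1e-12)
        np.testing.assert_allclose(res.d_minus, d_minus, atol=1e-12)
        np.testing.assert_allclose(res.rc, rc, atol=1e-12)

    def test_two_alternatives_rc_sums_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            dm = random_decision_matrix(rng, n=2)
            rc = rank_alternatives(dm).rc
            assert rc.sum() == pytest.approx(1.0, abs=1e-9)

    def test_strict_dominator_gets_rc_one(self):
        dm = make_decision_matrix(
            [[9, 1], [5, 3], [4, 6]],
            ["best", "mid", "low"],
            [CriterionSpec("b", BENEFIT, 0.7), CriterionSpec("c", COST, 0.3)],
        )
        res = rank_alternatives(dm)
        assert res.rc_of("best") == pytest.approx(1.0, abs=1e-12)
        assert res.rank_of("best") == 1

    def test_ranks_are_permutation_and_ordered_by_rc(self):
        rng = np.random.default_rng(23)
        dm = random_decision_matrix(rng, n=7, m=4)
        res = rank_alternatives(dm)
        assert sorted(res.rank) == list(range(1, 8))
        order = np.argsort(res.rank)
        assert (np.diff(res.rc[order]) <= 1e-15).all()

    def test_permuting_alternatives_permutes_rc(self):
        rng = np.random.default_rng(29)
        dm = random_decision_matrix(rng, n=6, m=3)
        perm = rng.permutation(6)
        dm2 = make_decision_matrix(
            dm.values[perm],
            [dm.alternative_labels[i] for i in perm],
            dm.criteria,
        )
        np.testing.assert_allclose(
            rank_alternatives(dm2).rc, rank_alternatives(dm).rc[perm], atol=1e-12
        )

    def test_permuting_criteria_leaves_rc_unchanged(self):
        rng = np.random.default_rng(31)
        dm = random_decision_matrix(rng, n=5, m=4)
        perm = rng.permutation(4)
        dm2 = make_decision_matrix(
            dm.values[:, perm],
            dm.alternative_labels,
            [dm.criteria[j] for j in perm],
        )
        np.testing.assert_allclose(
            rank_alternatives(dm2).rc, rank_alternatives(dm).rc, atol=1e-12
        )

    def test_zero_weight_equals_column_deletion(self):
        rng = np.random.default_rng(37)
        base = random_decision_matrix(rng, n=5, m=4)
        w = base.weights.copy()
        w[2] = 0.0
        w = w / w.sum()
        # zero out criterion 2, renormalizing the rest
        zeroed = make_decision_matrix(
            base.values,
            base.alternative_labels,
            [CriterionSpec(c.name, c.direction, float(w[j]))
             for j, c in enumerate(base.criteria)],
        )
        keep = [0, 1, 3]
        w_del = base.weights[keep] / base.weights[keep].sum()
        deleted = make_decision_matrix(
            base.values[:, keep],
            base.alternative_labels,
            [CriterionSpec(base.criteria[j].name, base.criteria[j].direction,
                           float(w_del[k])) for k, j in enumerate(keep)],
        )
        np.testing.assert_allclose(
            rank_alternatives(zeroed).rc, rank_alternatives(deleted).rc, atol=1e-12
        )

    def test_identical_alternatives_get_half_with_warning(self):
        dm = equal_weight_matrix([[2, 3], [2, 3]])
        with pytest.warns(DegeneracyWarning):
            res = rank_alternatives(dm)
        np.testing.assert_allclose(res.rc, [0.5, 0.5], atol=1e-15)
        assert res.ties

    def test_constant_column_warns_but_ranks(self):
        dm = equal_weight_matrix([[2, 5], [2, 3], [2, 1]])
        with pytest.warns(DegeneracyWarning):
            res = rank_alternatives(dm)
        assert res.rank_of("a0") == 1

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            equal_weight_matrix([[1, -2], [2, 3]])

    def test_ties_get_consecutive_ranks_in_input_order(self):
        dm = equal_weight_matrix([[3, 4], [4, 3], [5, 5]])
        res = rank_alternatives(dm)
        # equal column norms and equal weights make a0/a1 mirror images
        assert res.rc[0] == pytest.approx(res.rc[1], abs=1e-12)
        assert res.rank_of("a0") + 1 == res.rank_of("a1")
        assert ("a0", "a1") in res.ties

    def test_invert_costs_mode_regression(self, toy_3x2):
        d_star, d_minus, rc = brute_force_topsis(
            [[7, 1], [8, 0], [9, 2]], [0.6, 0.4], [BENEFIT, BENEFIT]
        )
        res = rank_alternatives(toy_3x2, invert_costs=True)
        np.testing.assert_allclose(res.rc, rc, atol=1e-12)

    def test_invert_costs_constant_cost_column_warns(self):
        dm = equal_weight_matrix([[2, 5], [2, 3], [2, 1]], [COST, BENEFIT])
        with pytest.warns(DegeneracyWarning):
            res = rank_alternatives(dm, invert_costs=True)
        assert np.isfinite(res.rc).all()


@settings(derandomize=True, max_examples=80, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_rc_always_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    dm = random_decision_matrix(rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegeneracyWarning)
        rc = rank_alternatives(dm).rc
    assert (rc >= -1e-15).all() and (rc <= 1 + 1e-15).all()


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_column_scale_invariance_of_rc(seed):
    rng = np.random.default_rng(seed)
    dm = random_decision_matrix(rng, n=5, m=3)
    scale = rng.uniform(0.5, 20.0, size=3)
    dm2 = make_decision_matrix(
        dm.values * scale, dm.alternative_labels, dm.criteria
    )
    np.testing.assert_allclose(
        rank_alternatives(dm2).rc, rank_alternatives(dm).rc, atol=1e-10
    )
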