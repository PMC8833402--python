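"""Statistical kernels vs independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cirblood.stats import (DesignError, ats_test, bh_adjust,
                            bonferroni_adjust, mixed_model_wald,
                            tost_equivalence, wts_rank_interaction)


def bh_stepup_oracle(p):
    """Hand-rolled BH step-up: q_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_matches_bonferroni(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)
        assert bonferroni_adjust([0.037])[0] == pytest.approx(0.037)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_stepup_oracle_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_stepup_oracle(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestTost:
    def test_p_is_max_of_one_sided(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(0.3, 1, size=6)
            r = tost_equivalence(a, b, margin=1.0)
            assert r.p == pytest.approx(max(r.p_lower, r.p_upper))

    def test_agrees_with_statsmodels_to_1e10(self):
        from statsmodels.stats.weightstats import ttost_ind
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 12))
            b = rng.normal(0.2, 1.5, size=rng.integers(3, 12))
            margin = float(rng.uniform(0.2, 2.0))
            r = tost_equivalence(a, b, margin=margin)
            p_sm, _, _ = ttost_ind(a, b, -margin, margin, usevar="unequal")
            assert abs(r.p - p_sm) < 1e-10

    def test_identical_samples_huge_margin(self):
        r = tost_equivalence([1, 2, 3, 4], [1, 2, 3, 4], margin=10.0)
        assert r.p < 1e-3 and r.equivalent

    def test_shift_far_outside_margin_not_equivalent(self):
        r = tost_equivalence([0, 0, 0], [5, 5, 5], margin=1.0)
        assert not r.equivalent and r.degenerate

    def test_degenerate_equal_means(self):
        r = tost_equivalence([2, 2, 2], [2, 2, 2], margin=0.5)
        assert r.equivalent and r.p == 0.0 and r.degenerate

    def test_invalid_margin(self):
        with pytest.raises(ValueError):
            tost_equivalence([1, 2], [1, 2], margin=0.0)


def _sign_flip_oracle(vals, subj, tp):
    """Exhaustive within-subject order-flip permutation distribution."""
    n = np.unique(subj).size
    obs = ats_test(vals, subj, tp).statistic
    stats = []
    for flips in itertools.product([0, 1], repeat=n):
        v = vals.copy()
        for k, f in enumerate(flips):
            if f:
                i0 = np.flatnonzero((subj == k) & (tp == 0))[0]
                i1 = np.flatnonzero((subj == k) & (tp == 1))[0]
                v[i0], v[i1] = v[i1], v[i0]
        stats.append(ats_test(v, subj, tp).statistic)
    return obs, float(np.mean(np.asarray(stats) >= obs - 1e-12))


class TestAts:
    def test_all_equal_gives_p_one(self):
        subj = np.repeat(np.arange(4), 3)
        tp = np.tile(np.arange(3), 4)
        r = ats_test(np.ones(12), subj, tp)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        subj = np.repeat(np.arange(6), 4)
        tp = np.tile(np.arange(4), 6)
        y = rng.normal(size=24)
        assert ats_test(y, subj, tp).p == pytest.approx(
            ats_test(np.exp(y), subj, tp).p)

    @pytest.mark.parametrize("vals", [
        # all post above all pre: perfectly consistent shift
        np.array([1.0, 2, 3, 4, 5, 6, 7, 8]),
        # generic overlapping values
        np.array([0.35, -1.3, 0.9, 0.2, 1.1, -0.2, 1.8, 0.9]),
    ])
    def test_matches_sign_flip_permutation_oracle(self, vals):
        """On 4 subjects x 2 timepoints the approximate p agrees with the
        exhaustive sign-flip oracle within the oracle's resolution (the
        smallest attainable two-orbit p, 2/16)."""
        subj = np.array([0, 1, 2, 3] * 2)
        tp = np.array([0] * 4 + [1] * 4)
        r = ats_test(vals, subj, tp)
        _, p_perm = _sign_flip_oracle(vals, subj, tp)
        assert abs(r.p - p_perm) <= 2 / 16 + 1e-12

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DesignError):
            ats_test([1.0, 2, 3, 4], [0, 0, 1, 1], [0, 1, 0, 1])

    def test_sparse_level_rejected(self):
        subj = np.array([0, 0, 1, 1, 2, 2, 0])
        tp = np.array([0, 1, 0, 1, 0, 1, 2])   # level 2 seen in 1 subject
        with pytest.raises(DesignError, match="< 2 subjects"):
            ats_test(np.arange(7.0), subj, tp)


def _wts_bruteforce(vals, A, B):
    """Independent evaluation of the interaction quadratic form."""
    vals = np.asarray(vals, float)
    ranks = sps.rankdata(vals)
    N = len(vals)
    a_ids = sorted(set(A))
    b_ids = sorted(set(B))
    a, b = len(a_ids), len(b_ids)
    p = np.zeros((a, b))
    var = np.zeros((a, b))
    for i, ai in enumerate(a_ids):
        for j, bj in enumerate(b_ids):
            cell = ranks[(np.asarray(A) == ai) & (np.asarray(B) == bj)]
            p[i, j] = (cell.mean() - 0.5) / N
            var[i, j] = (cell.var(ddof=1) / (N ** 2 * len(cell))
                         if len(cell) > 1 else 0.0)
    Pa = np.eye(a) - 1 / a
    Pb = np.eye(b) - 1 / b
    C = np.kron(Pa, Pb)
    q = C @ p.ravel()
    M = C @ np.diag(var.ravel()) @ C.T
    return float(q @ np.linalg.pinv(M) @ q)


class TestWts:
    def test_additive_mean_ranks_give_zero_statistic(self):
        # cells {1,2},{3,4},{5,6},{7,8}: mean ranks 1.5/3.5/5.5/7.5, additive
        vals = np.arange(1.0, 9.0)
        A = [0, 0, 0, 0, 1, 1, 1, 1]
        B = [0, 0, 1, 1, 0, 0, 1, 1]
        r = wts_rank_interaction(vals, A, B)
        assert r.statistic == pytest.approx(0.0, abs=1e-10)
        assert r.p == pytest.approx(1.0)

    def test_matches_bruteforce_quadratic_form(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            A = np.repeat([0, 1], 8)
            B = np.tile(np.repeat([0, 1], 4), 2)
            vals = rng.normal(size=16) + 0.8 * (A == 1) * (B == 1)
            r = wts_rank_interaction(vals, A, B)
            assert abs(r.statistic - _wts_bruteforce(vals, A, B)) < 1e-8

    def test_df_for_3x2_design(self):
        rng = np.random.default_rng(4)
        A = np.repeat([30, 33, 36], 6)
        B = np.tile([0, 1], 9)
        r = wts_rank_interaction(rng.normal(size=18), A, B)
        assert r.df == 2

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        A = np.repeat([0, 1], 10)
        B = np.tile([0, 1], 10)
        y = rng.normal(size=20)
        r1 = wts_rank_interaction(y, A, B)
        r2 = wts_rank_interaction(np.tanh(y) * 100, A, B)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_empty_cell_named(self):
        A = [0, 0, 1, 1]
        B = [0, 1, 0, 0]
        with pytest.raises(DesignError, match="A=1.*B=1"):
            wts_rank_interaction([1.0, 2, 3, 4], A, B)


class TestMixedModelWald:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(6)
        n_pat, n_tp = 14, 4
        groups = np.repeat(np.arange(n_pat), n_tp)
        x = np.repeat(rng.integers(0, 2, n_pat).astype(float), n_tp)
        y = (2.0 * x + rng.normal(0, 0.3, n_pat)[groups]
             + rng.normal(0, 0.1, n_pat * n_tp))
        r = mixed_model_wald(y, pd.DataFrame({"x": x}), groups)
        assert 1.8 < r.params["x"] < 2.2

    def test_duplicate_covariate_rejected(self):
        rng = np.random.default_rng(7)
        groups = np.repeat(np.arange(5), 2)
        x = rng.normal(size=10)
        with pytest.raises(DesignError, match="singular"):
            mixed_model_wald(rng.normal(size=10),
                             pd.DataFrame({"a": x, "b": x}), groups)

    def test_single_group_rejected(self):
        with pytest.raises(DesignError):
            mixed_model_wald(np.arange(4.0),
                             pd.DataFrame({"x": [0.0, 1, 0, 1]}),
                             np.zeros(4))
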