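"""Ensemble SPA: bootstrap machinery, evaluation-index arithmetic, and the
forward-accumulation selection."""

import numpy as np
import pytest

from nirselect import models
from nirselect.ebspa import (
    bootstrap_indices,
    compute_alpha,
    compute_b,
    compute_purity,
    ebspa_select,
    run_bspa,
)
from nirselect.spa import SPAChain


def _chain(order, h):
    order = np.asarray(order)
    curve = np.linspace(1.0, 0.1, order.size)
    curve[h - 1] = 0.05  # minimum at the declared h
    return SPAChain(k0=int(order[0]), order=order, rmsecv_by_length=curve, h=h)


class TestBootstrap:
    def test_length_and_determinism(self):
        idx = bootstrap_indices(50, seed=3)
        assert idx.size == 50 and idx.min() >= 0 and idx.max() < 50
        np.testing.assert_array_equal(idx, bootstrap_indices(50, seed=3))
        assert not np.array_equal(idx, bootstrap_indices(50, seed=4))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_indices(1, seed=0)


class TestAlpha:
    def test_descending_ordinals_single_chain(self):
        alpha = compute_alpha([_chain([4, 9, 2], h=3)])
        assert alpha == {4: 3.0, 9: 2.0, 2: 1.0}

    def test_weights_summed_across_chains(self):
        chains = [_chain([7, 1, 3, 5, 8], h=5), _chain([2, 6, 7, 9], h=4)]
        alpha = compute_alpha(chains)
        assert alpha[7] == 5.0 + 2.0  # position 1 (h=5) plus position 3 (h=4)

    def test_absent_variable_not_in_table(self):
        alpha = compute_alpha([_chain([4, 9, 2], h=2)])
        assert 2 not in alpha  # beyond the retained prefix

    def test_capital_h_scheme(self):
        alpha = compute_alpha([_chain([4, 9], h=2)], scheme="H", H=10)
        assert alpha == {4: 10.0, 9: 9.0}


class TestPurity:
    def test_two_point_closed_form(self):
        p = compute_purity(np.array([[1.0], [3.0]]))
        assert p[0] == pytest.approx(np.sqrt(2.0) / 2.0, abs=1e-4)

    def test_constant_column_zero(self):
        assert compute_purity(np.array([[2.0], [2.0], [2.0]]))[0] == 0.0

    def test_near_zero_mean_guarded(self):
        col = np.array([[1e-12], [-1e-12], [3e-12]])
        assert np.isfinite(compute_purity(col)[0])


class TestB:
    def test_slope_recovered_for_single_variable(self, rng):
        x = rng.normal(size=25)
        X = x[:, None]
        b = compute_b(X, 2.0 * x, np.array([0]), folds=5)
        assert b[0] == pytest.approx(2.0, abs=1e-8)

    def test_column_scaling_inverts_coefficient(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, 0.5, -1.0, 2.0])
        b1 = compute_b(X, y, np.arange(4), folds=5)
        X2 = X.copy()
        X2[:, 2] *= 4.0
        b2 = compute_b(X2, y, np.arange(4), folds=5)
        assert b2[2] == pytest.approx(b1[2] / 4.0, rel=1e-6)

    def test_uninformative_variable_has_smaller_coefficient(self, rng):
        x = rng.normal(size=40)
        junk = rng.normal(size=40)
        X = np.column_stack([x, junk])
        b = compute_b(X, 3.0 * x, np.arange(2), folds=5)
        assert b[1] < b[0]


class TestRunBspa:
    def test_degenerate_ensemble_equals_single_run(self, tiny_dataset):
        ds = tiny_dataset
        chains, union = run_bspa(ds.X, ds.y, T=1, H=5, folds=5, seed=9)
        assert len(chains) == 1
        np.testing.assert_array_equal(union, np.sort(np.unique(chains[0].selected)))

    def test_union_bounded_by_total_selections(self, tiny_dataset):
        ds = tiny_dataset
        T, H = 4, 5
        chains, union = run_bspa(ds.X, ds.y, T=T, H=H, folds=5, seed=1)
        assert union.size <= sum(c.h for c in chains) <= T * H

    def test_union_monotone_in_T(self, tiny_dataset):
        """Same master seed: the union at T is a subset of the union at T+1."""
        ds = tiny_dataset
        _, u3 = run_bspa(ds.X, ds.y, T=3, H=5, folds=5, seed=5)
        _, u4 = run_bspa(ds.X, ds.y, T=4, H=5, folds=5, seed=5)
        assert set(u3) <= set(u4)


class TestEbspaSelect:
    def test_reproducible_from_seed(self, tiny_dataset):
        ds = tiny_dataset
        a = ebspa_select(ds.X, ds.y, T=3, H=5, folds=5, seed=2)
        b = ebspa_select(ds.X, ds.y, T=3, H=5, folds=5, seed=2)
        np.testing.assert_array_equal(a.final_selected, b.final_selected)
        np.testing.assert_allclose(a.accumulation_rmsecv, b.accumulation_rmsecv)
        np.testing.assert_allclose(a.ei.w, b.ei.w)

    def test_final_set_is_prefix_at_curve_minimum(self, tiny_dataset):
        ds = tiny_dataset
        res = ebspa_select(ds.X, ds.y, T=3, H=5, folds=5, seed=2)
        k = res.n_selected
        assert res.accumulation_rmsecv[k - 1] == res.accumulation_rmsecv.min()
        np.testing.assert_array_equal(res.final_selected, res.sorted_order[:k])
        assert res.n_selected <= res.union.size <= 3 * 5

    def test_single_variable_union(self, rng):
        """With H=1 every bootstrap run keeps one channel; if they agree the
        union is a singleton and the final set is that variable."""
        x = rng.normal(size=30)
        X = np.column_stack([x, rng.normal(0, 0.01, size=30)])
        y = 2.0 * x
        res = ebspa_select(X, y, T=3, H=1, folds=5, seed=0)
        np.testing.assert_array_equal(res.union, [0])
        np.testing.assert_array_equal(res.final_selected, [0])

    def test_sort_is_by_w_descending(self, tiny_dataset):
        ds = tiny_dataset
        res = ebspa_select(ds.X, ds.y, T=3, H=5, folds=5, seed=2)
        w_of = dict(zip(res.ei.variables.tolist(), res.ei.w))
        ws = np.array([w_of[int(v)] for v in res.sorted_order])
        assert np.all(np.diff(ws) <= 1e-12)
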