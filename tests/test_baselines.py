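"""Baseline selectors: interval bookkeeping, interval PLS, UVE family, CARS."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

from nirselect.baselines import (
    bipls,
    cars,
    fipls,
    mc_uve,
    mcuve_stability,
    partition_intervals,
    uve,
    uve_stability,
)


class TestPartition:
    @pytest.mark.parametrize(
        "M,k,expected_sizes",
        [
            (4001, 30, [133] * 19 + [134] * 11),
            (10, 2, [5, 5]),
            (10, 3, [3, 3, 4]),
        ],
    )
    def test_sizes(self, M, k, expected_sizes):
        part = partition_intervals(M, k)
        sizes = [b - a for a, b in part.boundaries]
        assert sizes == expected_sizes

    def test_too_many_intervals_rejected(self):
        with pytest.raises(ValueError):
            partition_intervals(5, 6)

    @given(st.integers(1, 200), st.integers(1, 50))
    def test_contiguous_disjoint_exhaustive(self, M, k):
        if k > M:
            M, k = k, M
        part = partition_intervals(M, k)
        flat = np.concatenate([part.indices(i) for i in range(k)])
        np.testing.assert_array_equal(flat, np.arange(M))
        sizes = {b - a for a, b in part.boundaries}
        assert max(sizes) - min(sizes) <= 1


def _interval_data(rng, n=30, m=20, k=4, informative_interval=2, noise=0.0):
    X = rng.normal(size=(n, m))
    part = partition_intervals(m, k)
    cols = part.indices(informative_interval)
    y = X[:, cols[0]] + 0.5 * X[:, cols[1]] + noise * rng.normal(size=n)
    return X, y, part


class TestIntervalPLS:
    def test_fipls_finds_single_informative_interval(self, rng):
        X, y, part = _interval_data(rng)
        selected = fipls(X, y, k=4, folds=5)
        np.testing.assert_array_equal(selected, part.indices(2))

    def test_fipls_trace_non_increasing(self, rng):
        X = rng.normal(size=(30, 20))
        y = X @ rng.normal(size=20) + 0.2 * rng.normal(size=30)
        _, trace = fipls(X, y, k=4, folds=5, return_trace=True)
        assert np.all(np.diff(trace) <= 0)

    def test_bipls_keeps_everything_when_all_informative(self, rng):
        """Every interval carries unique signal: no removal helps."""
        X = rng.normal(size=(40, 12))
        y = X @ np.ones(12)  # all channels needed, noise-free
        selected = bipls(X, y, k=3, folds=5)
        np.testing.assert_array_equal(selected, np.arange(12))


class TestUVE:
    def test_informative_channel_always_retained(self, rng):
        x = rng.normal(size=25)
        X = np.column_stack([x, rng.normal(0, 1, size=(25, 19))])
        retained = uve(X, 2.0 * x + 0.01 * rng.normal(size=25), folds=5)
        assert 0 in retained

    def test_pure_noise_response_retains_almost_nothing(self):
        """With y unrelated to X, real variables behave like the noise block."""
        fractions = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 60))
            y = rng.normal(size=24)
            fractions.append(uve(X, y, folds=5, seed=seed).size / 60)
        assert np.mean(fractions) < 0.05

    def test_raising_threshold_never_retains_more(self, rng):
        X = rng.normal(size=(20, 30))
        y = X[:, 4] + 0.1 * rng.normal(size=20)
        low = uve(X, y, threshold=0.5, folds=5, seed=0)
        high = uve(X, y, threshold=1.0, folds=5, seed=0)
        assert set(high) <= set(low)

    def test_noise_block_flagged(self, rng):
        X = rng.normal(size=(15, 10))
        table = uve_stability(X, X[:, 0], folds=5)
        assert table.is_noise.sum() == 10 and table.stability.size == 20


class TestMCUVE:
    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 25))
        y = X[:, 3] + 0.05 * rng.normal(size=30)
        a = mc_uve(X, y, runs=8, eval_step=5, folds=5, seed=11)
        b = mc_uve(X, y, runs=8, eval_step=5, folds=5, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_stability_ranks_agree_with_uve(self, rng):
        """Both stability tables rank informative channels the same way on a
        strongly structured instance."""
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        X = np.column_stack(
            [x1, x2, x1 + x2] + [rng.normal(0, 1, 30) for _ in range(12)]
        )
        y = 2 * x1 + x2 + 0.05 * rng.normal(size=30)
        c_uve = np.abs(uve_stability(X, y, folds=5, seed=0).stability[:15])
        c_mc = np.abs(mcuve_stability(X, y, runs=40, folds=5, seed=0).stability)
        rho = spearmanr(c_uve, c_mc).statistic
        assert rho > 0.8

    def test_fine_grid_minimum_bounds_coarse(self, rng):
        """Evaluating every q can only match or beat the step-10 sweep."""
        X = rng.normal(size=(25, 30))
        y = X[:, 5] - X[:, 17] + 0.1 * rng.normal(size=25)
        coarse = mc_uve(X, y, runs=8, eval_step=10, folds=5, seed=3)
        fine = mc_uve(X, y, runs=8, eval_step=1, folds=5, seed=3)
        # same ranking => the fine sweep's chosen error is <= the coarse one's
        from nirselect.models import select_pls_lv

        err = lambda cols: select_pls_lv(X[:, cols], y, 15, 5, 3).best_rmsecv
        assert err(fine) <= err(coarse) + 1e-12


class TestCARS:
    def test_schedule_endpoints(self):
        """The retention schedule keeps everything at run 1, two at the end."""
        m, runs = 50, 20
        k = np.log(m / 2.0) / (runs - 1)
        a = np.exp(k)
        ratios = a * np.exp(-k * np.arange(1, runs + 1))
        assert ratios[0] == pytest.approx(1.0)
        assert ratios[-1] * m == pytest.approx(2.0)
        assert np.all(np.diff(ratios) < 0)

    def test_recovers_informative_channels(self):
        """Noise-free 3-channel signal: the winning subset keeps all three in
        most seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(30, 40))
            y = X[:, 5] + 0.7 * X[:, 20] - X[:, 33]
            selected = cars(X, y, runs=25, folds=5, seed=seed)
            hits += {5, 20, 33} <= set(selected)
        assert hits >= 8

    def test_deterministic_and_subset(self, rng):
        X = rng.normal(size=(25, 30))
        y = X[:, 2] + 0.05 * rng.normal(size=25)
        a = cars(X, y, runs=15, folds=5, seed=4)
        b = cars(X, y, runs=15, folds=5, seed=4)
        np.testing.assert_array_equal(a, b)
        assert np.all((a >= 0) & (a < 30)) and np.unique(a).size == a.size
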