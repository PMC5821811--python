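"""Truncated discrete power-law MLE, KS goodness of fit, interval scanning."""

import numpy as np
import pytest
from scipy import special

from avalanches import (
    TruncatedDiscretePowerLaw,
    fit_alternatives,
    ks_p_analytic,
    ks_p_surrogate,
    mle_fit,
    scan_intervals,
)
from avalanches.errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
    NoPlateauError,
)


def grid_search_mle(data, x_low, x_high, step=1e-4):
    """Independent likelihood maximizer: dense grid over the exponent range."""
    tail = np.asarray(data)
    tail = tail[(tail >= x_low) & (tail <= x_high)]
    gammas = np.arange(1.05, 6.0 + step, step)
    z = special.zeta(gammas[:, None], x_low) - special.zeta(gammas[:, None], x_high + 1)
    ll = -gammas * np.log(tail).sum() - tail.size * np.log(z[:, 0])
    return gammas[np.argmax(ll)]


class TestModel:
    @pytest.mark.parametrize("exponent,lo,hi", [(1.5, 1, 100), (2.7, 3, 5000), (1.05, 2, 17)])
    def test_pmf_normalizes(self, exponent, lo, hi):
        model = TruncatedDiscretePowerLaw(exponent, lo, hi)
        total = model.pmf(np.arange(lo, hi + 1)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_cdf_limits(self):
        model = TruncatedDiscretePowerLaw(2.0, 2, 50)
        assert model.cdf(1) == 0.0
        assert model.cdf(50) == pytest.approx(1.0, abs=1e-12)
        assert model.cdf(99) == 1.0

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            TruncatedDiscretePowerLaw(0.9, 1, 10)
        with pytest.raises(InvalidParameterError):
            TruncatedDiscretePowerLaw(1.5, 10, 10)


class TestMleFit:
    def test_agrees_with_grid_search_oracle(self, rng):
        for _ in range(20):
            true = rng.uniform(1.2, 3.5)
            lo = int(rng.integers(1, 5))
            hi = lo * int(rng.integers(20, 200))
            model = TruncatedDiscretePowerLaw(true, lo, hi)
            data = model.sample(2000, rng)
            if np.unique(data).size < 2:
                continue
            fit = mle_fit(data, lo, hi)
            assert abs(fit.exponent - grid_search_mle(data, lo, hi)) < 1e-3

    def test_coverage_of_two_sigma_interval(self, rng):
        # ~95% nominal coverage; 33/40 is far below any plausible failure
        true = 1.5
        model = TruncatedDiscretePowerLaw(true, 1, 10_000)
        hits = 0
        for _ in range(40):
            data = model.sample(20_000, rng)
            fit = mle_fit(data, 1, 10_000)
            hits += abs(fit.exponent - true) <= fit.uncertainty_2sigma
        assert hits >= 33

    def test_degenerate_sample_raises_boundary_flag(self):
        fit = mle_fit(np.full(100, 2), 2, 50)
        assert fit.boundary_warning
        assert fit.exponent > 5.9  # pushed to the steep end of the search range

    def test_discards_out_of_interval_observations(self, rng):
        model = TruncatedDiscretePowerLaw(2.0, 5, 500)
        inside = model.sample(3000, rng)
        polluted = np.concatenate([inside, np.full(1000, 1), np.full(50, 10_000)])
        fit = mle_fit(polluted, 5, 500)
        assert fit.n_tail == 3000
        assert abs(fit.exponent - 2.0) < 3 * fit.sigma + 0.05

    def test_insufficient_tail(self):
        with pytest.raises(InsufficientDataError):
            mle_fit(np.arange(1, 20), 1, 100, floor=50)


class TestKsAnalytic:
    def test_zero_distance_gives_one(self):
        assert ks_p_analytic(0.0, 100) == 1.0

    def test_agrees_with_brute_force_series(self):
        # independent oracle: direct 10^4-term summation
        def brute(d, n):
            z = d * np.sqrt(n) + 0.12 * d + 0.11 * d / np.sqrt(n)
            i = np.arange(1, 10_001)
            return float(np.clip(2 * np.sum((-1.0) ** (i - 1) * np.exp(-2 * i**2 * z**2)), 0, 1))

        for d in [0.005, 0.02, 0.05, 0.1, 0.3]:
            for n in [10, 100, 1000, 50_000]:
                assert ks_p_analytic(d, n) == pytest.approx(brute(d, n), abs=1e-6)

    def test_monotone_in_distance_and_sample_size(self):
        # tolerance sits above the series-truncation noise (~1e-10)
        ds = np.linspace(0.01, 0.5, 25)
        ns = [10, 30, 100, 300, 1000, 10_000]
        for n in ns:
            ps = [ks_p_analytic(d, n) for d in ds]
            assert all(a >= b - 1e-9 for a, b in zip(ps, ps[1:]))
        for d in ds:
            ps = [ks_p_analytic(d, n) for n in ns]
            assert all(a >= b - 1e-9 for a, b in zip(ps, ps[1:]))

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            ks_p_analytic(-0.1, 10)


class TestKsSurrogate:
    def test_requires_minimum_surrogates(self, rng):
        model = TruncatedDiscretePowerLaw(1.8, 1, 200)
        fit = mle_fit(model.sample(500, rng), 1, 200)
        with pytest.raises(InvalidParameterError):
            ks_p_surrogate(fit, n_surrogates=50)

    def test_surrogate_p_not_larger_than_analytic_on_average(self, rng):
        # the analytic formula is known to overestimate; allow MC slack
        model = TruncatedDiscretePowerLaw(1.6, 1, 1000)
        p_s, p_a = [], []
        for _ in range(15):
            fit = mle_fit(model.sample(600, rng), 1, 1000)
            p_s.append(ks_p_surrogate(fit, n_surrogates=100, rng=rng))
            p_a.append(fit.p_analytic)
        assert np.mean(p_s) <= np.mean(p_a) + 0.05

    def test_rejects_geometric_tail(self, rng):
        # geometric sample spanning ~2 decades, power-law fit
        data = rng.geometric(0.02, 4000)
        data = data[(data >= 1) & (data <= 300)]
        fit = mle_fit(data, 1, 300)
        assert ks_p_surrogate(fit, n_surrogates=200, rng=rng) < 0.1

    def test_reproducible_under_fixed_seed(self, rng):
        model = TruncatedDiscretePowerLaw(1.5, 1, 500)
        fit = mle_fit(model.sample(800, rng), 1, 500)
        assert ks_p_surrogate(fit, 100, seed=7) == ks_p_surrogate(fit, 100, seed=7)


class TestScanIntervals:
    def test_recovers_exponent_on_pure_sample(self):
        rng = np.random.default_rng(5)
        model = TruncatedDiscretePowerLaw(2.0, 1, 1000)
        data = model.sample(50_000, rng)
        emap = scan_intervals(data, n_surrogates=0)
        sel = emap.selected
        span = np.log10(sel.model.x_high / sel.model.x_low)
        assert span >= 2.0
        assert abs(sel.exponent - 2.0) <= max(sel.uncertainty_2sigma, 0.02)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        data = TruncatedDiscretePowerLaw(1.7, 1, 300).sample(5000, rng)
        a = scan_intervals(data, n_surrogates=0)
        b = scan_intervals(data, n_surrogates=0)
        assert a.selected.to_dict() == b.selected.to_dict()
        assert np.array_equal(a.exponent_grid, b.exponent_grid, equal_nan=True)

    def test_exponential_tail_confines_upper_cutoff(self):
        rng = np.random.default_rng(8)
        body = TruncatedDiscretePowerLaw(1.8, 1, 50).sample(30_000, rng)
        tail = (50 + rng.exponential(8, 3000)).astype(np.int64)
        data = np.concatenate([body, tail])
        emap = scan_intervals(data, n_surrogates=0)
        assert emap.selected.model.x_high <= 100

    def test_plateau_is_flat_across_nested_subintervals(self):
        rng = np.random.default_rng(9)
        data = TruncatedDiscretePowerLaw(1.5, 1, 10_000).sample(100_000, rng)
        emap = scan_intervals(data, n_surrogates=0)
        sel = emap.selected
        lo, hi = sel.model.x_low, sel.model.x_high
        for f_lo, f_hi in [(2, 1.0), (1, 0.5), (3, 0.7)]:
            sub = mle_fit(data, int(lo * f_lo), max(int(lo * f_lo) + 10, int(hi * f_hi)))
            comb = np.hypot(sel.uncertainty_2sigma, sub.uncertainty_2sigma)
            assert abs(sub.exponent - sel.exponent) < max(comb, 0.04)

    def test_no_plateau_error_carries_best_fit(self, rng):
        # strongly curved (geometric) data: no interval passes the gate
        data = rng.geometric(0.05, 5000)
        with pytest.raises(NoPlateauError) as err:
            scan_intervals(data, p_gate=0.9999, n_surrogates=0)
        assert err.value.best_fit is not None

    def test_inadmissible_cells_are_nan_not_zero(self):
        rng = np.random.default_rng(10)
        data = TruncatedDiscretePowerLaw(2.0, 1, 100).sample(2000, rng)
        emap = scan_intervals(data, n_surrogates=0)
        nan_cells = np.isnan(emap.exponent_grid)
        assert nan_cells.any()
        assert not np.any(emap.exponent_grid[~nan_cells] == 0.0)


class TestAlternatives:
    def test_power_law_sample_rejects_thin_tailed_models(self):
        rng = np.random.default_rng(11)
        data = TruncatedDiscretePowerLaw(1.6, 1, 500).sample(3000, rng)
        cmp = fit_alternatives(data, 1, 500, n_surrogates=100, seed=1)
        assert cmp.models["poisson"]["p_surrogate"] < 0.01
        assert cmp.models["geometric"]["p_surrogate"] < 0.01

    def test_yule_sample_prefers_yule_over_power_law(self):
        wins = 0
        n_rep = 8
        for k in range(n_rep):
            rng = np.random.default_rng(100 + k)
            # Yule-Simon(rho=1.2) via its exponential-geometric mixture
            w = rng.exponential(1.0, 2000)
            data = rng.geometric(np.exp(-w / 1.2)).astype(np.int64)
            data = data[data <= 1000]
            cmp = fit_alternatives(data, 1, 1000, n_surrogates=100, seed=k)
            pl = mle_fit(data, 1, 1000)
            p_pl = ks_p_surrogate(pl, n_surrogates=100, seed=k)
            wins += cmp.models["yule"]["p_surrogate"] > p_pl
        assert wins >= n_rep - 2

    def test_single_valued_sample_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_alternatives(np.full(200, 7), 1, 100, n_surrogates=100)
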