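"""Power-law fitting: log-log OLS, discrete MLE, KS distance, k_min scan,
bootstrap goodness of fit."""

import numpy as np
import pytest

from oligodist.errors import (
    DivergentEstimateError,
    InsufficientDataError,
    InvalidParameterError,
)
from oligodist.powerlaw import (
    bootstrap_pvalue,
    ks_statistic,
    loglog_ols_fit,
    mle_gamma,
    sample_discrete_powerlaw,
    select_kmin,
)


class TestLogLogOLS:
    def test_exact_power_law(self):
        fit = loglog_ols_fit({k: k**-2.0 for k in (2, 4, 8)})
        assert fit.exponent == pytest.approx(-2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_model_points_closed_form_slope(self):
        """Slope of log(k/2^k) on log k at k=2,4,6,8, against Sxy/Sxx by hand."""
        pts = {k: k / 2.0**k for k in (2, 4, 6, 8)}
        x = np.log(list(pts))
        y = np.log(list(pts.values()))
        slope_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum(
            (x - x.mean()) ** 2
        )
        fit = loglog_ols_fit(pts)
        assert fit.exponent == pytest.approx(slope_oracle, rel=1e-12)
        assert fit.exponent == pytest.approx(-1.918, abs=5e-4)

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            loglog_ols_fit({2: 0.5, 4: 0.25})
        with pytest.raises(InvalidParameterError):
            loglog_ols_fit({2: 0.5, 4: 0.0, 8: 0.1})


class TestMLEGamma:
    def test_matches_grid_search_oracle(self):
        """MLE equals the brute-force likelihood argmax (step 1e-4)."""
        from scipy.special import zeta

        vals = np.array([8, 9, 10, 12, 16, 24, 40], dtype=float)
        grid = np.arange(1.0001, 6.0001, 1e-4)
        negll = grid * np.log(vals).mean() + np.log(zeta(grid, 8))
        oracle = grid[np.argmin(negll)]
        assert mle_gamma(vals, 8) == pytest.approx(oracle, abs=1e-4)
        assert mle_gamma(vals, 8) == pytest.approx(2.5289, abs=2e-4)

    def test_degenerate_tail_signals(self):
        with pytest.raises(DivergentEstimateError):
            mle_gamma([5, 5, 5, 5], 5)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(777)
        x = sample_discrete_powerlaw(10_000, 2.5, 5, rng)
        assert mle_gamma(x, 5) == pytest.approx(2.5, abs=0.05)

    def test_continuous_approximation_band(self):
        """Discrete MLE is within 0.1 of the Hill-type continuous estimator
        1 + n / sum(ln(x / (k_min - 0.5))) for gamma in [2,3], k_min >= 8."""
        rng = np.random.default_rng(4242)
        for gamma in (2.0, 2.5, 3.0):
            x = sample_discrete_powerlaw(10_000, gamma, 8, rng)
            approx = 1.0 + x.size / np.sum(np.log(x / 7.5))
            assert mle_gamma(x, 8) == pytest.approx(approx, abs=0.1)


class TestKS:
    def test_toy_tail_hand_tabulated(self):
        """D for {8,8,16} at gamma=2, k_min=8 from direct partial zeta sums."""
        ks = np.arange(8, 2_000_000, dtype=float)
        pmf = ks**-2.0
        z = pmf.sum()
        cdf = {8: pmf[0] / z, 16: pmf[: 16 - 8 + 1].sum() / z}
        d_oracle = max(abs(2 / 3 - cdf[8]), abs(1.0 - cdf[16]))
        assert ks_statistic([8, 8, 16], 2.0, 8) == pytest.approx(d_oracle, abs=1e-6)
        assert ks_statistic([8, 8, 16], 2.0, 8) == pytest.approx(0.549306, abs=1e-5)

    def test_bounds(self):
        rng = np.random.default_rng(5)
        x = sample_discrete_powerlaw(500, 2.2, 3, rng)
        d = ks_statistic(x, 2.2, 3)
        assert 0.0 <= d <= 1.0


class TestSelectKmin:
    def test_pure_power_law_selects_small_kmin(self):
        rng = np.random.default_rng(99)
        x = sample_discrete_powerlaw(10_000, 2.5, 1, rng)
        fit = select_kmin(x)
        assert fit.k_min <= np.quantile(x, 0.5)
        assert fit.gamma == pytest.approx(2.5, abs=0.1)

    def test_head_plus_tail_recovery_rate(self):
        """k_min generated at 8 under a Poisson(3) head: selection never dips
        into the head, the mode sits at 8, gamma stays accurate, and most
        runs land within {6..10}. The KS-minimizing scan has a flat distance
        landscape across correct (nested) cutoffs on discrete data, so the
        selected k_min jitters upward in a minority of runs."""
        from oligodist.synthetic import NetworkSimParams, generate_degree_sequence

        n_runs = 50
        selected, gamma_ok = [], 0
        for seed in range(n_runs):
            params = NetworkSimParams(
                n_nodes=10_000, gamma=2.5, k_min=8, head_mean=3.0,
                tail_fraction=0.5, seed=seed,
            )
            degrees = generate_degree_sequence(params)
            fit = select_kmin(degrees[degrees > 0])
            selected.append(fit.k_min)
            gamma_ok += abs(fit.gamma - 2.5) <= 0.1
        assert min(selected) >= 6  # the Poisson head is never mistaken for tail
        assert max(selected, key=selected.count) == 8
        assert sum(6 <= k <= 10 for k in selected) >= 0.75 * n_runs
        assert gamma_ok >= 0.9 * n_runs

    def test_insufficient_data_signal(self):
        with pytest.raises(InsufficientDataError):
            select_kmin([3, 5, 8, 9, 12], min_tail=10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(31)
        x = sample_discrete_powerlaw(2_000, 2.3, 4, rng)
        fit1 = select_kmin(x)
        fit2 = select_kmin(rng.permutation(x))
        assert (fit1.k_min, fit1.gamma, fit1.ks_D) == (
            fit2.k_min, fit2.gamma, fit2.ks_D
        )

    def test_scan_table_attached(self):
        rng = np.random.default_rng(8)
        x = sample_discrete_powerlaw(2_000, 2.5, 5, rng)
        fit = select_kmin(x)
        assert len(fit.scan) >= 2
        assert any(row[0] == fit.k_min for row in fit.scan)
        assert min(row[2] for row in fit.scan) == fit.ks_D


class TestBootstrap:
    def test_invalid_n_boot(self):
        rng = np.random.default_rng(6)
        x = sample_discrete_powerlaw(200, 2.5, 5, rng)
        fit = select_kmin(x)
        with pytest.raises(InvalidParameterError):
            bootstrap_pvalue(x, fit, n_boot=0)

    def test_rejects_truncated_geometric(self):
        """Geometric data with a hard truncation is rejected (p < 0.1); an
        exponential body plus a pile-up cliff is not a power-law tail."""
        rng = np.random.default_rng(2024)
        x = np.minimum(rng.geometric(0.08, size=5_000) + 4, 40)
        fit = select_kmin(x)
        p = bootstrap_pvalue(x, fit, n_boot=200, seed=11)
        assert p < 0.1

    def test_calibration_on_model_data(self):
        """For data drawn from the fitted family, p rarely rejects."""
        non_reject = 0
        n_runs = 10
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            x = sample_discrete_powerlaw(1_000, 2.5, 5, rng)
            fit = select_kmin(x)
            p = bootstrap_pvalue(x, fit, n_boot=100, seed=seed + 1000)
            non_reject += p > 0.1
        assert non_reject >= 0.9 * n_runs
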