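"""Statistical battery: oracles, symmetries, and robustness properties."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

from cawi import stats as cs

# ---------------------------------------------------------------------------
# independent oracles


def rank_then_pearson(x, y):
    """Brute-force Spearman: average ranks computed by pairwise counting."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(v.size)
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            ranks[i] = less + (equal + 1) / 2.0
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def fisher_oracle(r1, n1, r2, n2):
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return z, 2 * scipy.stats.norm.sf(abs(z))


def steiger_oracle(r1c, r2c, r12, n):
    z1, z2 = math.atanh(r1c), math.atanh(r2c)
    rbar = (r1c + r2c) / 2
    f = min(1.0, (1 - r12) / (2 * (1 - rbar**2)))
    h = (1 - f * rbar**2) / (1 - rbar**2)
    return (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - r12) * h))


def huber_loss(beta, X, y, scale, c=1.345):
    r = (y - X @ beta) / scale
    return float(np.sum(np.where(np.abs(r) <= c, r**2 / 2, c * np.abs(r) - c**2 / 2)))


# ---------------------------------------------------------------------------
# Shapiro-Wilk


def test_shapiro_rejects_heavy_tailed_mixture():
    rng = np.random.default_rng(42)
    x = np.where(rng.random(50) < 0.8, rng.normal(0, 1, 50), rng.normal(0, 8, 50))
    res = cs.shapiro_wilk(x)
    assert res.test_name == "shapiro_wilk"
    assert 0 < res.statistic <= 1
    assert res.p_value < 0.05


def test_shapiro_equally_spaced_points_near_max_w():
    res = cs.shapiro_wilk(np.linspace(0, 1, 20))
    ref_w, _ = scipy.stats.shapiro(np.linspace(0, 1, 20))
    assert res.statistic == pytest.approx(ref_w, rel=1e-12)
    assert res.statistic > 0.95


def test_shapiro_degenerate_and_range_errors():
    with pytest.raises(ValueError, match="constant"):
        cs.shapiro_wilk([2.0] * 10)
    with pytest.raises(ValueError, match="3 <= n"):
        cs.shapiro_wilk([1.0, 2.0])


# ---------------------------------------------------------------------------
# variance F-test


def test_f_test_identical_samples():
    x = np.arange(10.0)
    res = cs.variance_f_test(x, x)
    assert res.statistic == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == (9.0, 9.0)


def test_f_test_swap_symmetry():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 30), rng.normal(0, 2, 40)
    a = cs.variance_f_test(x, y)
    b = cs.variance_f_test(y, x)
    assert a.statistic == pytest.approx(1 / b.statistic, rel=1e-12)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-12)


def test_f_test_detects_dispersion_ratio_of_benchmark_size():
    """SD 0.27 vs 0.15 at n = 94 per arm is overwhelmingly significant."""
    rng = np.random.default_rng(123)
    x = rng.normal(0, 0.27, 94)
    y = rng.normal(0, 0.15, 94)
    assert cs.variance_f_test(x, y).p_value < 0.001


def test_f_test_zero_variance_errors():
    with pytest.raises(ValueError, match="zero-variance"):
        cs.variance_f_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_pairs():
    x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
    assert cs.spearman(x, np.exp(x)).rho == pytest.approx(1.0)
    assert cs.spearman(x, -(x**3)).rho == pytest.approx(-1.0)


def test_spearman_tie_fixture_matches_oracle():
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0])
    y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 7.0, 6.0, 8.0])
    res = cs.spearman(x, y)
    assert res.rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)
    assert res.n == 8


def test_spearman_constant_vector_errors():
    with pytest.raises(ValueError, match="constant"):
        cs.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Fisher z / Steiger


def test_fisher_equal_correlations_give_zero():
    res = cs.fisher_z_compare(0.5, 94, 0.5, 94)
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_fisher_antisymmetry_and_oracle():
    a = cs.fisher_z_compare(0.78, 94, 0.67, 94)
    b = cs.fisher_z_compare(0.67, 94, 0.78, 94)
    assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
    z, p = fisher_oracle(0.78, 94, 0.67, 94)
    assert a.statistic == pytest.approx(z, abs=1e-12)
    assert a.p_value == pytest.approx(p, abs=1e-12)


def test_fisher_perfect_correlation_errors():
    with pytest.raises(ValueError, match="Fisher z infinite"):
        cs.fisher_z_compare(1.0, 50, 0.5, 50)
    with pytest.raises(ValueError, match="n > 3"):
        cs.fisher_z_compare(0.5, 3, 0.5, 50)


def test_fisher_type_one_error_rate():
    """Rejection rate is about alpha when both samples share one correlation."""
    rng = np.random.default_rng(7)
    n, reps, rho = 50, 10_000, 0.4
    cov = np.array([[1, rho], [rho, 1]])
    L = np.linalg.cholesky(cov)
    rejections = 0
    for _ in range(reps):
        a = rng.standard_normal((n, 2)) @ L.T
        b = rng.standard_normal((n, 2)) @ L.T
        r1 = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
        r2 = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
        if cs.fisher_z_compare(r1, n, r2, n).p_value < 0.05:
            rejections += 1
    assert abs(rejections / reps - 0.05) < 0.012


def test_steiger_equal_correlations_give_zero():
    assert cs.steiger_compare_dependent(0.5, 0.5, 0.3, 94).statistic == 0.0


def test_steiger_dependence_sharpens_the_test():
    low = abs(cs.steiger_compare_dependent(0.6, 0.4, 0.0, 94).statistic)
    high = abs(cs.steiger_compare_dependent(0.6, 0.4, 0.9, 94).statistic)
    assert high > low


def test_steiger_fixture_matches_textbook_oracle():
    res = cs.steiger_compare_dependent(0.6, 0.4, 0.5, 94)
    assert res.statistic == pytest.approx(steiger_oracle(0.6, 0.4, 0.5, 94), abs=1e-12)


def test_steiger_infeasible_triple_errors():
    with pytest.raises(ValueError, match="infeasible"):
        cs.steiger_compare_dependent(0.9, -0.9, 0.9, 94)


# ---------------------------------------------------------------------------
# Huber regression


def test_huber_exact_line_recovered():
    x = np.arange(10.0)
    y = 3.0 + 2.0 * x
    fit = cs.huber_regression(x, y)
    assert fit.params["const"] == pytest.approx(3.0, abs=1e-10)
    assert fit.params["x1"] == pytest.approx(2.0, abs=1e-10)
    assert np.allclose(fit.resid, 0, atol=1e-9)
    assert np.allclose(fit.fitted + fit.resid, y)


def test_huber_large_c_equals_ols():
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = 1.0 + 0.5 * x + rng.normal(scale=0.3, size=40)
    fit = cs.huber_regression(x, y, tuning_c=1e8)
    X = np.column_stack([np.ones(40), x])
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-8)


def test_huber_outlier_fixture_matches_loss_minimizer():
    """IRLS fixed point minimizes the Huber objective at the converged scale."""
    x = np.arange(10.0)
    y = 1.0 + 0.4 * x + np.array([0.05, -0.1, 0.02, 0.08, -0.04, 0.1, -0.06, 0.0, 0.03, 8.0])
    fit = cs.huber_regression(x, y)
    X = np.column_stack([np.ones(10), x])
    res = scipy.optimize.minimize(
        huber_loss,
        fit.params.to_numpy() + 0.05,
        args=(X, y, fit.scale),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10_000},
    )
    assert np.allclose(fit.params.to_numpy(), res.x, atol=1e-4)
    # the gross outlier keeps the largest absolute residual
    assert np.argmax(np.abs(fit.resid)) == 9


def test_huber_downweights_contamination_better_than_ols():
    """With 10% gross outliers the Huber slope error beats the OLS slope error."""
    rng = np.random.default_rng(11)
    huber_err, ols_err = [], []
    for _ in range(30):
        x = rng.normal(size=50)
        y = 1.0 + 2.0 * x + rng.normal(scale=0.5, size=50)
        y[:5] += 25.0
        fit = cs.huber_regression(x, y)
        X = np.column_stack([np.ones(50), x])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        huber_err.append(abs(fit.params["x1"] - 2.0))
        ols_err.append(abs(beta_ols[1] - 2.0))
    assert np.mean(huber_err) < np.mean(ols_err)


def test_huber_unbiased_without_contamination():
    rng = np.random.default_rng(21)
    errs = []
    for _ in range(40):
        x = rng.normal(size=60)
        y = 0.5 + 1.5 * x + rng.normal(scale=0.4, size=60)
        errs.append(cs.huber_regression(x, y).params["x1"] - 1.5)
    assert abs(np.mean(errs)) < 0.03


def test_huber_rank_deficiency_and_nonconvergence():
    x = np.ones(10)
    with pytest.raises(ValueError, match="rank-deficient"):
        cs.huber_regression(np.column_stack([x, x]), np.arange(10.0))
    rng = np.random.default_rng(5)
    xr = rng.normal(size=30)
    yr = xr + rng.normal(size=30) + np.where(rng.random(30) < 0.2, 10.0, 0.0)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        fit = cs.huber_regression(xr, yr, max_iter=1)
    assert not fit.converged


def test_huber_bisquare_option_runs():
    rng = np.random.default_rng(9)
    x = rng.normal(size=40)
    y = 1 + x + rng.normal(scale=0.2, size=40)
    fit = cs.huber_regression(x, y, weight_function="bisquare")
    assert fit.params["x1"] == pytest.approx(1.0, abs=0.15)
    with pytest.raises(ValueError, match="weight_function"):
        cs.huber_regression(x, y, weight_function="cauchy")


def test_huber_dataframe_design_names_coefficients():
    rng = np.random.default_rng(13)
    X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
    y = 1 + 2 * X["a"] - 3 * X["b"] + rng.normal(scale=0.1, size=30)
    fit = cs.huber_regression(X, y)
    assert list(fit.params.index) == ["const", "a", "b"]
    assert (fit.bse[["a", "b"]] > 0).all()
    assert np.allclose(fit.fitted + fit.resid, y)


# ---------------------------------------------------------------------------
# residual diagnostics


def test_diagnostics_perfect_fit_all_zero():
    x = np.arange(10.0)
    fit = cs.huber_regression(x, 2 * x + 1)
    diag = cs.residual_diagnostics(fit)
    assert diag.residual_sd == pytest.approx(0.0, abs=1e-9)
    assert diag.spread_slope == pytest.approx(0.0, abs=1e-9)


def test_diagnostics_flag_heteroscedastic_spread():
    rng = np.random.default_rng(17)
    x = np.linspace(1, 10, 200)
    y = x + rng.normal(scale=0.05 * x, size=200)  # spread grows with level
    diag = cs.residual_diagnostics(cs.huber_regression(x, y))
    assert diag.spread_slope > 0
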