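"""Statistical core vs hand oracles: OLS, permutation, ANOVA, adjustments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from facehouse.inference import (
    adjust_bonferroni,
    adjust_fdr_bh,
    bh_family,
    bonferroni_family,
    fit_ols,
    one_way_anova,
    residual_permutation_test,
    tukey_hsd,
)


# ------------------------------------------------------------------ OLS


def test_exact_linear_relation():
    x = np.arange(10, dtype=float)
    fit = fit_ols(2.0 * x, pd.DataFrame({"x": x}))
    assert fit.params["x"] == pytest.approx(2.0, abs=1e-12)
    assert np.max(np.abs(fit.resid)) < 1e-10


def test_intercept_only_recovers_mean(rng):
    y = rng.normal(3.0, 1.0, 25)
    fit = fit_ols(y, pd.DataFrame(index=range(25)))
    assert fit.params["const"] == pytest.approx(y.mean(), abs=1e-12)


def test_six_point_normal_equations_oracle():
    """Hand-computable 6-point dataset vs the normal-equations solution."""
    x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    x2 = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
    y = np.array([1.1, 2.3, 2.8, 4.5, 5.1, 6.2])
    fit = fit_ols(y, pd.DataFrame({"x1": x1, "x2": x2}))
    X = np.column_stack([np.ones(6), x1, x2])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / 3
    se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)
    assert np.allclose(fit.bse.to_numpy(), se, atol=1e-10)
    assert fit.df_resid == 3


def test_listwise_deletion_reduces_df(rng):
    y = rng.normal(size=30)
    y[:4] = np.nan
    fit = fit_ols(y, pd.DataFrame({"x": rng.normal(size=30)}))
    assert fit.nobs == 26
    assert fit.df_resid == 24


def test_rank_deficiency_rejected(rng):
    x = rng.normal(size=20)
    with pytest.raises(ValueError, match="rank"):
        fit_ols(rng.normal(size=20), pd.DataFrame({"a": x, "b": 2 * x}))


# -------------------------------------------------------- permutation test


def _planted(n=60, beta=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = beta * x + 0.5 * z + rng.normal(size=n)
    return y, pd.DataFrame({"x": x, "z": z})


def test_permutation_floor_with_overwhelming_effect():
    """B = 10,000 and zero exceedances: p = 1/10,001 = 0.0001 at 4 d.p."""
    y, X = _planted(beta=10.0)
    _, perm = residual_permutation_test(y, X, "x", n_perm=10_000, seed=1)
    assert perm.p_permuted == pytest.approx(1.0 / 10_001)
    assert round(perm.p_permuted, 4) == 0.0001


def test_orthogonal_variable_p_near_one(rng):
    """When t_orig ~ 0 nearly every permuted |t| exceeds it."""
    n = 80
    x = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
    y = rng.normal(size=n)
    y = y - y.mean()
    y = y - x * (x @ y) / (x @ x)  # force exact orthogonality: t_orig = 0
    _, perm = residual_permutation_test(y, pd.DataFrame({"x": x}), "x", n_perm=500, seed=2)
    assert abs(perm.t_orig) < 1e-10
    assert perm.p_permuted > 0.99


def test_permutation_p_bounds_and_determinism():
    y, X = _planted(beta=0.3, seed=3)
    _, a = residual_permutation_test(y, X, "x", n_perm=999, seed=7)
    _, b = residual_permutation_test(y, X, "x", n_perm=999, seed=7)
    assert a.p_permuted == b.p_permuted
    assert np.array_equal(a.t_perm, b.t_perm)
    assert 1.0 / 1000.0 <= a.p_permuted <= 1.0


def test_permutation_invariant_to_affine_outcome_transform():
    """With an intercept in the model, y -> a*y + b leaves every t (and
    hence the permutation p) unchanged."""
    y, X = _planted(beta=0.4, seed=4)
    _, p1 = residual_permutation_test(y, X, "x", n_perm=300, seed=5)
    _, p2 = residual_permutation_test(3.7 * y + 11.0, X, "x", n_perm=300, seed=5)
    assert p1.p_permuted == p2.p_permuted
    assert np.allclose(p1.t_perm, p2.t_perm, atol=1e-8)


def test_permutation_matches_parametric_under_normality():
    """Gaussian errors: permutation p tracks the two-sided t-test p."""
    diffs = []
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        n = 200
        x = rng.normal(size=n)
        y = 0.12 * x + rng.normal(size=n)
        fit, perm = residual_permutation_test(
            y, pd.DataFrame({"x": x}), "x", n_perm=4000, seed=seed
        )
        p_param = 2 * stats.t.sf(abs(perm.t_orig), fit.df_resid)
        diffs.append(abs(perm.p_permuted - p_param))
    assert max(diffs) < 0.02


def test_power_monotone_in_effect_size():
    """Rejection rate at alpha=.05 rises with the planted effect."""
    rates = []
    for beta in (0.0, 0.25, 0.6):
        rej = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            x = rng.normal(size=n)
            y = beta * x + rng.normal(size=n)
            _, perm = residual_permutation_test(
                y, pd.DataFrame({"x": x}), "x", n_perm=199, seed=seed
            )
            rej += perm.p_permuted < 0.05
        rates.append(rej / 40)
    assert rates[0] < rates[1] < rates[2]


def test_permutation_t_matches_statsmodels_refit():
    """The vectorized permutation refit reproduces a statsmodels OLS refit
    of the same surrogate outcomes, iteration by iteration."""
    import statsmodels.api as sm

    y, X = _planted(n=40, beta=0.5, seed=6)
    _, perm = residual_permutation_test(y, X, "x", n_perm=5, seed=11)
    # rebuild the same surrogates with the same stream
    Xd = sm.add_constant(X)
    null = sm.OLS(y, Xd.drop(columns="x")).fit()
    rng = np.random.default_rng(11)
    idx = rng.permuted(np.tile(np.arange(len(y)), (5, 1)), axis=1)
    for b in range(5):
        y_star = null.fittedvalues.to_numpy() + null.resid.to_numpy()[idx[b]]
        refit = sm.OLS(y_star, Xd).fit()
        assert perm.t_perm[b] == pytest.approx(refit.tvalues["x"], abs=1e-8)


def test_permutation_preconditions():
    y, X = _planted()
    with pytest.raises(ValueError):
        residual_permutation_test(y, X, "missing", n_perm=10)
    with pytest.raises(ValueError):
        residual_permutation_test(y, X, "x", n_perm=0)


# ------------------------------------------------------------------ ANOVA


def test_anova_identical_groups_f_zero(rng):
    g = rng.normal(size=20)
    res = one_way_anova({"a": g, "b": g.copy()})
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_anova_two_groups_equals_t_squared(rng):
    a = rng.normal(0, 1, 15)
    b = rng.normal(0.8, 1, 12)
    res = one_way_anova({"a": a, "b": b})
    t, p = stats.ttest_ind(a, b)
    assert res.F == pytest.approx(t**2, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_anova_three_group_sums_of_squares_oracle():
    groups = {
        "a": np.array([1.0, 2.0, 3.0]),
        "b": np.array([2.0, 3.0, 4.0]),
        "c": np.array([5.0, 6.0, 7.0]),
    }
    res = one_way_anova(groups)
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    f_oracle = (ss_between / 2) / (ss_within / 6)
    assert res.F == pytest.approx(f_oracle, abs=1e-10)
    assert (res.df_between, res.df_within) == (2, 6)


def test_anova_preconditions():
    with pytest.raises(ValueError):
        one_way_anova({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        one_way_anova({"a": [1.0, 2.0], "b": [1.0]})


# ------------------------------------------------------------------ Tukey


def test_tukey_two_groups_equals_t_test(rng):
    a = rng.normal(0, 1, 20)
    b = rng.normal(0.5, 1, 20)
    tk = tukey_hsd({"a": a, "b": b})
    _, p = stats.ttest_ind(a, b)
    assert tk.loc[0, "p_adj"] == pytest.approx(p, abs=1e-3)


def test_tukey_identical_groups_p_one(rng):
    g = rng.normal(size=15)
    tk = tukey_hsd({"a": g, "b": g.copy(), "c": g.copy()})
    assert (tk["p_adj"] > 0.999).all()


def test_tukey_shifted_group_detected(rng):
    base = {f"g{i}": rng.normal(0, 1, 30) for i in range(3)}
    base["far"] = rng.normal(8.0, 1, 30)
    tk = tukey_hsd(base)
    far = tk[(tk.group_a == "far") | (tk.group_b == "far")]
    rest = tk[~((tk.group_a == "far") | (tk.group_b == "far"))]
    assert (far["p_adj"] < 0.001).all()
    assert (rest["p_adj"] > 0.05).all()


# ------------------------------------------------------------ adjustments


@pytest.mark.parametrize("alpha,m,expected", [(0.05, 4, 0.0125), (0.05, 10, 0.005), (0.05, 1, 0.05)])
def test_bonferroni_threshold(alpha, m, expected):
    assert adjust_bonferroni(alpha, m) == pytest.approx(expected)


def test_bonferroni_invalid_m():
    with pytest.raises(ValueError):
        adjust_bonferroni(0.05, 0)


def test_bh_step_up_hand_computation():
    adj = adjust_fdr_bh([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_equal_p():
    assert adjust_fdr_bh([0.2]) == pytest.approx([0.2])
    assert np.allclose(adjust_fdr_bh([0.3, 0.3, 0.3]), 0.3)


def _bh_oracle(p):
    """Independent step-up computation: p_(i) * m / i with cumulative min."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_matches_oracle_exactly(pvals):
    assert np.allclose(adjust_fdr_bh(pvals), _bh_oracle(pvals), atol=1e-12)


def test_bh_invalid_p_rejected():
    with pytest.raises(ValueError):
        adjust_fdr_bh([0.5, 1.2])


def test_family_wrappers():
    fam_b = bonferroni_family([0.01, 0.02, 0.2, 0.4])
    assert fam_b.threshold == pytest.approx(0.0125)
    assert list(fam_b.significant) == [True, False, False, False]
    fam_f = bh_family([0.001, 0.2, 0.9])
    assert fam_f.adjusted is not None and fam_f.significant[0]
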