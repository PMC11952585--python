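"""AFT likelihood machinery: MLE vs closed forms and lifelines, penalized path."""

import numpy as np
import pandas as pd
import pytest

from smahp.aft import (active_set, cv_penalized_aft, fit_aft_mle,
                       fit_penalized_aft, select_lambda_cv, stratified_folds)


def test_uncensored_no_covariates_reduces_to_normal_mle():
    rng = np.random.default_rng(1)
    t = np.exp(rng.normal(2.0, 0.7, size=400))
    fit = fit_aft_mle(np.empty((400, 0)), t, np.ones(400, dtype=int),
                      family="lognormal")
    logt = np.log(t)
    assert fit.intercept == pytest.approx(logt.mean(), abs=1e-5)
    assert fit.scale == pytest.approx(logt.std(ddof=0), rel=1e-4)


def test_optimum_is_local_maximum(aft_toy):
    X, time, delta = aft_toy
    fit = fit_aft_mle(X, time, delta)
    from smahp.aft import _nll_grad

    Xd = np.column_stack([np.ones(len(time)), X])
    params = np.concatenate([[fit.intercept], fit.coef, [np.log(fit.scale)]])
    base, _ = _nll_grad(params, Xd, np.log(time), delta, "lognormal")
    for i in range(len(params)):
        for eps in (0.01, -0.01):
            pert = params.copy()
            pert[i] += eps
            val, _ = _nll_grad(pert, Xd, np.log(time), delta, "lognormal")
            assert val >= base - 1e-9


@pytest.mark.parametrize("family,fitter", [
    ("lognormal", "LogNormalAFTFitter"),
    ("weibull", "WeibullAFTFitter"),
])
def test_mle_matches_lifelines(aft_toy, family, fitter):
    """Coefficients, SEs and log-likelihood agree with the lifelines oracle."""
    lifelines = pytest.importorskip("lifelines")
    X, time, delta = aft_toy
    fit = fit_aft_mle(X, time, delta, family=family)
    df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
    df["T"], df["E"] = time, delta
    oracle = getattr(lifelines, fitter)().fit(df, "T", "E")
    prm = oracle.params_.unstack()
    top = "mu_" if family == "lognormal" else "lambda_"
    assert fit.intercept == pytest.approx(prm.loc[top, "Intercept"], abs=1e-4)
    for i, c in enumerate(["x0", "x1", "x2"]):
        assert fit.coef[i] == pytest.approx(prm.loc[top, c], abs=1e-4)
        assert fit.se[i] == pytest.approx(
            oracle.standard_errors_.loc[(top, c)], rel=1e-3)
    assert fit.loglik == pytest.approx(oracle.log_likelihood_, abs=1e-4)


def test_mle_parameter_recovery_with_censoring():
    """Estimates fall within 3 reported SEs of the truth in most replicates."""
    rng = np.random.default_rng(3)
    beta = np.array([0.5, -0.3])
    n, hits, total = 1000, 0, 0
    for _ in range(30):
        X = rng.normal(size=(n, 2))
        logt = 0.7 + X @ beta + 0.8 * rng.normal(size=n)
        t = np.exp(logt)
        c = rng.exponential(np.exp(2.4), size=n)
        time, delta = np.minimum(t, c), (t <= c).astype(int)
        fit = fit_aft_mle(X, time, delta)
        hits += int(np.all(np.abs(fit.coef - beta) < 3 * fit.se))
        total += 1
    assert hits / total >= 0.9


def test_mle_input_validation(aft_toy):
    X, time, delta = aft_toy
    with pytest.raises(ValueError, match="censored"):
        fit_aft_mle(X, time, np.zeros_like(delta))
    with pytest.raises(ValueError, match="positive"):
        fit_aft_mle(X, time - time.max(), delta)
    with pytest.raises(ValueError, match="rank"):
        fit_aft_mle(np.column_stack([X, X[:, 0]]), time, delta)


def test_penalized_path_endpoints(aft_toy):
    X, time, delta = aft_toy
    path = fit_penalized_aft(X, time, delta, penalty="lasso")
    assert np.all(np.diff(path.lambdas) < 0)
    assert np.abs(path.coefs[0]).max() == 0.0          # lambda_max kills everything
    mle = fit_aft_mle(X, time, delta)
    p0 = fit_penalized_aft(X, time, delta, lambdas=np.array([0.0]),
                           max_iter=50_000)
    assert np.abs(p0.coefs[0] - mle.coef).max() < 1e-3


def test_penalized_rejects_bad_inputs(aft_toy):
    X, time, delta = aft_toy
    with pytest.raises(ValueError, match="censored"):
        fit_penalized_aft(X, time, np.zeros_like(delta))
    with pytest.raises(ValueError, match="non-negative"):
        fit_penalized_aft(X, time, delta, lambdas=np.array([-0.1]))
    with pytest.raises(ValueError, match="constant"):
        fit_penalized_aft(np.column_stack([X, np.ones(len(time))]), time, delta)


def test_lasso_path_selects_true_signals():
    """CV-selected active set contains both true coefficients in most reps."""
    rng = np.random.default_rng(5)
    hits = 0
    n_rep = 10
    for r in range(n_rep):
        n, d = 300, 40
        X = rng.normal(0.4, 0.5, size=(n, d))
        logt = 1.0 + 0.8 * X[:, 3] + 0.8 * X[:, 11] + rng.normal(size=n)
        t = np.exp(logt)
        c = rng.exponential(np.exp(2.2), size=n)
        time, delta = np.minimum(t, c), (t <= c).astype(int)
        path = cv_penalized_aft(X, time, delta, seed=r)
        act = active_set(path, path.lambda_selected)
        hits += int({3, 11} <= set(act))
    assert hits / n_rep >= 0.9


def test_cv_single_lambda_grid_returned(aft_toy):
    X, time, delta = aft_toy
    lam = 0.05
    path = cv_penalized_aft(X, time, delta, lambdas=np.array([lam]))
    assert path.lambda_selected == pytest.approx(lam)


def test_cv_curve_invariant_to_column_order(aft_toy):
    X, time, delta = aft_toy
    grid = np.geomspace(0.5, 0.01, 10)
    a = cv_penalized_aft(X, time, delta, lambdas=grid, seed=0)
    b = cv_penalized_aft(X[:, ::-1], time, delta, lambdas=grid, seed=0)
    assert np.allclose(a.cv_scores, b.cv_scores, atol=1e-6)
    assert np.allclose(a.coefs[-1], b.coefs[-1][::-1], atol=1e-5)


def test_null_design_selects_sparse_models():
    """Pure-noise design: the screening selector keeps (almost) nothing."""
    rng = np.random.default_rng(9)
    sparse = 0
    n_rep = 10
    for r in range(n_rep):
        n, d = 200, 30
        X = rng.normal(size=(n, d))
        t = np.exp(1.0 + rng.normal(size=n))
        c = rng.exponential(np.exp(1.8), size=n)
        time, delta = np.minimum(t, c), (t <= c).astype(int)
        path = cv_penalized_aft(X, time, delta, seed=r, rule="ebic")
        sparse += int(len(active_set(path, path.lambda_selected)) <= 3)
    assert sparse / n_rep >= 0.8


def test_active_set_matches_brute_force(aft_toy):
    X, time, delta = aft_toy
    path = fit_penalized_aft(X, time, delta)
    for i, lam in enumerate(path.lambdas[::20]):
        expected = sorted(
            np.flatnonzero(np.abs(path.coefs[::20][i] * path.feature_sds) > 1e-8).tolist())
        assert active_set(path, lam) == expected


def test_weibull_family_recovers_truth():
    rng = np.random.default_rng(13)
    n = 2000
    X = rng.normal(size=(n, 2))
    # minimum-extreme-value error => Weibull times
    eps = np.log(rng.exponential(size=n))
    logt = 0.5 + 0.6 * X[:, 0] - 0.4 * X[:, 1] + 0.5 * eps
    fit = fit_aft_mle(X, np.exp(logt), np.ones(n, dtype=int), family="weibull")
    assert np.all(np.abs(fit.coef - [0.6, -0.4]) < 3 * fit.se)
    assert fit.scale == pytest.approx(0.5, abs=0.05)


def test_stratified_folds_balance_events():
    delta = np.array([1] * 30 + [0] * 10)
    assign = stratified_folds(delta, 5, seed=0)
    for f in range(5):
        assert delta[assign == f].sum() == 6       # events spread evenly


def test_select_lambda_cv_requires_three_folds():
    with pytest.raises(ValueError):
        select_lambda_cv(lambda idx: None, lambda p, i: None, 10, folds=2)
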