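"""MCP/lasso/enet coordinate descent: closed forms, oracles, invariances."""

import numpy as np
import pytest
from scipy import optimize

from smahp.penalized_linear import (fit_penalized_linear, mcp_univariate,
                                    screen_all_mediators)


@pytest.mark.parametrize("z,lam,gamma,expected", [
    (0.3, 0.5, 3.0, 0.0),                  # below threshold
    (1.0, 0.5, 3.0, 0.75),                 # (1.0-0.5)/(1-1/3)
    (2.0, 0.5, 3.0, 2.0),                  # beyond gamma*lambda: unpenalized
    (-1.0, 0.5, 3.0, -0.75),
    (0.8, 0.0, 3.0, 0.8),                  # no penalty
])
def test_mcp_univariate_closed_form(z, lam, gamma, expected):
    assert mcp_univariate(z, lam, gamma) == pytest.approx(expected)


def test_mcp_univariate_grid_piecewise():
    """Firm threshold on a grid: 0 / linear shrinkage / identity regions."""
    lam, gamma = 0.4, 2.5
    for z in np.linspace(-3, 3, 61):
        got = mcp_univariate(z, lam, gamma)
        if abs(z) <= lam:
            assert got == 0.0
        elif abs(z) <= gamma * lam:
            assert got == pytest.approx(np.sign(z) * (abs(z) - lam) / (1 - 1 / gamma))
        else:
            assert got == pytest.approx(z)


def test_mcp_gamma_must_exceed_one():
    with pytest.raises(ValueError):
        mcp_univariate(1.0, 0.5, 1.0)


def _orthonormal_design(rng, n, p):
    """Centered design whose standardized Gram is the identity."""
    A = rng.normal(size=(n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q * np.sqrt(n)          # unit-variance, exactly orthogonal columns


def test_orthonormal_design_matches_univariate_rule():
    rng = np.random.default_rng(0)
    n, p = 200, 6
    X = _orthonormal_design(rng, n, p)
    beta = np.array([1.2, 0.0, -0.6, 0.25, 0.0, 2.0])
    y = X @ beta + 0.3 * rng.normal(size=n)
    lam, gamma = 0.35, 3.0
    fit = fit_penalized_linear(X, y, penalty="mcp", lambdas=np.array([lam]),
                               gamma=gamma)
    z = X.T @ (y - y.mean()) / n
    sd = X.std(axis=0)
    expected = np.array([mcp_univariate(zj, lam, gamma) for zj in z])
    assert np.allclose(fit.coef * sd, expected, atol=1e-6)


def test_mcp_large_gamma_approaches_lasso():
    rng = np.random.default_rng(1)
    n, p = 150, 10
    X = rng.normal(size=(n, p))
    y = X[:, 0] - 0.5 * X[:, 4] + 0.5 * rng.normal(size=n)
    lam = np.array([0.2])
    mcp = fit_penalized_linear(X, y, penalty="mcp", lambdas=lam, gamma=1e6)
    lasso = fit_penalized_linear(X, y, penalty="lasso", lambdas=lam)
    assert np.abs(mcp.coef - lasso.coef).max() < 1e-4


def test_lambda_max_zeroes_everything():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(100, 8))
    y = X[:, 2] + rng.normal(size=100)
    lam_max = np.abs(((X - X.mean(0)) / X.std(0)).T @ (y - y.mean())).max() / 100
    fit = fit_penalized_linear(X, y, penalty="mcp",
                               lambdas=np.array([2 * lam_max]))
    assert fit.active == [] and np.abs(fit.coef).max() == 0.0


def test_lasso_matches_bound_constrained_qp():
    """5x3 toy problem against an independent split-variable QP solution."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 3))
    y = rng.normal(size=12)
    lam = 0.15
    fit = fit_penalized_linear(X, y, penalty="lasso", lambdas=np.array([lam]))
    Xs = (X - X.mean(0)) / X.std(0)
    yc = y - y.mean()
    n = len(y)

    def objective(v):
        b = v[:3] - v[3:]
        r = yc - Xs @ b
        return 0.5 * (r @ r) / n + lam * v.sum()

    res = optimize.minimize(objective, np.zeros(6),
                            bounds=[(0, None)] * 6, method="L-BFGS-B",
                            options={"ftol": 1e-15, "gtol": 1e-12})
    qp_beta = res.x[:3] - res.x[3:]
    assert np.allclose(fit.coef * X.std(0), qp_beta, atol=1e-6)


def test_coefficients_permute_with_columns():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(120, 7))
    y = 0.9 * X[:, 1] - 0.7 * X[:, 5] + 0.4 * rng.normal(size=120)
    perm = rng.permutation(7)
    a = fit_penalized_linear(X, y, penalty="mcp", seed=0)
    b = fit_penalized_linear(X[:, perm], y, penalty="mcp", seed=0)
    assert np.allclose(a.coef[perm], b.coef, atol=1e-8)


def test_constant_response_warns_and_zeroes():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(50, 4))
    with pytest.warns(UserWarning, match="constant"):
        fit = fit_penalized_linear(X, np.full(50, 3.0), penalty="mcp")
    assert np.abs(fit.coef).max() == 0.0 and fit.intercept == pytest.approx(3.0)


class TestScreenAllMediators:
    def test_keys_cover_every_mediator_once(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 10))
        M = rng.normal(size=(80, 7))
        out = screen_all_mediators(X, M)
        assert sorted(out) == list(range(7))

    def test_column_subset_respected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 10))
        M = rng.normal(size=(80, 7))
        out = screen_all_mediators(X, M, columns=[2, 5])
        assert sorted(out) == [2, 5]

    def test_matches_sequential_fits(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 12))
        M = np.column_stack([0.8 * X[:, 1] + 0.3 * rng.normal(size=100),
                             rng.normal(size=100)])
        batch = screen_all_mediators(X, M, seed=3)
        for s in range(2):
            solo = fit_penalized_linear(X, M[:, s], penalty="mcp", seed=3)
            assert batch[s] == solo.active

    def test_signal_and_noise_mediators(self):
        """X-driven mediator keeps its parent; pure noise stays mostly empty."""
        rng = np.random.default_rng(8)
        n, p = 400, 30
        hit = noise_empty = 0
        n_rep = 10
        for _ in range(n_rep):
            X = rng.normal(0.4, 0.5, size=(n, p))
            M = np.column_stack([
                0.8 * X[:, 0] + rng.normal(0, 0.3, size=n),
                rng.normal(0, 0.3, size=n),
            ])
            out = screen_all_mediators(X, M, seed=0, rule="ebic")
            hit += int(0 in out[0])
            noise_empty += int(out[1] == [])
        assert hit / n_rep >= 0.95
        assert noise_empty / n_rep >= 0.9
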