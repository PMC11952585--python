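"""Joint-significance testing: Wald p, max-p, BH, final models."""

import numpy as np
import pytest
from scipy import stats

from smahp.inference import (assemble_result, bh_adjust, fit_final_models,
                             ols_fit, pmax_matrix, wald_p, MediationResult)
from smahp.screening import ActiveSets


@pytest.mark.parametrize("est,se,expected", [
    (0.0, 1.0, 1.0),
    (1.96, 1.0, 0.0500),
    (1.0, 0.5, 0.0455),
    (-1.0, 0.5, 0.0455),
])
def test_wald_p_values(est, se, expected):
    assert wald_p(est, se) == pytest.approx(expected, abs=5e-5)


def test_wald_p_rejects_bad_se():
    with pytest.raises(ValueError):
        wald_p(1.0, 0.0)


def test_pmax_matrix_basics():
    p_alpha = np.array([[0.01, np.nan], [0.5, 0.2]])
    p_beta = np.array([0.04, 1.0])
    out = pmax_matrix(p_alpha, p_beta)
    assert out[0, 0] == 0.04
    assert np.isnan(out[0, 1])
    assert out[1, 1] == 1.0                       # p_beta = 1 forces the column
    rng = np.random.default_rng(0)
    pa = rng.uniform(size=(6, 4))
    pb = rng.uniform(size=4)
    out = pmax_matrix(pa, pb)
    assert np.all(out >= pa) and np.all(out >= pb[None, :])


def test_bh_adjust_step_up_arithmetic():
    got = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust(np.array([0.3])) == pytest.approx([0.3])
    assert bh_adjust(np.array([])).size == 0


def test_bh_adjust_matches_brute_force_and_dominates_raw():
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 40))
        got = bh_adjust(p)
        # brute-force step-up: sort, scale, enforce monotonicity from the top
        order = np.argsort(p)
        scaled = p[order] * len(p) / (np.arange(len(p)) + 1)
        ref = np.minimum.accumulate(scaled[::-1])[::-1]
        ref = np.minimum(ref, 1.0)
        assert np.allclose(got[order], ref)
        assert np.all(got >= p - 1e-12)


def test_bh_adjust_with_family_size_override():
    p = np.array([0.001, 0.02, 0.8])
    got = bh_adjust(p, m=10)
    order = np.argsort(p)
    scaled = p[order] * 10 / (np.arange(3) + 1)
    ref = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    assert np.allclose(got[order], ref)
    with pytest.raises(ValueError):
        bh_adjust(p, m=2)


def test_ols_fit_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    X = rng.normal(size=(60, 3))
    y = 1.0 + X @ [0.5, -0.2, 0.0] + rng.normal(size=60)
    coef, se, intercept, resid = ols_fit(X, y)
    ref = sm.OLS(y, sm.add_constant(X)).fit()
    assert np.allclose(coef, ref.params[1:])
    assert np.allclose(se, ref.bse[1:], rtol=1e-8)
    assert intercept == pytest.approx(ref.params[0])
    # normal equations: residuals orthogonal to the design
    assert np.abs(resid @ X).max() / len(y) < 1e-8


def _mediation_setup(seed=0, n=400):
    """One gene driving one mediator driving log-time."""
    rng = np.random.default_rng(seed)
    p, k = 6, 5
    X = rng.normal(0.4, 0.5, size=(n, p))
    M = rng.normal(0, 0.3, size=(n, k))
    M[:, 2] += 0.8 * X[:, 1]
    Z = np.column_stack([rng.normal(size=n), rng.binomial(1, 0.3, n)])
    logt = 1.0 + 4.0 * M[:, 2] + 0.12 * Z.sum(axis=1) + rng.normal(size=n)
    t = np.exp(logt)
    c = rng.exponential(np.quantile(t, 0.9), size=n)
    time, delta = np.minimum(t, c), (t <= c).astype(int)
    sets = ActiveSets(S1=[2], T_set=[], J1={2: [1]}, S2=[2], J2={2: [1]})
    return X, M, Z, time, delta, sets


def test_final_models_recover_strong_pair():
    hits = 0
    for seed in range(10):
        X, M, Z, time, delta, sets = _mediation_setup(seed)
        models = fit_final_models(X, M, Z, time, delta, sets,
                                  rescale_exposures=False)
        beta, i = models.outcome_fit.coef, \
            models.outcome_columns["labels"].index("mediator_2")
        med = models.mediation_fits[2]
        ok_beta = abs(beta[i] - 4.0) < 3 * models.outcome_fit.se[i]
        ok_alpha = abs(med["alpha"][0] - 0.8) < 3 * med["alpha_se"][0]
        hits += int(ok_beta and ok_alpha)
    assert hits >= 9


def test_assemble_result_flags_and_effects():
    X, M, Z, time, delta, sets = _mediation_setup(3)
    models = fit_final_models(X, M, Z, time, delta, sets)
    res = assemble_result(models, sets, q_level=0.05)
    assert len(res.rows) == 1
    row = res.rows.iloc[0]
    assert row["p_max"] == max(row["p_alpha"], row["p_beta"])
    assert row["p_adjusted"] >= row["p_max"]
    assert row["nie"] == pytest.approx(row["alpha_hat"] * row["beta_hat"])
    assert bool(row["significant"]) == (row["p_adjusted"] <= 0.05)
    assert res.global_nie[2] == pytest.approx(row["nie"])
    assert res.discoveries == {(1, 2)}


def test_global_nie_sums_rows():
    X, M, Z, time, delta, _ = _mediation_setup(4)
    sets = ActiveSets(S1=[2], T_set=[0], J1={2: [1, 3]}, S2=[2], J2={2: [1, 3]})
    models = fit_final_models(X, M, Z, time, delta, sets)
    res = assemble_result(models, sets)
    assert res.global_nie[2] == pytest.approx(res.rows["nie"].sum())


def test_empty_screen_yields_empty_result():
    X, M, Z, time, delta, _ = _mediation_setup(5)
    sets = ActiveSets(S1=[2], T_set=[], J1={2: []})
    assert fit_final_models(X, M, Z, time, delta, sets) is None
    res = assemble_result(None, sets)
    assert len(res.rows) == 0 and res.discoveries == set()
    assert res.status == "no candidate mediators"


def test_rank_deficient_final_design_drops_columns():
    X, M, Z, time, delta, sets = _mediation_setup(6)
    M = M.copy()
    M[:, 4] = M[:, 2]                          # duplicate screened mediator
    sets = ActiveSets(S1=[2, 4], T_set=[], J1={2: [1], 4: [1]},
                      S2=[2, 4], J2={2: [1], 4: [1]})
    with pytest.warns(UserWarning, match="rank-deficient"):
        models = fit_final_models(X, M, Z, time, delta, sets)
    kept = models.outcome_columns["mediators"]
    assert len(kept) == 1


def test_null_mediation_rarely_rejected():
    """Max-p under each composite sub-null rejects at most ~nominal rate."""
    rejections = 0
    n_rep = 40
    for seed in range(n_rep):
        rng = np.random.default_rng(1000 + seed)
        n = 300
        X = rng.normal(0.4, 0.5, size=(n, 4))
        M = rng.normal(0, 0.5, size=(n, 3))
        M[:, 0] += 0.8 * X[:, 0]                       # H10: alpha != 0, beta = 0
        Z = np.column_stack([rng.normal(size=n), rng.binomial(1, 0.3, n)])
        logt = 1.0 + rng.normal(size=n)                # outcome independent of M
        time = np.exp(logt)
        delta = np.ones(n, dtype=int)
        sets = ActiveSets(S1=[0, 1], T_set=[], J1={0: [0], 1: [1]},
                          S2=[0, 1], J2={0: [0], 1: [1]})
        models = fit_final_models(X, M, Z, time, delta, sets)
        res = assemble_result(models, sets, q_level=0.05)
        rejections += len(res.discoveries)
    assert rejections / n_rep <= 0.10


try:
    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_bh_adjust_properties_hypothesis(pvals):
        """BH dominates the raw p-values, preserves order, stays in [0, 1]."""
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1 + 1e-12))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
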