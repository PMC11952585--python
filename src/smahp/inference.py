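"""Final models and joint-significance (max-p) mediation testing (Step 3).

The screened mediators enter one joint AFT outcome model together with
the candidate direct genes and the covariates; each screened mediator
gets an OLS mediation model on its screened genes plus covariates.  Each
(gene j, mediator s) pair is tested with the max-p statistic
``Pmax = max(P_alpha_js, P_beta_s)`` (normal Wald p-values), adjusted
across all tested pairs by Benjamini-Hochberg.  The natural indirect
effect of a pair is the coefficient product alpha_hat * beta_hat on the
log-time scale; a positive direct coefficient means longer survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aft import AFTFit, fit_aft_mle

if TYPE_CHECKING:  # pragma: no cover
    from .screening import ActiveSets

__all__ = [
    "MediationResult",
    "FinalModels",
    "ols_fit",
    "wald_p",
    "pmax_matrix",
    "bh_adjust",
    "fit_final_models",
    "assemble_result",
]

_RESULT_COLUMNS = [
    "gene", "mediator", "alpha_hat", "alpha_se", "beta_hat", "beta_se",
    "p_alpha", "p_beta", "p_max", "p_adjusted", "nie", "significant",
]


def ols_fit(X: np.ndarray, y: np.ndarray):
    """Least squares with an intercept: (coef, se, intercept, residuals).

    Classic OLS covariance ``sigma^2 (X'X)^{-1}`` with the usual n - d - 1
    denominator.  A thin vectorized helper (validated against the
    statsmodels OLS in the test suite); ``se`` covers the non-intercept
    coefficients only.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    Xd = np.column_stack([np.ones(n), X])
    coef_all, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef_all
    dof = n - d - 1
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(Xd.T @ Xd)
    se_all = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    return coef_all[1:], se_all[1:], float(coef_all[0]), resid


def wald_p(est: float, se: float) -> float:
    """Two-sided normal Wald p-value 2(1 - Phi(|est| / se))."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(est) / se))


def pmax_matrix(p_alpha: np.ndarray, p_beta: np.ndarray) -> np.ndarray:
    """Elementwise max of the gene x mediator alpha p-values and the per-
    mediator beta p-values; NaN entries (pairs absent after screening)
    stay NaN."""
    p_alpha = np.asarray(p_alpha, dtype=float)
    p_beta = np.asarray(p_beta, dtype=float)
    if p_alpha.shape[1] != len(p_beta):
        raise ValueError("dimension mismatch between p_alpha columns and p_beta")
    out = np.maximum(p_alpha, p_beta[None, :])
    out[np.isnan(p_alpha)] = np.nan
    return out


def bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order).

    ``m`` overrides the family size: hypotheses of the family that carry no
    computable p-value (pairs dropped by screening within the tested
    gene x mediator matrix) are counted in the correction but can never be
    rejected.  Default ``m = len(p)`` is the standard procedure.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if m is None or m == len(p):
        return multipletests(p, method="fdr_bh")[1]
    if m < len(p):
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / (np.arange(len(p)) + 1.0)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class FinalModels:
    """The joint outcome fit and the per-mediator mediation fits of Step 3."""

    outcome_fit: AFTFit
    outcome_columns: dict                        # {"genes": [...], "n_covariates": q, "mediators": [...]}
    mediation_fits: dict[int, dict]              # s -> {"genes", "alpha", "alpha_se"}


@dataclass
class MediationResult:
    """Tested pairs with effects, max-p and BH-adjusted p-values."""

    rows: pd.DataFrame
    nde: pd.DataFrame
    global_nie: dict[int, float]
    q_level: float = 0.05
    n_dropped: int = 0
    status: str = "ok"
    sets: "ActiveSets | None" = field(default=None, repr=False)

    @classmethod
    def empty(cls, q_level: float = 0.05, status: str = "no candidate mediators",
              sets=None) -> "MediationResult":
        return cls(rows=pd.DataFrame(columns=_RESULT_COLUMNS),
                   nde=pd.DataFrame(columns=["gene", "estimate", "se", "p"]),
                   global_nie={}, q_level=q_level, status=status, sets=sets)

    @property
    def discoveries(self) -> set[tuple[int, int]]:
        if len(self.rows) == 0:
            return set()
        sig = self.rows[self.rows["significant"].astype(bool)]
        return {(int(g), int(s)) for g, s in zip(sig["gene"], sig["mediator"])}


def _drop_rank_deficient(cols: np.ndarray, labels: list[str]):
    """Greedily drop columns until full rank; returns (kept indices, dropped labels)."""
    keep = list(range(cols.shape[1]))
    dropped = []
    while keep:
        sub = cols[:, keep]
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(sub)), sub]))
        if rank == len(keep) + 1:
            break
        # drop the last linearly dependent column found by pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(np.column_stack([np.ones(len(sub)), sub]),
                       mode="economic", pivoting=True)
        bad = [i - 1 for i in piv[rank:] if i > 0]
        j = keep[max(bad)] if bad else keep[-1]
        dropped.append(labels[j])
        keep.remove(j)
    if dropped:
        warnings.warn(f"rank-deficient final design; dropped columns {dropped}")
    return keep, dropped


def fit_final_models(X: np.ndarray, M: np.ndarray, Z: np.ndarray,
                     time: np.ndarray, delta: np.ndarray, sets: "ActiveSets",
                     family: str = "lognormal", rescale_exposures: bool = True
                     ) -> FinalModels | None:
    """Fit the joint AFT outcome model and the per-mediator OLS models.

    Exposures are standardized to unit variance by default, so direct and
    indirect effects are per-standard-deviation of the exposure.  Returns
    ``None`` when no mediators survived screening.
    """
    if not sets.S2:
        return None
    X = np.asarray(X, dtype=float)
    if rescale_exposures:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    M = np.asarray(M, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(time):
        Z = Z.T
    q = Z.shape[1]
    genes = list(sets.T_set)
    meds = list(sets.S2)
    n = len(time)
    if len(genes) + len(meds) + q + 2 >= n:
        raise ValueError("final outcome model has more parameters than samples allow")

    feats = np.column_stack([X[:, genes], Z, M[:, meds]]) if genes \
        else np.column_stack([Z, M[:, meds]])
    labels = ([f"gene_{j}" for j in genes] + [f"z_{i}" for i in range(q)]
              + [f"mediator_{s}" for s in meds])
    keep, dropped = _drop_rank_deficient(feats, labels)
    kept_labels = [labels[i] for i in keep]
    while True:
        try:
            outcome = fit_aft_mle(feats[:, keep], time, delta, family=family,
                                  check_rank=False)
            break
        except ValueError:
            if len(keep) <= 1:
                raise
            # near-singular information: drop the most collinear column
            sub = feats[:, keep]
            corr = np.abs(np.corrcoef(sub, rowvar=False))
            np.fill_diagonal(corr, 0.0)
            worst = int(np.argmax(corr.max(axis=0)))
            warnings.warn(f"near-singular final design; dropped {kept_labels[worst]}")
            del keep[worst], kept_labels[worst]
    outcome_cols = {
        "genes": [g for g, lab in zip(genes, labels[:len(genes)]) if lab in kept_labels],
        "labels": kept_labels,
        "mediators": [s for s in meds if f"mediator_{s}" in kept_labels],
    }

    mediation: dict[int, dict] = {}
    for s in meds:
        gj = list(sets.J2.get(s, []))
        design = np.column_stack([X[:, gj], Z]) if gj else Z
        alpha, se, _, _ = ols_fit(design, M[:, s])
        mediation[s] = {"genes": gj, "alpha": alpha[:len(gj)],
                        "alpha_se": se[:len(gj)]}
    return FinalModels(outcome_fit=outcome, outcome_columns=outcome_cols,
                       mediation_fits=mediation)


def assemble_result(models: FinalModels | None, sets: "ActiveSets",
                    q_level: float = 0.05, bh_family: str = "matrix"
                    ) -> MediationResult:
    """Max-p tests, BH adjustment and effect estimates for all screened pairs."""
    if models is None:
        return MediationResult.empty(q_level=q_level, sets=sets)
    fit = models.outcome_fit
    labels = models.outcome_columns["labels"]
    beta_by_med: dict[int, tuple[float, float]] = {}
    for s in models.outcome_columns["mediators"]:
        i = labels.index(f"mediator_{s}")
        beta_by_med[s] = (float(fit.coef[i]), float(fit.se[i]))

    records = []
    for s in sets.S2:
        if s not in beta_by_med or s not in models.mediation_fits:
            continue
        beta_hat, beta_se = beta_by_med[s]
        p_beta = wald_p(beta_hat, beta_se) if beta_se > 0 else 1.0
        med = models.mediation_fits[s]
        for j, a, a_se in zip(med["genes"], med["alpha"], med["alpha_se"]):
            p_alpha = wald_p(a, a_se) if a_se > 0 else 1.0
            records.append({
                "gene": int(j), "mediator": int(s),
                "alpha_hat": float(a), "alpha_se": float(a_se),
                "beta_hat": beta_hat, "beta_se": beta_se,
                "p_alpha": p_alpha, "p_beta": p_beta,
                "p_max": max(p_alpha, p_beta),
                "nie": float(a) * beta_hat,
            })
    if not records:
        return MediationResult.empty(q_level=q_level, sets=sets)
    rows = pd.DataFrame.from_records(records)
    if bh_family == "matrix":
        # full tested matrix: (union of screened genes) x (screened
        # mediators); entries without a mediation coefficient are never
        # rejectable but belong to the tested family.
        u = len({j for s in sets.S2 for j in sets.J2.get(s, [])})
        m_family = max(u * len(sets.S2), len(rows))
    elif bh_family == "pairs":
        m_family = len(rows)
    else:
        raise ValueError("bh_family must be 'matrix' or 'pairs'")
    rows["p_adjusted"] = bh_adjust(rows["p_max"].to_numpy(), m=m_family)
    rows["significant"] = rows["p_adjusted"] <= q_level
    rows = rows[_RESULT_COLUMNS]

    nde_records = []
    for g in models.outcome_columns["genes"]:
        i = labels.index(f"gene_{g}")
        est, se = float(fit.coef[i]), float(fit.se[i])
        nde_records.append({"gene": int(g), "estimate": est, "se": se,
                            "p": wald_p(est, se) if se > 0 else 1.0})
    nde = pd.DataFrame.from_records(nde_records) if nde_records \
        else pd.DataFrame(columns=["gene", "estimate", "se", "p"])
    global_nie = {int(s): float(rows.loc[rows["mediator"] == s, "nie"].sum())
                  for s in rows["mediator"].unique()}
    return MediationResult(rows=rows, nde=nde, global_nie=global_nie,
                           q_level=q_level, sets=sets)
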