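"""Comparator methods and the power/FDR simulation-study harness.

Two baselines accompany the full pipeline:

* ``sis_sis`` — Step 1 is replaced by univariate marginal screening: each
  mediator and each exposure is ranked by its univariate AFT Wald
  statistic, each (mediator, exposure) mediation association by its
  univariate OLS t-statistic, keeping the top floor(d*n/log n) per model;
  Steps 2 and 3 are then identical to the full pipeline.
* ``naive`` — every (gene, mediator) pair is tested directly from
  marginal models (no penalization, no screening), with BH over all
  p * k pairs.

``run_study`` replicates datasets from the synthetic generator, applies
the selected methods and averages pair-level power and false discovery
proportion, mirroring the structure of a simulation-study table.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .aft import fit_aft_mle
from .inference import (MediationResult, assemble_result, bh_adjust,
                        fit_final_models, ols_fit, wald_p)
from .pipeline import PipelineConfig, run_smahp
from .screening import ActiveSets, select_pairs, sis_threshold, step2_fit
from .simulate import SimulationConfig, TruthSet, calibrate_censoring, generate_dataset

logger = logging.getLogger("smahp")

__all__ = [
    "StudyMetrics",
    "run_sis_sis",
    "run_naive",
    "compute_metrics",
    "run_study",
]


@dataclass
class StudyMetrics:
    """One cell of a simulation-study table (one method in one scenario)."""

    method: str
    p: int
    k: int
    n: int
    censoring: float
    power: float | None
    power_se: float | None
    fdr: float
    fdr_se: float
    n_reps: int
    n_failed: int
    mean_minutes: float
    seed: int

    def __post_init__(self) -> None:
        if self.power is not None and not (0.0 <= self.power <= 1.0):
            raise ValueError("power must lie in [0, 1]")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError("fdr must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Univariate screening utilities
# ---------------------------------------------------------------------------


def _univariate_aft_z(features: np.ndarray, time: np.ndarray, delta: np.ndarray,
                      family: str) -> np.ndarray:
    """|Wald z| of the slope of a univariate AFT fit, per column (0 on failure)."""
    d = features.shape[1]
    z = np.zeros(d)
    for j in range(d):
        col = features[:, [j]]
        if col.std() == 0:
            continue
        try:
            fit = fit_aft_mle(col, time, delta, family=family, check_rank=False)
        except ValueError:
            continue
        if fit.converged and np.isfinite(fit.se[0]) and fit.se[0] > 0:
            z[j] = abs(fit.coef[0]) / fit.se[0]
    return z


def _univariate_ols_t(X: np.ndarray, m: np.ndarray) -> np.ndarray:
    """|t| of the slope of m ~ X_j (with intercept), vectorized over columns."""
    n = len(m)
    xc = X - X.mean(axis=0)
    yc = m - m.mean()
    sxx = (xc ** 2).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    slope = xc.T @ yc / sxx
    ss_res = (yc ** 2).sum() - slope ** 2 * sxx
    sigma2 = np.clip(ss_res, 0.0, None) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(slope) / se
    return np.nan_to_num(t)


def _top(stats: np.ndarray, count: int) -> list[int]:
    """Indices of the ``count`` largest statistics (ties by column order)."""
    order = np.argsort(-stats, kind="stable")
    return sorted(order[: min(count, len(stats))].tolist())


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def run_sis_sis(X, M, Z, time, delta, d: float = 1.0,
                family: str = "lognormal", q_level: float = 0.05
                ) -> MediationResult:
    """Univariate-marginal Step 1, then SIS and joint-significance testing."""
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    n = len(time)
    thr = sis_threshold(n, d)
    S1 = _top(_univariate_aft_z(M, time, delta, family), thr)
    T_set = _top(_univariate_aft_z(X, time, delta, family), thr)
    J1 = {s: _top(_univariate_ols_t(X, M[:, s]), thr) for s in S1}
    sets = ActiveSets(S1=S1, T_set=T_set, J1=J1)
    pairs = step2_fit(X, M, time, delta, sets, family=family)
    sets.S2, sets.J2 = select_pairs(pairs, thr) if pairs else ([], {})
    sets.validate(p=X.shape[1], k=M.shape[1])
    models = fit_final_models(X, M, Z, time, delta, sets, family=family)
    return assemble_result(models, sets, q_level=q_level)


def run_naive(X, M, Z, time, delta, family: str = "lognormal",
              q_level: float = 0.05, max_pairs: int = 2_000_000
              ) -> MediationResult:
    """Marginal max-p tests of every (gene, mediator) pair, BH over p*k.

    Per mediator: AFT of log-time on (M_s, Z); per pair: OLS of M_s on
    (X_j, Z).  The OLS fits are batched per gene (shared design, all
    mediators as right-hand sides).
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(time):
        Z = Z.T
    n, p = X.shape
    k = M.shape[1]
    if p * k > max_pairs:
        raise ValueError(
            f"{p * k} pairs exceed the cap {max_pairs}; subsample features first"
        )

    beta = np.full(k, np.nan)
    beta_se = np.full(k, np.nan)
    p_beta = np.ones(k)
    for s in range(k):
        try:
            fit = fit_aft_mle(np.column_stack([M[:, s], Z]), time, delta,
                              family=family, check_rank=False)
        except ValueError:
            continue
        if fit.converged and np.isfinite(fit.se[0]) and fit.se[0] > 0:
            beta[s], beta_se[s] = fit.coef[0], fit.se[0]
            p_beta[s] = wald_p(beta[s], beta_se[s])

    dof = n - Z.shape[1] - 2
    records = []
    for j in range(p):
        D = np.column_stack([np.ones(n), X[:, j], Z])
        dtd_inv = np.linalg.pinv(D.T @ D)
        B = dtd_inv @ (D.T @ M)                       # (q+2) x k
        resid = M - D @ B
        sigma2 = (resid ** 2).sum(axis=0) / dof
        a = B[1]
        a_se = np.sqrt(np.clip(sigma2 * dtd_inv[1, 1], 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(a) / a_se
        p_a = 2.0 * _norm_sf(z)
        for s in range(k):
            records.append((j, s, a[s], a_se[s],
                            beta[s] if np.isfinite(beta[s]) else 0.0,
                            beta_se[s] if np.isfinite(beta_se[s]) else np.nan,
                            p_a[s], p_beta[s]))
    rows = pd.DataFrame.from_records(
        records, columns=["gene", "mediator", "alpha_hat", "alpha_se",
                          "beta_hat", "beta_se", "p_alpha", "p_beta"])
    rows["p_max"] = rows[["p_alpha", "p_beta"]].max(axis=1)
    rows["p_adjusted"] = bh_adjust(rows["p_max"].to_numpy())
    rows["nie"] = rows["alpha_hat"] * rows["beta_hat"]
    rows["significant"] = rows["p_adjusted"] <= q_level
    rows = rows[["gene", "mediator", "alpha_hat", "alpha_se", "beta_hat",
                 "beta_se", "p_alpha", "p_beta", "p_max", "p_adjusted", "nie",
                 "significant"]]
    global_nie = rows.groupby("mediator")["nie"].sum().to_dict()
    return MediationResult(rows=rows,
                           nde=pd.DataFrame(columns=["gene", "estimate", "se", "p"]),
                           global_nie={int(s): float(v) for s, v in global_nie.items()},
                           q_level=q_level, status="naive")


def _norm_sf(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    return stats.norm.sf(np.nan_to_num(z))


# ---------------------------------------------------------------------------
# Metrics and the replicated study
# ---------------------------------------------------------------------------


def compute_metrics(result: MediationResult, truth: TruthSet
                    ) -> tuple[float | None, float]:
    """Pair-level (power, FDR) of one analysis against the ground truth.

    power = |discoveries intersect true pairs| / |true pairs| (None when the
    truth has no pairs); fdr = false discoveries / max(1, discoveries).
    """
    disc = result.discoveries
    true = truth.true_pairs
    fdr = len(disc - true) / max(1, len(disc))
    power = None if not true else len(disc & true) / len(true)
    return power, fdr


_METHODS = ("smahp", "sis_sis", "naive")


def _run_method(method: str, ds, family: str, q_level: float, d: float,
                rep_seed: int, pipeline_config: PipelineConfig | None
                ) -> MediationResult:
    if method == "smahp":
        cfg = pipeline_config or PipelineConfig()
        cfg = replace(cfg, family=family, q_level=q_level, sis_d=d, seed=rep_seed)
        return run_smahp(ds.X, ds.M, ds.Z, ds.time, ds.delta, cfg)
    if method == "sis_sis":
        return run_sis_sis(ds.X, ds.M, ds.Z, ds.time, ds.delta, d=d,
                           family=family, q_level=q_level)
    if method == "naive":
        return run_naive(ds.X, ds.M, ds.Z, ds.time, ds.delta, family=family,
                         q_level=q_level)
    raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")


def run_study(configs: list[SimulationConfig], methods=("smahp",),
              n_reps: int = 200, seed: int = 0, d: float = 1.0,
              q_level: float = 0.05, family: str = "lognormal",
              pipeline_config: PipelineConfig | None = None) -> pd.DataFrame:
    """Replicate the generator, analyze with each method, average the metrics.

    Replicate r of a config uses generator seed ``seed + r`` (one shared
    dataset per replicate across methods); failures are logged, counted and
    excluded.  Returns one row per (config, method) with Monte-Carlo
    standard errors of the averaged power and FDR.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    cells: list[StudyMetrics] = []
    for config in configs:
        rate = calibrate_censoring(config)
        per_method = {m: {"power": [], "fdr": [], "minutes": [], "failed": 0}
                      for m in methods}
        for r in range(n_reps):
            rep_seed = seed + r
            ds = generate_dataset(replace(config, seed=rep_seed), censor_rate=rate)
            for m in methods:
                t0 = _time.perf_counter()
                try:
                    res = _run_method(m, ds, family, q_level, d, rep_seed,
                                      pipeline_config)
                except Exception as exc:
                    logger.warning("replicate %d, method %s failed: %s", r, m, exc)
                    per_method[m]["failed"] += 1
                    continue
                per_method[m]["minutes"].append((_time.perf_counter() - t0) / 60)
                power, fdr = compute_metrics(res, ds.truth)
                if power is not None:
                    per_method[m]["power"].append(power)
                per_method[m]["fdr"].append(fdr)
        for m in methods:
            acc = per_method[m]
            pw = np.array(acc["power"], dtype=float)
            fd = np.array(acc["fdr"], dtype=float)
            cells.append(StudyMetrics(
                method=m, p=config.p, k=config.k, n=config.n,
                censoring=config.censor_target,
                power=float(pw.mean()) if pw.size else None,
                power_se=float(pw.std(ddof=1) / np.sqrt(pw.size)) if pw.size > 1 else None,
                fdr=float(fd.mean()) if fd.size else 0.0,
                fdr_se=float(fd.std(ddof=1) / np.sqrt(fd.size)) if fd.size > 1 else 0.0,
                n_reps=n_reps, n_failed=acc["failed"],
                mean_minutes=float(np.mean(acc["minutes"])) if acc["minutes"] else float("nan"),
                seed=seed,
            ))
            logger.info("study cell done: %s", cells[-1])
    return pd.DataFrame([asdict(c) for c in cells])
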