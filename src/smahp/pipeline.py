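"""End-to-end SMAHP orchestration, pre-screening and file I/O.

The full procedure on an (X genes, M proteins, Z covariates, survival)
dataset:

1. penalized AFT of log-time on all mediators (-> S1) and on all
   exposures (-> T_set); MCP-penalized regression of each candidate
   mediator on all exposures (-> J1k);
2. sure independence screening of the (gene, mediator) pairs by
   |alpha_hat * beta_hat| at the floor(d * n / log n) threshold
   (-> S2, J2s);
3. joint AFT outcome model plus per-mediator OLS mediation models,
   max-p joint-significance tests with BH FDR adjustment.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aft import cv_penalized_aft, active_set, fit_aft_mle
from .penalized_linear import screen_all_mediators
from .screening import ActiveSets, step2_fit, sis_threshold, select_pairs
from .inference import MediationResult, fit_final_models, assemble_result, wald_p

logger = logging.getLogger("smahp")

__all__ = [
    "PipelineConfig",
    "univariate_prescreen",
    "run_smahp",
    "io_read_tables",
    "io_write_result",
    "plot_pmax",
]


@dataclass
class PipelineConfig:
    """Tuning knobs of the three-step procedure."""

    family: str = "lognormal"            # AFT error family ("lognormal" | "weibull")
    outcome_penalty: str = "lasso"       # Step-1 outcome-model penalty
    mediator_penalty: str = "mcp"        # Step-1 mediator-model penalty
    gamma: float = 3.0                   # MCP concavity
    cv_folds: int = 5
    outcome_cv_rule: str = "ebic"        # lambda rule of the outcome screens ("ebic" | "bic" | "min" | "1se")
    mediator_cv_rule: str = "ebic"       # lambda rule of the mediator screens
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-2
    sis_d: float = 1.0                   # multiplier of the n/log(n) threshold
    q_level: float = 0.05                # BH FDR level
    bh_family: str = "matrix"            # BH correction family ("matrix" | "pairs")
    top_genes: int | None = None         # univariate pre-screen sizes (None = off)
    top_proteins: int | None = None
    rescale_exposures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.q_level < 1.0):
            raise ValueError("q_level must lie in (0, 1)")
        for attr in ("top_genes", "top_proteins"):
            v = getattr(self, attr)
            if v is not None and v < 1:
                raise ValueError(f"{attr} must be positive")


def univariate_prescreen(features: np.ndarray, time: np.ndarray,
                         delta: np.ndarray, top_n: int,
                         family: str = "lognormal") -> list[int]:
    """Columns with the smallest univariate-AFT Wald p-values.

    Each column is fitted alone (with an intercept); non-converging columns
    are assigned p = 1 with a warning.  Ties break by column order.
    """
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    features = np.asarray(features, dtype=float)
    d = features.shape[1]
    pvals = np.ones(d)
    for j in range(d):
        col = features[:, [j]]
        if col.std() == 0:
            warnings.warn(f"column {j}: constant; assigned p=1")
            continue
        try:
            fit = fit_aft_mle(col, time, delta, family=family, check_rank=False)
        except ValueError as exc:
            warnings.warn(f"column {j}: univariate AFT failed ({exc}); assigned p=1")
            continue
        if not fit.converged or not np.isfinite(fit.se[0]) or fit.se[0] <= 0:
            warnings.warn(f"column {j}: univariate AFT did not converge; assigned p=1")
            continue
        pvals[j] = wald_p(fit.coef[0], fit.se[0])
    order = np.argsort(pvals, kind="stable")
    return sorted(order[: min(top_n, d)].tolist())


def _complete_cases(X, M, Z, time, delta):
    ok = (np.isfinite(X).all(axis=1) & np.isfinite(M).all(axis=1)
          & np.isfinite(Z).all(axis=1) & np.isfinite(time) & np.isfinite(delta))
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d incomplete cases (complete-case analysis)", dropped)
    return X[ok], M[ok], Z[ok], time[ok], delta[ok], dropped


def run_smahp(X: np.ndarray, M: np.ndarray, Z: np.ndarray, time: np.ndarray,
              delta: np.ndarray, config: PipelineConfig | None = None
              ) -> MediationResult:
    """Run the full three-step procedure; deterministic given config.seed."""
    config = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(time):
        Z = Z.T
    time = np.asarray(time, dtype=float)
    delta = np.asarray(delta)
    X, M, Z, time, delta, n_dropped = _complete_cases(X, M, Z, time, delta)
    n = len(time)

    gene_idx = np.arange(X.shape[1])
    prot_idx = np.arange(M.shape[1])
    if config.top_genes is not None and config.top_genes < X.shape[1]:
        gene_idx = np.array(univariate_prescreen(X, time, delta,
                                                 config.top_genes, config.family))
        X = X[:, gene_idx]
    if config.top_proteins is not None and config.top_proteins < M.shape[1]:
        prot_idx = np.array(univariate_prescreen(M, time, delta,
                                                 config.top_proteins, config.family))
        M = M[:, prot_idx]

    kw = dict(n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
              gamma=config.gamma)
    # Step 1a: penalized AFT on all mediators -> S1
    path_m = cv_penalized_aft(M, time, delta, family=config.family,
                              penalty=config.outcome_penalty,
                              n_folds=config.cv_folds, seed=config.seed,
                              rule=config.outcome_cv_rule, **kw)
    S1 = active_set(path_m, path_m.lambda_selected)
    # Step 1b: penalized AFT on all exposures -> T_set
    path_x = cv_penalized_aft(X, time, delta, family=config.family,
                              penalty=config.outcome_penalty,
                              n_folds=config.cv_folds, seed=config.seed + 1,
                              rule=config.outcome_cv_rule, **kw)
    T_set = active_set(path_x, path_x.lambda_selected)
    sets = ActiveSets(S1=S1, T_set=T_set)
    if not S1:
        logger.info("no candidate mediators after Step 1")
        result = MediationResult.empty(q_level=config.q_level, sets=sets)
        result.n_dropped = n_dropped
        return _relabel(result, gene_idx, prot_idx)

    # Step 1c: penalized mediator models for the S1 candidates -> J1k
    sets.J1 = screen_all_mediators(X, M, penalty=config.mediator_penalty,
                                   gamma=config.gamma, cv_folds=config.cv_folds,
                                   n_lambda=config.n_lambda,
                                   lambda_min_ratio=config.lambda_min_ratio,
                                   seed=config.seed + 2, columns=S1,
                                   rule=config.mediator_cv_rule)
    if all(len(v) == 0 for v in sets.J1.values()):
        logger.info("no candidate genes for any candidate mediator")
        result = MediationResult.empty(q_level=config.q_level, sets=sets)
        result.n_dropped = n_dropped
        return _relabel(result, gene_idx, prot_idx)

    # Step 2: SIS on |alpha * beta| products
    pairs = step2_fit(X, M, time, delta, sets, family=config.family)
    thr = sis_threshold(n, config.sis_d)
    sets.S2, sets.J2 = select_pairs(pairs, thr) if pairs else ([], {})
    sets.validate(p=X.shape[1], k=M.shape[1])

    # Step 3: final models + joint-significance testing
    models = fit_final_models(X, M, Z, time, delta, sets, family=config.family,
                              rescale_exposures=config.rescale_exposures)
    result = assemble_result(models, sets, q_level=config.q_level,
                             bh_family=config.bh_family)
    result.n_dropped = n_dropped
    return _relabel(result, gene_idx, prot_idx)


def _relabel(result: MediationResult, gene_idx: np.ndarray, prot_idx: np.ndarray
             ) -> MediationResult:
    """Map indices back to the original column space after pre-screening."""
    gmap = {i: int(g) for i, g in enumerate(gene_idx)}
    pmap = {i: int(s) for i, s in enumerate(prot_idx)}
    if len(result.rows):
        result.rows["gene"] = result.rows["gene"].map(gmap)
        result.rows["mediator"] = result.rows["mediator"].map(pmap)
    if len(result.nde):
        result.nde["gene"] = result.nde["gene"].map(gmap)
    result.global_nie = {pmap[s]: v for s, v in result.global_nie.items()}
    if result.sets is not None:
        s = result.sets
        s.S1 = [pmap[i] for i in s.S1]
        s.S2 = [pmap[i] for i in s.S2]
        s.T_set = [gmap[i] for i in s.T_set]
        s.J1 = {pmap[i]: [gmap[j] for j in v] for i, v in s.J1.items()}
        s.J2 = {pmap[i]: [gmap[j] for j in v] for i, v in s.J2.items()}
    return result


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path.name}: duplicate sample IDs {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path.name}: non-numeric cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return numeric


def io_read_tables(x_path, m_path, z_path, survival_path):
    """Read the four delimited inputs and inner-join them on sample ID.

    Returns (X, M, Z, time, delta, sample_ids, feature_names) with rows in
    the joined sample order.
    """
    X = _read_table(x_path)
    M = _read_table(m_path)
    Z = _read_table(z_path)
    surv = pd.read_csv(Path(survival_path),
                       sep="\t" if str(survival_path).endswith((".tsv", ".txt")) else ",")
    required = {"sample_id", "time", "event"}
    if not required <= set(surv.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if surv["sample_id"].duplicated().any():
        raise ValueError("survival table: duplicate sample IDs")
    surv = surv.set_index("sample_id")
    ids = X.index.intersection(M.index).intersection(Z.index).intersection(surv.index)
    ids = sorted(ids)
    if not ids:
        raise ValueError("no common sample IDs across the four tables "
                         f"({Path(x_path).name}, {Path(m_path).name}, "
                         f"{Path(z_path).name}, {Path(survival_path).name})")
    names = {"genes": list(X.columns), "proteins": list(M.columns),
             "covariates": list(Z.columns)}
    return (X.loc[ids].to_numpy(float), M.loc[ids].to_numpy(float),
            Z.loc[ids].to_numpy(float), surv.loc[ids, "time"].to_numpy(float),
            surv.loc[ids, "event"].to_numpy(int), list(ids), names)


def io_write_result(result: MediationResult, outdir: str | Path,
                    config: PipelineConfig | None = None,
                    names: dict | None = None) -> None:
    """Write result_pairs.tsv, nde.tsv, active_sets.json and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = result.rows.copy()
    nde = result.nde.copy()
    if names:
        rows["gene"] = rows["gene"].map(lambda j: names["genes"][j])
        rows["mediator"] = rows["mediator"].map(lambda s: names["proteins"][s])
        if len(nde):
            nde["gene"] = nde["gene"].map(lambda j: names["genes"][j])
    rows.to_csv(outdir / "result_pairs.tsv", sep="\t", index=False)
    nde.to_csv(outdir / "nde.tsv", sep="\t", index=False)
    sets = result.sets.to_jsonable() if result.sets is not None else {}
    (outdir / "active_sets.json").write_text(json.dumps(sets, indent=1))
    manifest = {
        "package": "smahp",
        "version": __version__,
        "status": result.status,
        "q_level": result.q_level,
        "n_dropped_incomplete": result.n_dropped,
        "n_tested_pairs": int(len(result.rows)),
        "n_significant": int(result.rows["significant"].sum()) if len(result.rows) else 0,
        "config": asdict(config) if config is not None else None,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("wrote results to %s", outdir)


def plot_pmax(result: MediationResult, path: str | Path) -> None:
    """Histogram of the max-p values of the tested pairs (diagnostic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if len(result.rows):
        ax.hist(result.rows["p_max"], bins=20, range=(0, 1), color="#4878a8")
    ax.set_xlabel(r"$P_{\max}$")
    ax.set_ylabel("pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
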