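"""Sure independence screening of (gene, mediator) pairs (Step 2).

Step 1 proposes candidate mediators (S1), candidate direct genes (T_set)
and per-mediator candidate genes (J1k) from penalized fits.  Step 2
refits, for each candidate mediator s, an unpenalized AFT of log-time on
(X restricted to T_set, M_s) giving beta_hat_Ms, and an OLS of M_s on its
candidate genes giving alpha_hat; the pairs with the largest indirect
effect magnitudes |alpha_hat * beta_hat| are kept, thresholded at
floor(d * n / log n) pairs (natural log).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .aft import fit_aft_mle
from .inference import ols_fit

__all__ = ["ActiveSets", "PairScore", "step2_fit", "sis_threshold", "select_pairs"]


@dataclass
class ActiveSets:
    """The nested index sets passed between the three steps."""

    S1: list[int] = field(default_factory=list)      # candidate mediators (outcome model)
    T_set: list[int] = field(default_factory=list)   # candidate direct genes
    J1: dict[int, list[int]] = field(default_factory=dict)  # mediator -> candidate genes
    S2: list[int] = field(default_factory=list)      # screened mediators
    J2: dict[int, list[int]] = field(default_factory=dict)  # mediator -> screened genes

    def validate(self, p: int | None = None, k: int | None = None) -> None:
        if not set(self.S2) <= set(self.S1):
            raise ValueError("S2 must be a subset of S1")
        for s in self.S2:
            if not set(self.J2.get(s, [])) <= set(self.J1.get(s, [])):
                raise ValueError(f"J2[{s}] must be a subset of J1[{s}]")
        if k is not None and any(not 0 <= s < k for s in self.S1):
            raise ValueError("mediator index out of bounds")
        if p is not None:
            genes = set(self.T_set) | {j for v in self.J1.values() for j in v}
            if any(not 0 <= j < p for j in genes):
                raise ValueError("gene index out of bounds")

    def to_jsonable(self) -> dict:
        return {
            "S1": list(map(int, self.S1)),
            "T_set": list(map(int, self.T_set)),
            "J1": {str(s): list(map(int, v)) for s, v in self.J1.items()},
            "S2": list(map(int, self.S2)),
            "J2": {str(s): list(map(int, v)) for s, v in self.J2.items()},
        }


@dataclass
class PairScore:
    """One candidate (gene, mediator) pair with its screening statistic."""

    gene: int
    mediator: int
    alpha: float
    beta: float

    @property
    def product(self) -> float:
        return abs(self.alpha * self.beta)


def sis_threshold(n: int, d: float = 1.0) -> int:
    """Number of pairs kept by screening: floor(d * n / ln n), at least 1."""
    if n < 3:
        raise ValueError("need n >= 3")
    if d <= 0:
        raise ValueError("multiplier d must be positive")
    return max(1, int(np.floor(d * n / np.log(n))))


def step2_fit(X: np.ndarray, M: np.ndarray, time: np.ndarray, delta: np.ndarray,
              sets: ActiveSets, family: str = "lognormal") -> list[PairScore]:
    """Refit per-mediator outcome and mediation models on Step-1 candidates.

    Mediators with an empty candidate gene set contribute no pairs; a
    non-converging AFT refit drops that mediator's pairs with a warning.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    t_cols = list(sets.T_set)
    pairs: list[PairScore] = []
    for s in sorted(sets.S1):
        genes = list(sets.J1.get(s, []))
        if not genes:
            continue
        feats = np.column_stack([X[:, t_cols], M[:, [s]]]) if t_cols else M[:, [s]]
        try:
            fit = fit_aft_mle(feats, time, delta, family=family,
                              compute_se=False)
        except ValueError as exc:
            warnings.warn(f"mediator {s}: step-2 AFT refit failed ({exc}); dropped")
            continue
        if not fit.converged:
            warnings.warn(f"mediator {s}: step-2 AFT refit did not converge; dropped")
            continue
        beta_ms = float(fit.coef[-1])
        alpha, *_ = ols_fit(X[:, genes], M[:, s])
        for gi, j in enumerate(genes):
            pairs.append(PairScore(gene=int(j), mediator=int(s),
                                   alpha=float(alpha[gi]), beta=beta_ms))
    return pairs


def select_pairs(pairs: list[PairScore], threshold: int
                 ) -> tuple[list[int], dict[int, list[int]]]:
    """Keep the top ``threshold`` pairs by |alpha * beta| (descending).

    Exact ties are broken by (mediator index, gene index) ascending, so the
    selection does not depend on the input order.  Returns (S2, J2).
    """
    if threshold < 1:
        raise ValueError("threshold must be at least 1")
    ranked = sorted(pairs, key=lambda ps: (-ps.product, ps.mediator, ps.gene))
    kept = ranked[:threshold]
    S2 = sorted({ps.mediator for ps in kept})
    J2: dict[int, list[int]] = {s: [] for s in S2}
    for ps in kept:
        J2[ps.mediator].append(ps.gene)
    for s in J2:
        J2[s] = sorted(J2[s])
    return S2, J2
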