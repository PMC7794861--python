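"""Inverse-variance meta-analysis of log-scale effect estimates.

Fixed-effect pooling combines the one- and two-sample MR arms of each
direction; DerSimonian-Laird random-effects pooling serves the synthesis of
observational study odds ratios, where real between-study heterogeneity is
expected.  Study inputs may be given directly as (beta, se) on the log
scale or as an odds ratio with a 95% CI, from which the SE is reconstructed
as (ln CI_high − ln CI_low) / (2·1.96).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StudyEstimate", "MetaResult", "fixed_effect",
           "dersimonian_laird", "or_table_report", "pool_table"]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class StudyEstimate:
    """One study's effect on the log scale."""

    label: str
    beta: float
    se: float

    def __post_init__(self):
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError("standard error must be positive and finite")

    @classmethod
    def from_odds_ratio(cls, label: str, or_: float, ci_low: float,
                        ci_high: float) -> "StudyEstimate":
        if not (0 < ci_low <= or_ <= ci_high):
            raise ValueError("need 0 < ci_low <= OR <= ci_high")
        return cls(label=label, beta=float(np.log(or_)),
                   se=float((np.log(ci_high) - np.log(ci_low)) / (2 * _Z95)))


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity statistics."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    q: float
    df: int
    q_pvalue: float
    i_squared: float
    tau_squared: float
    model: str


def _pool(betas: np.ndarray, weights: np.ndarray, k: int, q: float, df: int,
          i2: float, tau2: float, model: str) -> MetaResult:
    beta = float(np.sum(weights * betas) / weights.sum())
    se = float(np.sqrt(1.0 / weights.sum()))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MetaResult(beta=beta, se=se, ci_low=beta - _Z95 * se,
                      ci_high=beta + _Z95 * se, pvalue=float(p), k=k,
                      q=q, df=df,
                      q_pvalue=float(stats.chi2.sf(q, df)) if df > 0 else 1.0,
                      i_squared=i2, tau_squared=tau2, model=model)


def _arrays(estimates) -> tuple[np.ndarray, np.ndarray]:
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    return betas, ses


def _q_stat(betas, w) -> float:
    pooled = np.sum(w * betas) / w.sum()
    return float(np.sum(w * (betas - pooled) ** 2))


def fixed_effect(estimates) -> MetaResult:
    """Fixed-effect (inverse-variance) pooling."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate")
    betas, ses = _arrays(estimates)
    w = 1.0 / ses**2
    k = len(estimates)
    q = _q_stat(betas, w) if k > 1 else 0.0
    df = k - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return _pool(betas, w, k, q, df, i2, 0.0, "fixed")


def dersimonian_laird(estimates) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) with fixed-effect weights w, then
    the studies are re-pooled with weights 1/(se² + τ²); with Q ≤ df this
    reduces exactly to the fixed-effect result (τ² truncates to zero).
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates; use fixed_effect for one")
    betas, ses = _arrays(estimates)
    w = 1.0 / ses**2
    k = len(estimates)
    df = k - 1
    q = _q_stat(betas, w)
    c = w.sum() - np.sum(w**2) / w.sum()
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return _pool(betas, w_star, k, q, df, i2, tau2, "random")


def or_table_report(result: MetaResult) -> dict:
    """One tidy reporting row: pooled OR with CI plus heterogeneity."""
    return {
        "or": float(np.exp(result.beta)),
        "or_ci_low": float(np.exp(result.ci_low)),
        "or_ci_high": float(np.exp(result.ci_high)),
        "pvalue": result.pvalue,
        "k": result.k,
        "q": result.q,
        "i_squared": result.i_squared,
        "tau_squared": result.tau_squared,
        "model": result.model,
    }


def pool_table(studies: pd.DataFrame, model: str = "random",
               group_col: str | None = "group") -> pd.DataFrame:
    """Pool a per-study OR table, optionally within groups.

    ``studies`` needs columns label, or, ci_low, ci_high and optionally a
    grouping column (e.g. adult/child × overweight/obese strata).  Returns
    one pooled reporting row per group.
    """
    pooler = {"random": dersimonian_laird, "fixed": fixed_effect}[model]
    if group_col and group_col in studies.columns:
        groups = list(studies.groupby(group_col, sort=True))
    else:
        groups = [("all", studies)]
    rows = []
    for name, part in groups:
        ests = [StudyEstimate.from_odds_ratio(r["label"], r["or"], r["ci_low"],
                                              r["ci_high"])
                for _, r in part.iterrows()]
        pooled = pooler(ests) if len(ests) > 1 or model == "fixed" else \
            fixed_effect(ests)
        rows.append({"group": name, **or_table_report(pooled)})
    return pd.DataFrame(rows)
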