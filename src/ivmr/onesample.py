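"""One-sample Mendelian randomization on individual-level data.

The genetic risk score serves as a single composite instrument.  For a
continuous outcome the estimator is two-stage least squares with the proper
instrumental-variable sandwich SE (stage-2 residuals computed with the
observed, not fitted, exposure).  For a binary outcome the causal log-odds
per exposure unit is the ratio of the logistic reduced-form coefficient
(outcome on score) to the linear first-stage coefficient (exposure on
score), with a delta-method SE; the reverse direction (binary exposure,
continuous outcome) mirrors this with a logistic first stage, yielding
outcome units per unit exposure log-odds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .twosample import MREstimate

__all__ = ["StageFit", "OneSampleFit", "OneSampleMR",
           "tsls_continuous", "ratio_binary"]


@dataclass(frozen=True)
class StageFit:
    """One regression stage: instrument coefficient, SE and model family."""

    coef: float
    se: float
    family: str
    r_squared: float | None = None
    f_statistic: float | None = None


@dataclass
class OneSampleFit:
    """First stage, reduced form and the implied causal estimate."""

    first_stage: StageFit
    reduced_form: StageFit
    causal: MREstimate
    covariates: tuple

    def summary(self) -> str:
        fs, rf, c = self.first_stage, self.reduced_form, self.causal
        lines = [
            f"One-sample MR ({c.method})",
            f"  first stage ({fs.family}): coef = {fs.coef:.4g} "
            f"(SE {fs.se:.3g})"
            + (f", F = {fs.f_statistic:.1f}" if fs.f_statistic else ""),
            f"  reduced form ({rf.family}): coef = {rf.coef:.4g} "
            f"(SE {rf.se:.3g})",
            f"  causal: beta = {c.beta:.4g} (SE {c.se:.3g}), "
            f"95% CI [{c.ci_low:.4g}, {c.ci_high:.4g}], P = {c.pvalue:.2g}",
        ]
        if self.covariates:
            lines.append(f"  adjusted for: {', '.join(self.covariates)}")
        return "\n".join(lines)


def _design(score, covariates, names):
    cols = [np.ones_like(score), np.asarray(score, dtype=float)]
    used = tuple(names or ())
    for nm in used:
        cols.append(covariates[nm].to_numpy(dtype=float))
    return np.column_stack(cols), used


class OneSampleMR:
    """One-sample MR model: exposure, outcome and a score instrument.

    Parameters
    ----------
    exposure, outcome : arrays
    score : array
        The composite genetic instrument (GRS).
    covariates : DataFrame, optional
    exposure_family, outcome_family : {"gaussian", "binomial"}
        Family of each trait; they select the estimator on ``fit()``.
    """

    def __init__(self, exposure, outcome, score, covariates: pd.DataFrame | None = None,
                 exposure_family: str = "gaussian", outcome_family: str = "binomial",
                 weak_f_threshold: float = 10.0):
        self.exposure = np.asarray(exposure, dtype=float)
        self.outcome = np.asarray(outcome, dtype=float)
        self.score = np.asarray(score, dtype=float)
        if not (len(self.exposure) == len(self.outcome) == len(self.score)):
            raise ValueError("exposure, outcome and score lengths differ")
        if np.var(self.score) == 0:
            raise ValueError("degenerate instrument: score has zero variance")
        self.covariates = covariates if covariates is not None else pd.DataFrame(
            index=np.arange(len(self.score)))
        for fam in (exposure_family, outcome_family):
            if fam not in ("gaussian", "binomial"):
                raise ValueError(f"unknown family {fam!r}")
        self.exposure_family = exposure_family
        self.outcome_family = outcome_family
        self.weak_f_threshold = weak_f_threshold

    # ---- stages -----------------------------------------------------------

    def _stage(self, y, family, covariate_names):
        X, used = _design(self.score, self.covariates, covariate_names)
        if family == "gaussian":
            res = sm.OLS(y, X).fit()
            tval = res.tvalues[1]
            return StageFit(coef=float(res.params[1]), se=float(res.bse[1]),
                            family="gaussian",
                            r_squared=float(tval**2 / (tval**2 + res.df_resid)),
                            f_statistic=float(tval**2)), used
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return StageFit(coef=float(res.params[1]), se=float(res.bse[1]),
                        family="binomial"), used

    def fit(self, covariates: tuple = (), second_order_se: bool = True,
            n_boot: int = 0, seed=None) -> OneSampleFit:
        """Estimate the causal effect.

        gaussian exposure + gaussian outcome → 2SLS; binary outcome →
        logistic reduced form ratio (log-odds per exposure unit); binary
        exposure + gaussian outcome → logistic first stage ratio (outcome
        units per exposure log-odds).  ``n_boot > 0`` replaces the delta SE
        with a nonparametric individual-resampling bootstrap SE.
        """
        if self.exposure_family == "gaussian" and self.outcome_family == "gaussian":
            fit = self._tsls(covariates)
        else:
            fit = self._ratio(covariates, second_order_se)
        if n_boot > 0:
            fit = self._bootstrap_se(fit, covariates, n_boot, seed)
        return fit

    def _tsls(self, covariate_names) -> OneSampleFit:
        first, used = self._stage(self.exposure, "gaussian", covariate_names)
        if first.f_statistic is not None and first.f_statistic < self.weak_f_threshold:
            warnings.warn(
                f"weak instrument: first-stage F = {first.f_statistic:.2f} "
                f"< {self.weak_f_threshold}", RuntimeWarning, stacklevel=3)
        reduced, _ = self._stage(self.outcome, "gaussian", covariate_names)

        Z, _ = _design(self.score, self.covariates, covariate_names)
        X, _ = _design(self.exposure, self.covariates, covariate_names)
        y = self.outcome
        ztx = Z.T @ X
        beta = np.linalg.solve(ztx, Z.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - X.shape[1])
        cov = sigma2 * np.linalg.solve(ztx, np.linalg.solve(ztx.T, Z.T @ Z).T)
        causal = MREstimate.from_beta_se("tsls", beta[1], np.sqrt(cov[1, 1]), 1,
                                         exposure_type="continuous")
        return OneSampleFit(first_stage=first, reduced_form=reduced,
                            causal=causal, covariates=used)

    def _ratio(self, covariate_names, second_order_se: bool) -> OneSampleFit:
        if self.outcome_family == "binomial":
            cases = int(self.outcome.sum())
            if cases < 10 or cases > len(self.outcome) - 10:
                raise ValueError("insufficient cases for a binary-outcome MR")
            exposure_type = "continuous"
            method = "ratio_binary"
        else:
            exposure_type = "binary"
            method = "ratio_binary_exposure"
            cases = int(self.exposure.sum())
            if cases < 10 or cases > len(self.exposure) - 10:
                raise ValueError("insufficient cases for a binary-exposure MR")

        first, used = self._stage(self.exposure, self.exposure_family,
                                  covariate_names)
        reduced, _ = self._stage(self.outcome, self.outcome_family,
                                 covariate_names)
        if first.f_statistic is not None and first.f_statistic < self.weak_f_threshold:
            warnings.warn(
                f"weak instrument: first-stage F = {first.f_statistic:.2f} "
                f"< {self.weak_f_threshold}", RuntimeWarning, stacklevel=3)
        g, sg = first.coef, first.se
        G, sG = reduced.coef, reduced.se
        if g == 0:
            raise ValueError("first-stage coefficient is zero")
        beta = G / g
        var = sG**2 / g**2
        if second_order_se:
            var += G**2 * sg**2 / g**4
        causal = MREstimate.from_beta_se(method, beta, np.sqrt(var), 1,
                                         exposure_type=exposure_type)
        return OneSampleFit(first_stage=first, reduced_form=reduced,
                            causal=causal, covariates=used)

    def _bootstrap_se(self, fit: OneSampleFit, covariates, n_boot: int,
                      seed) -> OneSampleFit:
        rng = np.random.default_rng(seed)
        n = len(self.score)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            sub = OneSampleMR(self.exposure[idx], self.outcome[idx],
                              self.score[idx], self.covariates.iloc[idx],
                              self.exposure_family, self.outcome_family,
                              weak_f_threshold=0.0)
            draws[b] = sub.fit(covariates).causal.beta
        causal = MREstimate.from_beta_se(
            fit.causal.method, fit.causal.beta, draws.std(ddof=1), 1,
            se_method="bootstrap", **{k: v for k, v in fit.causal.info.items()
                                      if k != "se_method"})
        return OneSampleFit(first_stage=fit.first_stage,
                            reduced_form=fit.reduced_form,
                            causal=causal, covariates=fit.covariates)


# ---- functional wrappers --------------------------------------------------

def tsls_continuous(data, score, covariates: tuple = ()) -> OneSampleFit:
    """2SLS for a continuous outcome; ``data`` is an IndividualDataset."""
    model = OneSampleMR(data.exposure, data.outcome, score,
                        covariates=data.covariates,
                        exposure_family="gaussian", outcome_family="gaussian")
    return model.fit(covariates=covariates)


def ratio_binary(data, score, covariates: tuple = ()) -> OneSampleFit:
    """Logistic-reduced-form ratio estimator for a binary outcome."""
    model = OneSampleMR(data.exposure, data.outcome, score,
                        covariates=data.covariates,
                        exposure_family="gaussian", outcome_family="binomial")
    return model.fit(covariates=covariates)
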