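"""Two-sample Mendelian randomization from harmonized summary statistics.

Given per-SNP exposure effects γ_j (SE σ_γj) and outcome effects Γ_j
(SE σ_Γj) the per-SNP Wald ratio Γ_j/γ_j estimates the causal effect.  The
estimators here combine the ratios:

* IVW — inverse-variance weighted mean, equivalently weighted least squares
  of Γ on γ through the origin with weights 1/σ_Γj²;
* MR-Egger — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy, the slope remains a causal
  estimate under the InSIDE assumption;
* weighted median — consistent when ≥50% of the weight comes from valid
  instruments; SE by parametric bootstrap;
* Cochran's Q — heterogeneity of the per-SNP ratios around the pooled fit.

All effects are kept on the log-odds scale for binary outcomes; conversion
to odds ratios (or to the per-doubling-of-odds scale for binary exposures)
happens only at reporting time and is recorded in the estimate's ``scale``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "wald_ratio",
    "TwoSampleMR",
    "TwoSampleMRResults",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "scale_per_doubling",
    "to_odds_ratio",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MREstimate:
    """A method-tagged causal-effect estimate with its uncertainty.

    ``scale`` is one of ``per_unit`` (outcome log-odds — or outcome units —
    per unit of exposure) or ``per_doubling`` (outcome units per doubling of
    exposure odds, binary exposures only).  ``info`` carries method metadata
    such as the exposure type and never participates in comparisons.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    scale: str = "per_unit"
    info: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int,
                     scale: str = "per_unit", **info) -> "MREstimate":
        beta = float(beta)
        se = float(se)
        if se <= 0 or not np.isfinite(se):
            raise ValueError("standard error must be positive and finite")
        p = 2.0 * stats.norm.sf(abs(beta) / se)
        return cls(method=method, beta=beta, se=se,
                   ci_low=beta - _Z95 * se, ci_high=beta + _Z95 * se,
                   pvalue=float(p), n_snps=int(n_snps), scale=scale, info=info)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom and upper-tail p-value."""

    q: float
    df: int
    pvalue: float


def wald_ratio(gamma: float, se_gamma: float, Gamma: float, se_Gamma: float,
               second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate Γ/γ with a delta-method SE.

    First order: SE = σ_Γ/|γ|.  The second-order option adds the
    exposure-side term Γ²σ_γ²/γ⁴ inside the square root.
    """
    if gamma == 0:
        raise ValueError("weak/null instrument for ratio: gamma is zero")
    beta = Gamma / gamma
    var = (se_Gamma / gamma) ** 2
    if second_order:
        var += Gamma**2 * se_gamma**2 / gamma**4
    return MREstimate.from_beta_se("wald", beta, np.sqrt(var), 1)


def _extract(instruments):
    """Accept a HarmonizedInstrumentSet, DataFrame, or dict of arrays."""
    if hasattr(instruments, "table"):
        t = instruments.table
    elif isinstance(instruments, pd.DataFrame):
        t = instruments
    else:
        t = pd.DataFrame(instruments)
    arrs = tuple(t[c].to_numpy(dtype=float)
                 for c in ("gamma", "se_gamma", "Gamma", "se_Gamma"))
    ids = (t["variant_id"].to_numpy() if "variant_id" in t
           else np.arange(len(t)))
    return (*arrs, ids)


class TwoSampleMR:
    """Two-sample MR model over a harmonized instrument set.

    Parameters
    ----------
    instruments
        A :class:`~ivmr.instruments.HarmonizedInstrumentSet` (or DataFrame
        with columns gamma, se_gamma, Gamma, se_Gamma).
    exposure_type
        ``"continuous"`` or ``"binary"``; a binary exposure marks estimates
        as per unit log-odds, enabling the per-doubling scale transform.
    """

    def __init__(self, instruments, exposure_type: str = "continuous"):
        g, sg, G, sG, ids = _extract(instruments)
        keep = np.isfinite(g) & np.isfinite(sg) & np.isfinite(G) & np.isfinite(sG)
        self.gamma, self.se_gamma = g[keep], sg[keep]
        self.Gamma, self.se_Gamma = G[keep], sG[keep]
        self.variant_ids = ids[keep]
        if np.any(self.se_gamma <= 0) or np.any(self.se_Gamma <= 0):
            raise ValueError("all standard errors must be positive")
        self.exposure_type = exposure_type

    @property
    def n_snps(self) -> int:
        return self.gamma.shape[0]

    # ---- individual estimators -------------------------------------------

    def wald_ratios(self, second_order: bool = False) -> pd.DataFrame:
        """Per-SNP Wald ratios and delta-method SEs as a tidy table."""
        if np.any(self.gamma == 0):
            raise ValueError("weak/null instrument for ratio: gamma is zero")
        beta = self.Gamma / self.gamma
        var = (self.se_Gamma / self.gamma) ** 2
        if second_order:
            var += self.Gamma**2 * self.se_gamma**2 / self.gamma**4
        return pd.DataFrame({"variant_id": self.variant_ids, "beta": beta,
                             "se": np.sqrt(var)})

    def ivw(self, mode: str = "fixed") -> MREstimate:
        """Inverse-variance-weighted estimate (WLS of Γ on γ through origin).

        ``mode="multiplicative_random"`` inflates the fixed-effect SE by
        √max(1, Q/(J−1)) to absorb over-dispersion of the per-SNP ratios.
        """
        if mode not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown IVW mode {mode!r}")
        J = self.n_snps
        if J == 0 or not np.any(self.gamma != 0):
            raise ValueError("no usable instruments for IVW")
        w = 1.0 / self.se_Gamma**2
        denom = float(np.sum(w * self.gamma**2))
        beta = float(np.sum(w * self.gamma * self.Gamma)) / denom
        se = np.sqrt(1.0 / denom)
        method = "ivw_fixed"
        if mode == "multiplicative_random":
            if J == 1:
                warnings.warn("single instrument: multiplicative-random IVW "
                              "falls back to fixed", RuntimeWarning, stacklevel=2)
            else:
                q = float(np.sum(w * (self.Gamma - beta * self.gamma) ** 2))
                se *= np.sqrt(max(1.0, q / (J - 1)))
                method = "ivw_mre"
        return MREstimate.from_beta_se(method, beta, se, J,
                                       exposure_type=self.exposure_type)

    def egger(self) -> tuple[MREstimate, MREstimate]:
        """MR-Egger regression: (slope, intercept) estimates.

        γ are oriented positive first (flipping Γ alongside), the standard
        identifiability convention; weights are 1/σ_Γ² and coefficient SEs
        carry the multiplicative residual inflation max(1, RSS_w/(J−2)).
        """
        J = self.n_snps
        if J < 3:
            raise ValueError("insufficient instruments for Egger (need >= 3)")
        sign = np.where(self.gamma < 0, -1.0, 1.0)
        g = self.gamma * sign
        G = self.Gamma * sign
        w = 1.0 / self.se_Gamma**2
        sw, swg = w.sum(), (w * g).sum()
        swgg, swG, swgG = (w * g * g).sum(), (w * G).sum(), (w * g * G).sum()
        det = sw * swgg - swg**2
        if det <= 0:
            raise ValueError("degenerate design: instrument effects are collinear")
        slope = (sw * swgG - swg * swG) / det
        intercept = (swgg * swG - swg * swgG) / det
        rss = float(np.sum(w * (G - intercept - slope * g) ** 2))
        sigma2 = max(1.0, rss / (J - 2))
        se_slope = np.sqrt(sigma2 * sw / det)
        se_intercept = np.sqrt(sigma2 * swgg / det)
        return (
            MREstimate.from_beta_se("egger_slope", slope, se_slope, J,
                                    exposure_type=self.exposure_type,
                                    orientation="gamma_positive"),
            MREstimate.from_beta_se("egger_intercept", intercept, se_intercept, J,
                                    orientation="gamma_positive"),
        )

    def weighted_median(self, n_boot: int = 2000, seed=None) -> MREstimate:
        """Weighted median of the Wald ratios (50% breakdown estimator).

        The estimate interpolates the ratio order statistics at cumulative
        normalised inverse-variance weight 0.5; the SE comes from a
        parametric bootstrap resampling (γ_j, Γ_j) from their normals.
        """
        if self.n_snps < 3:
            raise ValueError("insufficient instruments for weighted median")
        if n_boot < 2:
            raise ValueError("n_boot must be at least 2")
        if n_boot < 100:
            warnings.warn("n_boot < 100 gives unstable bootstrap SEs",
                          RuntimeWarning, stacklevel=2)
        ratios = self.Gamma / self.gamma
        w = self.gamma**2 / self.se_Gamma**2   # 1 / Var(ratio), first order
        est = _weighted_median(ratios, w)

        rng = np.random.default_rng(seed)
        g = rng.normal(self.gamma[:, None], self.se_gamma[:, None],
                       (self.n_snps, n_boot))
        G = rng.normal(self.Gamma[:, None], self.se_Gamma[:, None],
                       (self.n_snps, n_boot))
        with np.errstate(divide="ignore", invalid="ignore"):
            rb = G / g
            wb = g**2 / self.se_Gamma[:, None] ** 2
        order = np.argsort(rb, axis=0)
        rb_s = np.take_along_axis(rb, order, axis=0)
        wb_s = np.take_along_axis(wb, order, axis=0)
        cum = np.cumsum(wb_s, axis=0) - 0.5 * wb_s
        cum /= wb_s.sum(axis=0, keepdims=True)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = np.interp(0.5, cum[:, b], rb_s[:, b])
        se = float(boots.std(ddof=1))
        return MREstimate.from_beta_se("weighted_median", est, se, self.n_snps,
                                       n_boot=n_boot,
                                       exposure_type=self.exposure_type)

    def heterogeneity(self, pooled: MREstimate | float | None = None
                      ) -> HeterogeneityResult:
        """Cochran's Q of the per-SNP Wald ratios around the pooled estimate."""
        J = self.n_snps
        if J < 2:
            raise ValueError("need at least 2 instruments for Cochran's Q")
        if pooled is None:
            pooled = self.ivw(mode="fixed")
        beta0 = pooled.beta if isinstance(pooled, MREstimate) else float(pooled)
        ratios = self.Gamma / self.gamma
        w = self.gamma**2 / self.se_Gamma**2
        q = float(np.sum(w * (ratios - beta0) ** 2))
        df = J - 1
        return HeterogeneityResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))

    # ---- fitting ----------------------------------------------------------

    def fit(self, methods=("ivw", "egger", "weighted_median"),
            ivw_mode: str = "fixed", n_boot: int = 2000,
            seed=None) -> "TwoSampleMRResults":
        estimates: dict[str, MREstimate] = {}
        for m in methods:
            if m == "ivw":
                estimates["ivw"] = self.ivw(mode=ivw_mode)
            elif m == "egger":
                slope, intercept = self.egger()
                estimates["egger_slope"] = slope
                estimates["egger_intercept"] = intercept
            elif m == "weighted_median":
                estimates["weighted_median"] = self.weighted_median(
                    n_boot=n_boot, seed=seed)
            else:
                raise ValueError(f"unknown method {m!r}")
        het = self.heterogeneity() if self.n_snps >= 2 else None
        return TwoSampleMRResults(model=self, estimates=estimates,
                                  heterogeneity=het)


@dataclass
class TwoSampleMRResults:
    """Fitted two-sample MR estimates with heterogeneity diagnostics."""

    model: TwoSampleMR
    estimates: dict
    heterogeneity: HeterogeneityResult | None

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (method, beta, se, ci, p, n_snps, scale)."""
        rows = [{
            "method": est.method, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pvalue": est.pvalue, "n_snps": est.n_snps, "scale": est.scale,
        } for est in self.estimates.values()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Two-sample Mendelian randomization",
                 f"  instruments: {self.model.n_snps}"]
        lines.append(self.to_frame().to_string(index=False,
                                               float_format="%0.4g"))
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(f"  Cochran's Q = {h.q:.2f} (df = {h.df}, "
                         f"P = {h.pvalue:.2g})")
        return "\n".join(lines)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, cum, v))


# ---- functional wrappers (operate on a harmonized set directly) -----------

def ivw(instruments, mode: str = "fixed",
        exposure_type: str = "continuous") -> MREstimate:
    return TwoSampleMR(instruments, exposure_type).ivw(mode=mode)


def mr_egger(instruments, exposure_type: str = "continuous"):
    return TwoSampleMR(instruments, exposure_type).egger()


def weighted_median(instruments, n_boot: int = 2000, seed=None,
                    exposure_type: str = "continuous") -> MREstimate:
    return TwoSampleMR(instruments, exposure_type).weighted_median(
        n_boot=n_boot, seed=seed)


def cochran_q(instruments, pooled: MREstimate | float | None = None
              ) -> HeterogeneityResult:
    return TwoSampleMR(instruments).heterogeneity(pooled)


# ---- scale transforms -----------------------------------------------------

_LN2 = float(np.log(2.0))


def scale_per_doubling(est: MREstimate) -> MREstimate:
    """Rescale a binary-exposure estimate to per doubling of exposure odds.

    Effects of a binary exposure are estimated per unit of its log-odds; one
    doubling of the odds is ln 2 units, so beta, SE and CI all scale by ln 2.
    """
    if est.scale != "per_unit":
        raise ValueError("estimate is not on the per-unit scale")
    if est.info.get("exposure_type") != "binary":
        raise ValueError("per-doubling scale applies only to a binary "
                         "(log-odds) exposure")
    return replace(est, beta=est.beta * _LN2, se=est.se * _LN2,
                   ci_low=est.ci_low * _LN2, ci_high=est.ci_high * _LN2,
                   scale="per_doubling")


def to_odds_ratio(est: MREstimate) -> dict:
    """Report a log-odds-scale estimate as an odds ratio with CI.

    Returns a reporting record; the log-scale parent estimate is retained
    under ``"estimate"``.
    """
    return {
        "or": float(np.exp(est.beta)),
        "or_ci_low": float(np.exp(est.ci_low)),
        "or_ci_high": float(np.exp(est.ci_high)),
        "pvalue": est.pvalue,
        "method": est.method,
        "estimate": est,
    }
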