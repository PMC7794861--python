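"""Vectorised per-variant association scans.

Marginal per-allele regressions for every SNP of a genotype matrix at once:
simple linear regression for a continuous trait, univariate logistic
regression (intercept + allele count) for a binary trait.  The logistic fit
exploits that with genotypes in {0, 1, 2} the likelihood depends on the data
only through the per-genotype-class totals and case counts, so every SNP is a
two-parameter Newton-Raphson problem on three support points; this is exact,
not an approximation, and is checked against statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["batch_linear", "batch_logistic"]

_GENOTYPE_LEVELS = np.array([0.0, 1.0, 2.0])


def batch_linear(genotypes: np.ndarray, y: np.ndarray):
    """Per-column OLS slope of ``y`` on allele count, with intercept.

    Returns ``(beta, se)`` arrays of length ``n_snps``; monomorphic columns
    yield NaN in both.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if G.shape[0] != n:
        raise ValueError("genotypes and trait have different lengths")
    if n < 3:
        raise ValueError("need at least 3 individuals for a regression")

    gbar = G.mean(axis=0)
    ybar = y.mean()
    sxx = np.einsum("ij,ij->j", G, G) - n * gbar**2
    sxy = G.T @ y - n * gbar * ybar
    syy = y @ y - n * ybar**2

    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe
    sse = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = sse / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    beta[mono] = np.nan
    se[mono] = np.nan
    return beta, se


def _class_counts(genotypes: np.ndarray, y: np.ndarray):
    """Totals and case counts per genotype class, shape (3, n_snps)."""
    G = np.asarray(genotypes)
    y = np.asarray(y, dtype=float)
    totals = np.empty((3, G.shape[1]))
    cases = np.empty((3, G.shape[1]))
    for k in range(3):
        mask = G == k
        totals[k] = mask.sum(axis=0)
        cases[k] = y @ mask
    return totals, cases


def batch_logistic(genotypes: np.ndarray, y: np.ndarray,
                   tol: float = 1e-10, max_iter: int = 60):
    """Per-column logistic regression of a binary trait on allele count.

    Returns ``(beta, se, converged)``; slope is log-odds per allele.
    Monomorphic or non-converged (separated) columns yield NaN.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for a regression")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary trait must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("binary trait has a single class")

    totals, cases = _class_counts(genotypes, y)
    J = totals.shape[1]
    x = _GENOTYPE_LEVELS[:, None]

    gvar = (totals * x**2).sum(0) / n - ((totals * x).sum(0) / n) ** 2
    mono = gvar <= 0

    rate = y.mean()
    a = np.full(J, np.log(rate / (1.0 - rate)))
    b = np.zeros(J)
    converged = np.zeros(J, dtype=bool)
    haa = hab = hbb = det = None

    for _ in range(max_iter):
        eta = np.clip(a + b * x, -30.0, 30.0)
        p = expit(eta)
        resid = cases - totals * p
        w = totals * p * (1.0 - p)
        ga = resid.sum(0)
        gb = (x * resid).sum(0)
        haa = w.sum(0)
        hab = (x * w).sum(0)
        hbb = (x**2 * w).sum(0)
        det = haa * hbb - hab**2
        det_safe = np.where(det <= 0, 1.0, det)
        da = (hbb * ga - hab * gb) / det_safe
        db = (haa * gb - hab * ga) / det_safe
        da = np.where(mono | (det <= 0), 0.0, da)
        db = np.where(mono | (det <= 0), 0.0, db)
        a += da
        b += db
        converged = np.maximum(np.abs(da), np.abs(db)) < tol
        if converged[~mono].all() if (~mono).any() else True:
            break

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(haa / det)
    bad = mono | ~converged | (det <= 0) | ~np.isfinite(se)
    beta = np.where(bad, np.nan, b)
    se = np.where(bad, np.nan, se)
    return beta, se, ~bad
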