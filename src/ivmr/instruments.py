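"""Genetic instruments: summary-statistic IO, harmonization and diagnostics.

Summary statistics live in plain pandas DataFrames with a fixed schema
(``SUMMARY_COLUMNS``); one row per SNP and trait, effects per copy of the
effect allele (log-odds for binary traits).  Harmonization aligns an
exposure table and an outcome table onto the exposure's effect alleles,
flipping outcome effect signs where the allele labels are swapped and
excluding anything irreconcilable — every input SNP ends up exactly once in
either the retained set or the exclusion log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SUMMARY_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "validate_summary_stats",
    "harmonize",
    "HarmonizedInstrumentSet",
    "build_grs",
    "impute_missing_genotypes",
    "InstrumentDiagnostics",
    "instrument_strength",
    "confounder_screen",
]

SUMMARY_COLUMNS = ("variant_id", "effect_allele", "other_allele",
                   "eaf", "beta", "se", "pvalue", "n")
_REQUIRED = ("variant_id", "effect_allele", "other_allele", "beta", "se")
_VALID_ALLELES = {"A", "C", "G", "T"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

#: common public-GWAS column spellings, applied case-insensitively on read
DEFAULT_ALIASES = {
    "snp": "variant_id", "rsid": "variant_id", "markername": "variant_id",
    "a1": "effect_allele", "allele1": "effect_allele", "ea": "effect_allele",
    "a2": "other_allele", "allele2": "other_allele", "oa": "other_allele",
    "nea": "other_allele", "freq": "eaf", "eaf": "eaf", "effect_allele_freq": "eaf",
    "b": "beta", "effect": "beta", "stderr": "se", "standard_error": "se",
    "p": "pvalue", "pval": "pvalue", "p_value": "pvalue", "samplesize": "n",
}


def validate_summary_stats(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a summary-statistics table into valid rows and an exclusion log."""
    table = table.copy()
    reasons = pd.Series("", index=table.index, dtype=object)

    def mark(mask, reason):
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    for col in ("beta", "se", "eaf", "pvalue"):
        if col in table:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        table[col] = table[col].astype(str).str.upper().str.strip()

    mark(table["variant_id"].duplicated(keep="first"), "duplicate variant id")
    mark(~table["effect_allele"].isin(_VALID_ALLELES)
         | ~table["other_allele"].isin(_VALID_ALLELES), "invalid allele")
    mark(table["effect_allele"] == table["other_allele"], "identical alleles")
    mark(table["beta"].isna(), "unparsable or missing beta")
    mark(table["se"].isna() | (table["se"] <= 0), "nonpositive SE")
    if "eaf" in table:
        mark(table["eaf"].notna() & ((table["eaf"] <= 0) | (table["eaf"] >= 1)),
             "eaf outside (0,1)")
    if "pvalue" in table:
        mark(table["pvalue"].notna()
             & ((table["pvalue"] <= 0) | (table["pvalue"] > 1)),
             "pvalue outside (0,1]")

    bad = reasons != ""
    exclusions = pd.DataFrame({
        "variant_id": table.loc[bad, "variant_id"].to_numpy(),
        "reason": reasons[bad].to_numpy(),
    })
    return table.loc[~bad].reset_index(drop=True), exclusions


def read_summary_stats(path, aliases: dict | None = None, sep: str = "\t"):
    """Read a GWAS summary-statistics table.

    Column names are mapped through ``aliases`` (defaults cover common
    public-GWAS spellings) case-insensitively.  Returns ``(table, exclusions)``:
    rows violating the schema invariants are routed to the exclusion log with
    a reason, never silently dropped.  A missing required column is a hard
    error naming the column.
    """
    raw = pd.read_csv(path, sep=sep)
    alias_map = {k.lower(): v for k, v in DEFAULT_ALIASES.items()}
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})
    renamed = {c: alias_map.get(c.lower(), c.lower()) for c in raw.columns}
    raw = raw.rename(columns=renamed)
    for col in _REQUIRED:
        if col not in raw.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    for col in SUMMARY_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    return validate_summary_stats(raw[list(SUMMARY_COLUMNS)])


def write_summary_stats(table: pd.DataFrame, path) -> None:
    """Write a summary-statistics table in the package's TSV dialect."""
    cols = [c for c in SUMMARY_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP (γ, Γ) pairs ready for ratio estimation.

    ``table`` columns: variant_id, effect_allele, other_allele, gamma,
    se_gamma, Gamma, se_Gamma, eaf_exposure, eaf_outcome.  ``exclusions``
    records every input SNP not retained, with a reason.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gamma(self) -> np.ndarray:
        return self.table["gamma"].to_numpy(dtype=float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.table["se_gamma"].to_numpy(dtype=float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.table["Gamma"].to_numpy(dtype=float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.table["se_Gamma"].to_numpy(dtype=float)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["variant_id"].to_numpy()


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_policy: str = "strict-exclude") -> HarmonizedInstrumentSet:
    """Align exposure- and outcome-side summary statistics on effect alleles.

    Rules, applied per SNP present in both tables:

    * identical allele labels → keep as is;
    * labels swapped (outcome effect allele = exposure other allele and vice
      versa) → flip the outcome beta sign and eaf → 1 − eaf;
    * palindromic SNPs (A/T or C/G): under ``"strict-exclude"`` (default)
      always excluded — strand cannot be established from the labels; under
      ``"eaf-infer"`` kept only when both allele frequencies clearly agree in
      orientation (both < 0.42 or both > 0.58), excluded otherwise;
    * anything else → excluded as an allele mismatch.

    SNPs missing from either table, or with a missing/non-positive SE, go to
    the exclusion log.  Harmonizing an already-harmonized pair is a no-op.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("both summary-statistics tables must be nonempty")
    if palindrome_policy not in ("strict-exclude", "eaf-infer"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    exclusions: list[tuple[str, str]] = []
    e_ids = set(exposure["variant_id"])
    o_ids = set(outcome["variant_id"])
    for vid in exposure.loc[~exposure["variant_id"].isin(o_ids), "variant_id"]:
        exclusions.append((vid, "missing in outcome table"))
    for vid in outcome.loc[~outcome["variant_id"].isin(e_ids), "variant_id"]:
        exclusions.append((vid, "missing in exposure table"))

    merged = exposure.merge(outcome, on="variant_id", suffixes=("_e", "_o"))
    rows = []
    for rec in merged.itertuples(index=False):
        vid = rec.variant_id
        for se in (rec.se_e, rec.se_o):
            if not np.isfinite(se) or se <= 0:
                exclusions.append((vid, "missing or nonpositive SE"))
                break
        else:
            ea_e, oa_e = rec.effect_allele_e, rec.other_allele_e
            ea_o, oa_o = rec.effect_allele_o, rec.other_allele_o
            if (ea_o, oa_o) == (ea_e, oa_e):
                flip = False
            elif (ea_o, oa_o) == (oa_e, ea_e):
                flip = True
            else:
                exclusions.append((vid, "allele mismatch"))
                continue
            beta_o = -rec.beta_o if flip else rec.beta_o
            eaf_o = rec.eaf_o
            if flip and np.isfinite(eaf_o):
                eaf_o = 1.0 - eaf_o
            if _is_palindromic(ea_e, oa_e):
                if palindrome_policy == "strict-exclude":
                    exclusions.append((vid, "palindromic"))
                    continue
                eaf_e = rec.eaf_e
                if (not np.isfinite(eaf_e) or not np.isfinite(eaf_o)
                        or not ((eaf_e < 0.42 and eaf_o < 0.42)
                                or (eaf_e > 0.58 and eaf_o > 0.58))):
                    exclusions.append((vid, "palindromic ambiguous orientation"))
                    continue
            rows.append({
                "variant_id": vid,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "gamma": rec.beta_e,
                "se_gamma": rec.se_e,
                "Gamma": beta_o,
                "se_Gamma": rec.se_o,
                "eaf_exposure": rec.eaf_e,
                "eaf_outcome": eaf_o,
            })

    table = pd.DataFrame(rows, columns=[
        "variant_id", "effect_allele", "other_allele", "gamma", "se_gamma",
        "Gamma", "se_Gamma", "eaf_exposure", "eaf_outcome"])
    log = pd.DataFrame(exclusions, columns=["variant_id", "reason"])
    return HarmonizedInstrumentSet(table=table, exclusions=log)


def build_grs(genotypes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted genetic risk score: score_i = Σ_j w_j g_ij.

    Missing genotypes are a hard error; impute explicitly first
    (see :func:`impute_missing_genotypes`) or drop the SNP.
    """
    G = np.asarray(genotypes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if G.ndim != 2 or G.shape[1] != w.shape[0]:
        raise ValueError("weight vector length must equal genotype column count")
    if np.isnan(G).any():
        raise ValueError("missing genotypes; impute or exclude before scoring")
    return G @ w


def impute_missing_genotypes(genotypes: np.ndarray, eaf: np.ndarray) -> np.ndarray:
    """Replace missing genotype entries by their expectation 2·eaf."""
    G = np.asarray(genotypes, dtype=float).copy()
    fill = np.broadcast_to(2.0 * np.asarray(eaf, dtype=float), G.shape)
    mask = np.isnan(G)
    G[mask] = fill[mask]
    return G


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """First-stage strength of an instrument: R² and the F-statistic."""

    f_statistic: float
    r_squared: float
    n: int
    k: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"F = {self.f_statistic:.1f}, R² = {100 * self.r_squared:.2f}% "
                f"(n = {self.n}, k = {self.k})")


def instrument_strength(score: np.ndarray, exposure: np.ndarray,
                        k: int = 1) -> InstrumentDiagnostics:
    """Instrument-strength diagnostics from the score→exposure regression.

    R² comes from the simple linear regression of the exposure on the score;
    F = ((n − k − 1)/k) · R²/(1 − R²), with k the number of instruments the
    score summarises (k = 1 for a single composite GRS).
    """
    score = np.asarray(score, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    n = score.shape[0]
    if exposure.shape[0] != n:
        raise ValueError("score and exposure have different lengths")
    if n < k + 2:
        raise ValueError("need at least k + 2 observations")
    if np.var(score) == 0:
        raise ValueError("degenerate instrument: score has zero variance")
    r = np.corrcoef(score, exposure)[0, 1]
    r2 = float(r * r)
    if r2 >= 1.0 - 1e-12:   # exact affine relation up to float error
        return InstrumentDiagnostics(np.inf, 1.0, n, k)
    f = (n - k - 1) / k * r2 / (1.0 - r2)
    return InstrumentDiagnostics(float(f), r2, n, k)


def confounder_screen(score: np.ndarray, covariates: pd.DataFrame) -> pd.DataFrame:
    """Screen covariates for association with the (standardised) instrument.

    Each covariate is regressed on the score standardised to unit variance,
    so effects read as covariate units per SD of score.  Nominal p < 0.05 is
    flagged without multiplicity adjustment — the screen is diagnostic, not
    confirmatory.  Constant covariates are skipped with a log entry.
    """
    score = np.asarray(score, dtype=float)
    if len(score) < 3:
        raise ValueError("need at least 3 observations")
    sd = score.std()
    if sd == 0:
        raise ValueError("degenerate instrument: score has zero variance")
    z = (score - score.mean()) / sd

    records = []
    for name in covariates.columns:
        v = covariates[name].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            logger.info("confounder_screen: skipping constant covariate %r", name)
            records.append({"covariate": name, "beta": np.nan, "se": np.nan,
                            "pvalue": np.nan, "flagged": False,
                            "note": "constant covariate skipped"})
            continue
        fit = stats.linregress(z, v)
        records.append({"covariate": name, "beta": fit.slope, "se": fit.stderr,
                        "pvalue": fit.pvalue, "flagged": fit.pvalue < 0.05,
                        "note": ""})
    return pd.DataFrame(records)
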