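"""End-to-end bidirectional MR analysis from a single configuration.

A run covers, per direction: instrument diagnostics, a one-sample
GRS-instrumented estimate on an individual-level cohort, two-sample
IVW/Egger/weighted-median estimates on summary statistics from independent
cohorts, heterogeneity, fixed-effect combination of the one- and two-sample
arms, and odds-ratio (forward) or per-doubling-of-odds (reverse) reporting.
Observational analyses (stratified logistic ORs per exposure unit, optional
per-study meta-analysis) run alongside for the confounding-vs-causation
contrast.

In simulation mode three cohorts are drawn per direction, mirroring a
biobank + published-GWAS layout: the biobank supplies individual-level data
for one-sample MR; a second cohort supplies exposure-side summary statistics
and the GRS weights (external weights avoid the overfitting bias of
in-sample weights); a third supplies outcome-side summary statistics.  An
``overlap_fraction`` knob lets the outcome-GWAS cohort share individuals
with the biobank to study the (null-ward) sample-overlap bias.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import __version__
from .instruments import (build_grs, confounder_screen, harmonize,
                          instrument_strength)
from .meta import StudyEstimate, fixed_effect, pool_table
from .onesample import OneSampleMR
from .scenarios import Scenario, build_scenario
from .simulate import IndividualDataset, cohort_to_summary_stats, simulate_cohort
from .twosample import TwoSampleMR

__all__ = ["AnalysisConfig", "AnalysisReport", "SimulatedStudy",
           "simulate_study", "two_sample_from_files", "run_forward",
           "run_reverse", "run_observational", "run_all", "write_report"]

_LN2 = float(np.log(2.0))

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    """Configuration of one bidirectional analysis run."""

    scenario: str = "forward_causal"
    overrides: dict = field(default_factory=dict)
    direction: str = "both"               # forward | reverse | both
    estimators: tuple = ("ivw", "egger", "weighted_median")
    ivw_mode: str = "fixed"
    n_boot: int = 1000
    seed: int = 0
    overlap_fraction: float = 0.0
    covariates: tuple = ()                # covariate names to adjust for
    strata: tuple = ((25.0, 30.0), (30.0, None))
    study_table: str | None = None        # per-study OR CSV for meta section
    output_dir: str | None = None

    def __post_init__(self):
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError("direction must be forward, reverse or both")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclass
class AnalysisReport:
    """Structured result of a run: one DataFrame per report table."""

    sections: dict
    metadata: dict

    def table(self, name: str) -> pd.DataFrame:
        return self.sections[name]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class SimulatedStudy:
    """The three simulated cohorts plus their scenario."""

    scenario: Scenario
    biobank: IndividualDataset
    exposure_gwas: IndividualDataset
    outcome_gwas: IndividualDataset


def simulate_study(config: AnalysisConfig) -> SimulatedStudy:
    scn = build_scenario(config.scenario, seed=config.seed, **config.overrides)
    s_bio, s_exp, s_out = _child_seeds(config.seed, 3)
    biobank = simulate_cohort(scn.config, seed=s_bio)
    exposure_gwas = simulate_cohort(scn.config, seed=s_exp)
    outcome_gwas = simulate_cohort(scn.config, seed=s_out)
    if config.overlap_fraction > 0:
        m = int(round(config.overlap_fraction * scn.config.n_individuals))
        outcome_gwas = IndividualDataset(
            genotypes=np.vstack([biobank.genotypes[:m],
                                 outcome_gwas.genotypes[m:]]),
            exposure=np.concatenate([biobank.exposure[:m],
                                     outcome_gwas.exposure[m:]]),
            outcome=np.concatenate([biobank.outcome[:m],
                                    outcome_gwas.outcome[m:]]),
            covariates=pd.concat([biobank.covariates.iloc[:m],
                                  outcome_gwas.covariates.iloc[m:]],
                                 ignore_index=True),
            variants=outcome_gwas.variants)
    return SimulatedStudy(scn, biobank, exposure_gwas, outcome_gwas)


def _instrument_indices(dataset: IndividualDataset, ids: list[str]) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(dataset.variants["variant_id"])}
    return np.array([lookup[v] for v in ids], dtype=int)


def _direction_section(study: SimulatedStudy, config: AnalysisConfig,
                       direction: str) -> dict:
    """Run one direction (forward: continuous→binary, reverse: binary→continuous)."""
    scn = study.scenario
    if direction == "forward":
        instrument_ids = scn.exposure_instruments
        exp_trait, out_trait = "exposure", "outcome"
        exposure_family = "gaussian"
    else:
        instrument_ids = scn.outcome_instruments
        exp_trait, out_trait = "outcome", "exposure"
        exposure_family = "binomial"

    idx = _instrument_indices(study.biobank, instrument_ids)

    # two-sample arm: exposure-side stats from the exposure-GWAS cohort,
    # outcome-side stats from the independent outcome-GWAS cohort
    exp_stats = cohort_to_summary_stats(study.exposure_gwas, exp_trait, idx)
    out_stats = cohort_to_summary_stats(study.outcome_gwas, out_trait, idx)
    hset = harmonize(exp_stats, out_stats)
    exposure_type = "binary" if exposure_family == "binomial" else "continuous"
    model = TwoSampleMR(hset, exposure_type=exposure_type)
    res2 = model.fit(methods=config.estimators, ivw_mode=config.ivw_mode,
                     n_boot=config.n_boot, seed=_child_seeds(config.seed, 5)[3])

    # one-sample arm on the biobank, GRS weighted by the external stats
    weights = exp_stats.set_index("variant_id").loc[instrument_ids, "beta"]
    usable = weights.notna().to_numpy()
    grs = build_grs(study.biobank.genotypes[:, idx[usable]],
                    weights.to_numpy(dtype=float)[usable])
    bio_exposure = (study.biobank.exposure if direction == "forward"
                    else study.biobank.outcome.astype(float))
    bio_outcome = (study.biobank.outcome if direction == "forward"
                   else study.biobank.exposure)
    diagnostics = instrument_strength(grs, bio_exposure, k=1)
    screen = confounder_screen(grs, study.biobank.covariates)
    os_model = OneSampleMR(
        bio_exposure, bio_outcome, grs, covariates=study.biobank.covariates,
        exposure_family=exposure_family,
        outcome_family="binomial" if direction == "forward" else "gaussian")
    os_fit = os_model.fit(covariates=config.covariates)

    # combine the two arms
    ivw_est = res2.estimates["ivw"]
    combined = fixed_effect([
        StudyEstimate("one_sample", os_fit.causal.beta, os_fit.causal.se),
        StudyEstimate("two_sample_ivw", ivw_est.beta, ivw_est.se),
    ])

    estimates = [dict(arm="one_sample", **_est_row(os_fit.causal))]
    for est in res2.estimates.values():
        estimates.append(dict(arm="two_sample", **_est_row(est)))
    estimates.append({
        "arm": "combined", "method": "meta_fixed", "beta": combined.beta,
        "se": combined.se, "ci_low": combined.ci_low,
        "ci_high": combined.ci_high, "pvalue": combined.pvalue,
        "n_snps": ivw_est.n_snps, "scale": "per_unit",
    })
    table = pd.DataFrame(estimates)

    if direction == "forward":
        # report odds ratios for the binary outcome
        table["or"] = np.exp(table["beta"])
        table["or_ci_low"] = np.exp(table["ci_low"])
        table["or_ci_high"] = np.exp(table["ci_high"])
        table.loc[table["method"] == "egger_intercept",
                  ["or", "or_ci_low", "or_ci_high"]] = np.nan
    else:
        # rescale binary-exposure effects to per doubling of exposure odds
        mask = table["method"] != "egger_intercept"
        for col in ("beta", "se", "ci_low", "ci_high"):
            table.loc[mask, f"{col}_per_doubling"] = table.loc[mask, col] * _LN2
        table.loc[mask, "scale_doubling"] = "per_doubling"

    het = res2.heterogeneity
    diag = pd.DataFrame([{
        "direction": direction, "f_statistic": diagnostics.f_statistic,
        "r_squared": diagnostics.r_squared, "n": diagnostics.n,
        "k": diagnostics.k, "n_instruments_retained": len(hset),
        "n_instruments_excluded": len(hset.exclusions),
        "q": het.q if het else np.nan, "q_df": het.df if het else np.nan,
        "q_pvalue": het.pvalue if het else np.nan,
    }])
    table.insert(0, "direction", direction)
    screen = screen.copy()
    screen.insert(0, "direction", direction)
    return {"estimates": table, "diagnostics": diag,
            "confounder_screen": screen, "exclusions": hset.exclusions,
            "combined": combined}


def two_sample_from_files(exposure_stats_path, outcome_stats_path,
                          config: AnalysisConfig | None = None,
                          exposure_type: str = "continuous"):
    """Two-sample MR directly from summary-statistics files.

    The file-input mode for published-GWAS analyses: read, validate and
    harmonize the two tables, then fit the configured estimator roster.
    Returns ``(results, harmonized_set)``.
    """
    from .instruments import read_summary_stats

    config = config or AnalysisConfig()
    exp_stats, _ = read_summary_stats(exposure_stats_path)
    out_stats, _ = read_summary_stats(outcome_stats_path)
    hset = harmonize(exp_stats, out_stats)
    model = TwoSampleMR(hset, exposure_type=exposure_type)
    results = model.fit(methods=config.estimators, ivw_mode=config.ivw_mode,
                        n_boot=config.n_boot,
                        seed=_child_seeds(config.seed, 1)[0])
    return results, hset


def run_forward(config: AnalysisConfig, study: SimulatedStudy | None = None) -> dict:
    """Forward direction: continuous exposure → binary outcome."""
    study = study or simulate_study(config)
    return _direction_section(study, config, "forward")


def run_reverse(config: AnalysisConfig, study: SimulatedStudy | None = None) -> dict:
    """Reverse direction: binary trait → continuous trait, per-doubling scale."""
    study = study or simulate_study(config)
    return _direction_section(study, config, "reverse")


def run_observational(config: AnalysisConfig,
                      study: SimulatedStudy | None = None) -> dict:
    """Stratified observational logistic ORs per exposure unit.

    Strata are half-open intervals [low, high) of the exposure; strata with
    fewer than 10 cases are skipped (logged in the table's note column).
    """
    study = study or simulate_study(config)
    data = study.biobank
    rows = []
    for low, high in config.strata:
        hi = np.inf if high is None else high
        mask = (data.exposure >= low) & (data.exposure < hi)
        label = f"[{low:g},{'inf' if high is None else f'{high:g}'})"
        n = int(mask.sum())
        cases = int(data.outcome[mask].sum())
        if cases < 10 or cases > n - 10:
            rows.append({"stratum": label, "n": n, "cases": cases,
                         "or_per_unit": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "pvalue": np.nan,
                         "note": "skipped: fewer than 10 cases"})
            continue
        X = sm.add_constant(data.exposure[mask])
        res = sm.GLM(data.outcome[mask], X,
                     family=sm.families.Binomial()).fit()
        b, se = res.params[1], res.bse[1]
        rows.append({"stratum": label, "n": n, "cases": cases,
                     "or_per_unit": float(np.exp(b)),
                     "ci_low": float(np.exp(b - 1.959963984540054 * se)),
                     "ci_high": float(np.exp(b + 1.959963984540054 * se)),
                     "pvalue": float(res.pvalues[1]), "note": ""})
    section = {"observational": pd.DataFrame(rows)}
    if config.study_table:
        studies = pd.read_csv(config.study_table)
        section["meta_observational"] = pool_table(studies, model="random")
    return section


def _stage(name: str, fn, *args, partial: dict | None = None):
    try:
        return fn(*args)
    except Exception as exc:
        if partial:
            logger.error("stage %r failed after sections %s: %s",
                         name, sorted(partial), exc)
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_all(config: AnalysisConfig) -> AnalysisReport:
    """Run the configured directions plus the observational analyses.

    A stage failure aborts the run with a :class:`StageError` naming the
    stage; sections completed before the failure are noted in the log.
    """
    study = _stage("simulate", simulate_study, config)
    sections: dict[str, pd.DataFrame] = {}
    if config.direction in ("forward", "both"):
        fwd = _stage("forward", run_forward, config, study, partial=sections)
        sections["forward_estimates"] = fwd["estimates"]
        sections["forward_diagnostics"] = fwd["diagnostics"]
        sections["forward_confounder_screen"] = fwd["confounder_screen"]
    if config.direction in ("reverse", "both"):
        rev = _stage("reverse", run_reverse, config, study, partial=sections)
        sections["reverse_estimates"] = rev["estimates"]
        sections["reverse_diagnostics"] = rev["diagnostics"]
    obs = _stage("observational", run_observational, config, study,
                 partial=sections)
    sections["observational"] = obs["observational"]
    if "meta_observational" in obs:
        sections["meta_observational"] = obs["meta_observational"]
    metadata = {
        "seed": config.seed,
        "scenario": config.scenario,
        "direction": config.direction,
        "ivmr_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {k: v for k, v in asdict(config).items()
                   if k not in ("output_dir",)},
    }
    report = AnalysisReport(sections=sections, metadata=metadata)
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def write_report(report: AnalysisReport, output_dir) -> None:
    """Write each report table as CSV plus a run-metadata JSON.

    Tables are rendered with a fixed float format so identical runs produce
    byte-identical files (the metadata file alone carries the timestamp).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in report.sections.items():
        table.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    meta = dict(report.metadata)
    meta["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in meta["config"].items()}
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2,
                                                      default=str))


def _est_row(est) -> dict:
    return {"method": est.method, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pvalue": est.pvalue, "n_snps": est.n_snps, "scale": est.scale}
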