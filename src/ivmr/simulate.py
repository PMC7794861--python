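"""Synthetic genotype→exposure→outcome cohorts for Mendelian-randomization studies.

The generator encodes the causal diagram an MR design assumes: independent
biallelic SNPs drawn at Hardy-Weinberg equilibrium act on a continuous
exposure (BMI-like, kg/m²), a latent standard-normal confounder acts on both
exposure and outcome, and a binary outcome (prevalence a few percent) follows
a logistic model in the exposure.  Optional direct SNP→outcome effects
(horizontal pleiotropy) and an outcome→exposure shift (reverse causation)
break the instrumental-variable assumptions on demand, so every estimator
downstream can be exercised under scenarios where its assumptions hold or
fail by construction.

SNPs are simulated without linkage disequilibrium: instruments in practice
are index SNPs from distinct GWAS loci and are treated as independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._batchreg import batch_linear, batch_logistic

__all__ = [
    "SimulationConfig",
    "IndividualDataset",
    "simulate_genotypes",
    "simulate_cohort",
    "cohort_to_summary_stats",
    "load_individual_dataset",
]

# non-palindromic allele pairs cycled across variants
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``gamma`` are per-allele exposure effects (exposure units per allele),
    ``pleiotropy`` direct per-allele log-odds effects on the outcome, and
    ``reverse_beta`` an additive exposure shift applied to cases after the
    outcome draw (reverse causation).  ``exposure_mean`` shifts the exposure
    onto its natural scale (e.g. BMI around 25 kg/m²) without touching the
    genetic architecture.
    """

    n_individuals: int
    n_snps: int
    maf: np.ndarray
    gamma: np.ndarray
    exposure_sd: float
    confounder_effect_x: float
    confounder_effect_y: float
    causal_beta: float
    baseline_logodds: float
    pleiotropy: np.ndarray | None = None
    reverse_beta: float = 0.0
    exposure_mean: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.maf = np.asarray(self.maf, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.pleiotropy is None:
            self.pleiotropy = np.zeros(self.n_snps)
        self.pleiotropy = np.asarray(self.pleiotropy, dtype=float)
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name, vec in (("maf", self.maf), ("gamma", self.gamma),
                          ("pleiotropy", self.pleiotropy)):
            if vec.shape != (self.n_snps,):
                raise ValueError(f"{name} must have length n_snps={self.n_snps}")
        if np.any((self.maf <= 0) | (self.maf > 0.5)):
            raise ValueError("all minor-allele frequencies must lie in (0, 0.5]")
        if self.exposure_sd <= 0:
            raise ValueError("exposure_sd must be positive")
        p0 = expit(self.baseline_logodds + self.causal_beta * self.expected_exposure())
        if p0 <= 0.0 or p0 >= 1.0:
            raise ValueError(
                "implied outcome prevalence is degenerate (0 or 1) at the intercept")

    def expected_exposure(self) -> float:
        return float(self.exposure_mean + 2.0 * self.maf @ self.gamma)


@dataclass
class IndividualDataset:
    """One simulated (or loaded) cohort: genotypes plus phenotypes.

    ``variants`` carries per-SNP metadata (variant_id, effect/other allele,
    generating allele frequency); the genotype entry counts copies of the
    effect allele.  The simulated confounder is stored in ``covariates`` so
    instrument-confounder screens can be run against a known truth, but it is
    never adjusted for by default — it stands in for an unmeasured confounder.
    """

    genotypes: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    covariates: pd.DataFrame
    variants: pd.DataFrame = field(default=None)

    def __post_init__(self):
        n, m = self.genotypes.shape
        if not (len(self.exposure) == len(self.outcome) == n):
            raise ValueError("phenotype vectors must match the genotype row count")
        if self.variants is not None and len(self.variants) != m:
            raise ValueError("variants table must match the genotype column count")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, maf: np.ndarray, seed=None) -> np.ndarray:
    """Draw an n × n_snps additive genotype matrix at Hardy-Weinberg equilibrium.

    Entry (i, j) ~ Binomial(2, maf_j), independent across individuals and SNPs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("all minor-allele frequencies must lie in (0, 0.5]")
    rng = _as_rng(seed)
    return rng.binomial(2, maf, size=(n, maf.shape[0])).astype(np.int8)


def default_variants(n_snps: int, maf: np.ndarray | None = None) -> pd.DataFrame:
    ids = [f"snp{j:05d}" for j in range(n_snps)]
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(n_snps)]
    table = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
    })
    if maf is not None:
        table["maf"] = np.asarray(maf, dtype=float)
    return table


def simulate_cohort(config: SimulationConfig, seed=None) -> IndividualDataset:
    """Simulate one cohort under the configured causal structure.

    Generative model (U ~ N(0,1) confounder, ε ~ N(0, exposure_sd²)):

        X0_i = exposure_mean + Σ_j γ_j g_ij + c_x U_i + ε_i
        Y_i  ~ Bernoulli(expit(b0 + β_causal X0_i + c_y U_i + Σ_j α_j g_ij))
        X_i  = X0_i + reverse_beta · Y_i

    so with pleiotropy ≡ 0 and reverse_beta = 0 the exclusion restriction
    holds by construction.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    n = config.n_individuals
    G = simulate_genotypes(n, config.maf, rng)
    U = rng.standard_normal(n)
    eps = rng.normal(0.0, config.exposure_sd, n)
    x0 = (config.exposure_mean + G @ config.gamma
          + config.confounder_effect_x * U + eps)
    eta = (config.baseline_logodds + config.causal_beta * x0
           + config.confounder_effect_y * U + G @ config.pleiotropy)
    y = (rng.random(n) < expit(eta)).astype(np.int8)
    exposure = x0 + config.reverse_beta * y

    prevalence = y.mean()
    if prevalence < 0.001:
        warnings.warn(
            f"simulated outcome prevalence {prevalence:.2%} is below 0.1%",
            RuntimeWarning, stacklevel=2)

    covariates = pd.DataFrame({"confounder": U})
    variants = default_variants(config.n_snps, config.maf)
    return IndividualDataset(genotypes=G, exposure=exposure, outcome=y,
                             covariates=covariates, variants=variants)


def load_individual_dataset(genotypes_path, phenotypes_path,
                            exposure_col: str = "exposure",
                            outcome_col: str = "outcome") -> IndividualDataset:
    """Load a cohort from delimited tables.

    ``genotypes_path``: one column per variant (header = variant id),
    additive 0/1/2 coding.  ``phenotypes_path``: exposure and outcome
    columns (roles configurable) plus any covariates.
    """
    geno = pd.read_csv(genotypes_path)
    pheno = pd.read_csv(phenotypes_path)
    for col in (exposure_col, outcome_col):
        if col not in pheno.columns:
            raise ValueError(f"phenotype column {col!r} missing")
    covars = pheno.drop(columns=[exposure_col, outcome_col])
    variants = default_variants(geno.shape[1])
    variants["variant_id"] = list(geno.columns)
    return IndividualDataset(
        genotypes=geno.to_numpy(),
        exposure=pheno[exposure_col].to_numpy(dtype=float),
        outcome=pheno[outcome_col].to_numpy(),
        covariates=covars.reset_index(drop=True),
        variants=variants)


def cohort_to_summary_stats(data: IndividualDataset, trait: str,
                            columns: np.ndarray | None = None) -> pd.DataFrame:
    """Marginal per-allele GWAS of one trait of a cohort.

    ``trait='exposure'`` fits per-SNP simple linear regressions of the
    continuous trait; ``trait='outcome'`` per-SNP logistic regressions of the
    binary trait (effects on the log-odds scale).  ``columns`` restricts the
    scan to a subset of SNP indices.  Monomorphic (or non-converged) SNPs are
    kept in the table flagged with a missing SE rather than silently dropped.
    """
    if data.n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    idx = np.arange(data.n_snps) if columns is None else np.asarray(columns)
    G = data.genotypes[:, idx]

    if trait == "exposure":
        beta, se = batch_linear(G, data.exposure)
    elif trait == "outcome":
        if data.outcome.min() == data.outcome.max():
            raise ValueError("outcome must contain both classes")
        beta, se, _ = batch_logistic(G, data.outcome)
    else:
        raise ValueError("trait must be 'exposure' or 'outcome'")

    with np.errstate(invalid="ignore", divide="ignore"):
        pval = 2.0 * norm.sf(np.abs(beta / se))
    variants = (data.variants.iloc[idx].reset_index(drop=True)
                if data.variants is not None else default_variants(len(idx)))
    table = pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy(),
        "effect_allele": variants["effect_allele"].to_numpy(),
        "other_allele": variants["other_allele"].to_numpy(),
        "eaf": G.mean(axis=0) / 2.0,
        "beta": beta,
        "se": se,
        "pvalue": pval,
        "n": data.n_individuals,
    })
    table["flag"] = np.where(np.isnan(se), "monomorphic_or_unstable", "")
    return table
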