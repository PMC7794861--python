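"""Named simulation scenarios for the bidirectional BMI↔AD-style study.

Each scenario is a flat key-value YAML file shipped with the package.  The
builder expands it into a concrete :class:`~ivmr.simulate.SimulationConfig`:
minor-allele frequencies are drawn uniformly from the configured range, and
per-SNP exposure effects get heterogeneous variance shares (exponential,
normalised) so the effect-size spread resembles a real GWAS architecture —
a handful of large loci and a long tail.  Uniform shares would make every
instrument carry the same precision-weighted leverage, which renders the
MR-Egger intercept nearly unidentified; heterogeneous shares are both more
realistic and what gives Egger regression its power.

The SNP panel has two blocks: exposure-trait instruments (direct effect on
the continuous trait only) and outcome-trait instruments (direct log-odds
effect on the binary trait only, carried in the ``pleiotropy`` vector).  The
second block is what a reverse-direction analysis instruments; it does not
touch the forward instruments' exclusion restriction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.special import logit

from .simulate import SimulationConfig

__all__ = ["Scenario", "build_scenario", "list_scenarios", "load_scenario_spec"]

SCENARIO_NAMES = (
    "null",
    "forward_causal",
    "confounded_null",
    "directional_pleiotropy",
    "balanced_pleiotropy",
    "reverse_causal",
)


@dataclass
class Scenario:
    """A concrete simulation configuration plus its instrument id lists."""

    name: str
    config: SimulationConfig
    exposure_instruments: list[str]
    outcome_instruments: list[str]


def list_scenarios() -> tuple[str, ...]:
    return SCENARIO_NAMES


def load_scenario_spec(name: str) -> dict:
    """Read a scenario's flat key-value spec (from the packaged YAML or a path)."""
    if name.endswith((".yaml", ".yml")):
        with open(name) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("ivmr") / "scenarios" / f"{name}.yaml"
    if not ref.is_file():
        raise ValueError(f"unknown scenario {name!r}; available: {SCENARIO_NAMES}")
    return yaml.safe_load(ref.read_text())


def build_scenario(name: str, seed: int = 0, **overrides) -> Scenario:
    """Expand a named scenario (plus keyword overrides) into a Scenario.

    The same (name, seed, overrides) always yields the identical
    configuration; cohort draws take their own seeds downstream.
    """
    spec = load_scenario_spec(name)
    unknown = set(overrides) - set(spec)
    if unknown:
        raise ValueError(f"unknown scenario overrides: {sorted(unknown)}")
    spec.update(overrides)

    rng = np.random.default_rng(seed)
    j_exp = int(spec["n_exposure_snps"])
    j_out = int(spec["n_outcome_snps"])
    j_all = j_exp + j_out
    maf = rng.uniform(spec["maf_low"], spec["maf_high"], j_all)
    het_var = 2.0 * maf * (1.0 - maf)

    var_total = float(spec["exposure_sd_total"]) ** 2
    gamma = np.zeros(j_all)
    if j_exp:
        shares = rng.exponential(1.0, j_exp)
        shares /= shares.sum()
        gvar = spec["exposure_h2_instruments"] * var_total * shares
        gamma[:j_exp] = np.sqrt(gvar / het_var[:j_exp])

    pleiotropy = np.zeros(j_all)
    mode = spec.get("instrument_pleiotropy_mode", "none")
    alpha = float(spec.get("instrument_pleiotropy_logodds", 0.0))
    if mode == "directional":
        pleiotropy[:j_exp] = alpha
    elif mode == "balanced":
        pleiotropy[:j_exp] = rng.normal(0.0, alpha, j_exp)
    elif mode != "none":
        raise ValueError(f"unknown pleiotropy mode {mode!r}")
    if j_out:
        pleiotropy[j_exp:] = rng.uniform(spec["outcome_snp_logodds_low"],
                                         spec["outcome_snp_logodds_high"], j_out)

    cx = float(spec["confounder_effect_x"])
    resid_var = var_total * (1.0 - spec["exposure_h2_instruments"]) - cx**2
    if resid_var <= 0:
        raise ValueError("confounder and genetic variance exceed the total "
                         "exposure variance")

    causal_beta = float(np.log(spec["causal_or_per_unit"]))
    target_mean = float(spec["exposure_mean"])
    exposure_mean = target_mean - float(2.0 * maf @ gamma)
    baseline = (logit(spec["baseline_prevalence"])
                - causal_beta * target_mean
                - float(2.0 * maf @ pleiotropy))

    config = SimulationConfig(
        n_individuals=int(spec["n_individuals"]),
        n_snps=j_all,
        maf=maf,
        gamma=gamma,
        exposure_sd=float(np.sqrt(resid_var)),
        confounder_effect_x=cx,
        confounder_effect_y=float(spec["confounder_effect_y"]),
        causal_beta=causal_beta,
        baseline_logodds=baseline,
        pleiotropy=pleiotropy,
        reverse_beta=float(spec["reverse_beta_kgm2"]),
        exposure_mean=exposure_mean,
        seed=seed,
    )
    ids = [f"snp{j:05d}" for j in range(j_all)]
    return Scenario(name=spec.get("name", name), config=config,
                    exposure_instruments=ids[:j_exp],
                    outcome_instruments=ids[j_exp:])
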