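import numpy as np
import pandas as pd
import pytest

from ivmr import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest valid-instrument cohort with known parameters."""
    rng = np.random.default_rng(7)
    j = 12
    maf = rng.uniform(0.1, 0.45, j)
    gamma = rng.normal(0.15, 0.04, j)
    config = SimulationConfig(
        n_individuals=4000, n_snps=j, maf=maf, gamma=gamma,
        exposure_sd=2.0, confounder_effect_x=0.8, confounder_effect_y=0.4,
        causal_beta=np.log(1.1), baseline_logodds=-2.4, seed=11)
    return simulate_cohort(config)


def summary_table(rows):
    """Build a summary-statistics DataFrame from short tuples."""
    cols = ["variant_id", "effect_allele", "other_allele", "eaf", "beta",
            "se", "pvalue", "n"]
    return pd.DataFrame(rows, columns=cols)
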