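"""Minimal forest plot for MR and meta-analysis estimate tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def forest_plot(table: pd.DataFrame, label_col: str = "method",
                beta_col: str = "beta", lo_col: str = "ci_low",
                hi_col: str = "ci_high", null_value: float = 0.0, ax=None):
    """Point-and-whisker forest plot of a tidy estimate table.

    Returns the matplotlib Axes; matplotlib is imported lazily so the rest
    of the package has no hard plotting dependency.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1))
    y = np.arange(len(table))[::-1]
    ax.errorbar(table[beta_col], y,
                xerr=[table[beta_col] - table[lo_col],
                      table[hi_col] - table[beta_col]],
                fmt="o", color="k", capsize=3)
    ax.axvline(null_value, color="grey", lw=1, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(table[label_col])
    ax.set_xlabel("effect (95% CI)")
    return ax
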