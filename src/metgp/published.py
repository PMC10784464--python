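"""Published variance-component estimates used as reference inputs.

REML variance components and genetic parameters reported for a maize
single-cross drought-tolerance program: 265 hybrids (188 lines x 2
testers) evaluated for grain yield (GY, t/ha) and female flowering time
(FFT, days) in four well-watered (WW) and four water-stress (WS)
environments (Janaúba and Teresina, 2010 and 2011). One row per analysis:
the joint four-environment fit per regime (``analysis == "joint"``, with
across-environment correlations) and the eight within-environment fits
(``analysis`` = environment id, no correlations).

These printed estimates serve as inputs for ratio arithmetic (h2, d2, H2,
dominance shares) and as magnitude references for simulation settings;
they are not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["variance_components", "budget_inputs"]

_COLS = ["trait", "regime", "analysis", "sigma2_ua", "sigma2_ud", "sigma2_e",
         "rho_a", "rho_d", "h2", "d2", "H2"]

_ROWS = [
    # trait, regime, analysis, s2_ua, s2_ud, s2_e, rho_a, rho_d, h2, d2, H2
    ("GY", "WS", "joint", 0.60, 0.30, 0.81, 0.35, 0.83, 0.35, 0.17, 0.53),
    ("GY", "WW", "joint", 1.00, 0.45, 1.98, 0.24, 0.85, 0.29, 0.13, 0.42),
    ("GY", "WS", "J10", 0.64, 0.39, 0.66, None, None, 0.38, 0.23, 0.61),
    ("GY", "WS", "T10", 0.88, 0.11, 1.61, None, None, 0.34, 0.04, 0.38),
    ("GY", "WS", "J11", 0.35, 0.34, 0.33, None, None, 0.34, 0.33, 0.68),
    ("GY", "WS", "T11", 0.50, 0.71, 0.44, None, None, 0.30, 0.43, 0.73),
    ("GY", "WW", "J10", 1.47, 0.56, 0.53, None, None, 0.57, 0.22, 0.79),
    ("GY", "WW", "T10", 1.15, 0.61, 1.02, None, None, 0.41, 0.22, 0.63),
    ("GY", "WW", "J11", 1.59, 1.42, 1.83, None, None, 0.33, 0.29, 0.62),
    ("GY", "WW", "T11", 0.96, 0.45, 3.30, None, None, 0.20, 0.10, 0.30),
    ("FFT", "WS", "joint", 4.66, 1.16, 4.54, 0.64, 0.43, 0.45, 0.11, 0.56),
    ("FFT", "WW", "joint", 3.13, 0.82, 1.64, 0.82, 0.37, 0.56, 0.15, 0.71),
    ("FFT", "WS", "J10", 6.86, 0.75, 0.97, None, None, 0.80, 0.09, 0.89),
    ("FFT", "WS", "T10", 1.54, 0.12, 14.73, None, None, 0.09, 0.01, 0.10),
    ("FFT", "WS", "J11", 6.85, 1.88, 1.73, None, None, 0.65, 0.18, 0.83),
    ("FFT", "WS", "T11", 2.04, 1.20, 1.40, None, None, 0.44, 0.26, 0.70),
    ("FFT", "WW", "J10", 4.24, 0.83, 0.69, None, None, 0.74, 0.14, 0.88),
    ("FFT", "WW", "T10", 2.93, 1.15, 1.88, None, None, 0.49, 0.19, 0.68),
    ("FFT", "WW", "J11", 3.42, 0.45, 2.70, None, None, 0.52, 0.07, 0.59),
    ("FFT", "WW", "T11", 2.38, 1.03, 1.04, None, None, 0.54, 0.23, 0.77),
]


def variance_components() -> pd.DataFrame:
    """The published estimates as a DataFrame (one row per trait x analysis)."""
    return pd.DataFrame(_ROWS, columns=_COLS)


def budget_inputs() -> dict:
    """Worked cost-example inputs: 265 hybrids x 8 trials x 3 replications at
    $17.00 per plot; 188 lines + 2 testers at $25.38 each; 25% of plots
    replaced by prediction."""
    return {
        "n_hybrids": 265, "n_trials": 8, "n_reps": 3, "cost_per_plot": 17.00,
        "n_lines": 190, "cost_per_line": 25.38, "savings_fraction": 0.25,
    }
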