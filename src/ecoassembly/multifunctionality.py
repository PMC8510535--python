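"""Ecosystem multifunctionality (EMF) by the averaging approach.

Each measured function is z-score standardised across samples (sample
standard deviation, n-1 denominator) and the per-sample EMF is the mean of
the standardised functions.  Because z-scores centre every function, the
grand mean of EMF over samples is exactly 0; treatment effects are
therefore best read as differences from the control mean.  The
ratio-based fold change is reported too, but a ratio of near-zero
z-score means is numerically and directionally unstable (a more negative
treatment over a negative control yields a fold change > 1), so the
difference metric is always co-reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

FUNCTION_CATEGORIES = {
    "plant_production": ["lettuce_yield"],
    "soil_conditions": ["soil_pH"],
    "nutrient_cycling": [
        "TC", "TN", "CN_ratio", "PAO", "urease", "phosphatase",
        "nitrification_genes", "denitrification_genes",
        "P_cycling_genes", "S_cycling_genes",
    ],
    "organic_matter_turnover": [
        "SBR", "beta_glucosidase", "beta_cellobiosidase",
        "N_acetyl_glucosaminidase", "C_fixation_genes", "C_degradation_genes",
    ],
}

DEFAULT_FUNCTIONS = [f for fs in FUNCTION_CATEGORIES.values() for f in fs]

__all__ = [
    "FUNCTION_CATEGORIES",
    "DEFAULT_FUNCTIONS",
    "zscore_functions",
    "emf",
    "emf_fold_change",
]


def zscore_functions(functions: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sd 1 with n-1 denominator)."""
    if functions.isna().any().any():
        raise ValueError("missing cells in function table (no imputation)")
    if functions.shape[0] < 2:
        raise ValueError("z-score needs at least 2 samples")
    sd = functions.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant function column(s): {constant}")
    return (functions - functions.mean(axis=0)) / sd


def emf(z: pd.DataFrame) -> pd.Series:
    """Per-sample multifunctionality index: mean of z-scored functions."""
    if z.shape[1] < 1:
        raise ValueError("need at least one function")
    if z.isna().any().any():
        raise ValueError("missing cells in z-matrix")
    out = z.mean(axis=1)
    assert abs(out.mean()) < 1e-10, "EMF grand mean must be 0"
    return out.rename("EMF")


def emf_fold_change(
    emf_values: pd.Series,
    meta: pd.DataFrame,
    control_label: str,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Per-treatment EMF relative to control: ratio and difference.

    ``fold_change`` = mean(EMF_treatment) / mean(EMF_control); suppressed
    (NaN, with a warning) when |control mean| < ``epsilon``.  The
    ``difference`` column (mean difference in EMF units) is always
    reported and is the recommended effect measure for a centred index.
    """
    treatments = meta["treatment"]
    if control_label not in set(treatments):
        raise ValueError(f"unknown control label: {control_label!r}")
    control_ids = treatments.index[treatments == control_label]
    control_mean = float(emf_values.loc[control_ids].mean())
    suppress = abs(control_mean) < epsilon
    if suppress:
        warnings.warn(
            "control EMF mean is within epsilon of 0; fold-change ratios "
            "suppressed, use the difference column",
            stacklevel=2,
        )
    rows = []
    for treat in sorted(set(treatments) - {control_label}):
        ids = treatments.index[treatments == treat]
        vals = emf_values.loc[ids]
        mean = float(vals.mean())
        rows.append(
            {
                "treatment": treat,
                "mean_emf": mean,
                "fold_change": np.nan if suppress else mean / control_mean,
                "difference": mean - control_mean,
                "sd_emf": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    out = pd.DataFrame(rows).set_index("treatment")
    out.attrs["control_mean"] = control_mean
    return out
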