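"""Published reference statistics from the potato-farm case study.

The method was developed on four seasons (2015-2018) of tuber-growth
sampling on a Dutch potato farm.  The published top-5 subgroup tables
report, for each mined subgroup, the quality phi, the target mean and sd of
the empirical-Bayes random effect, and the member count; soil thresholds
are in kg/ha (N, P, K, Ca, Mg, S) or g/ha (B, Fe, Mn, Zn).  These rows are
used as a consistency benchmark: the quality must recompute from the
printed (mean, sd, n) through t = mean * sqrt(n) / sd up to the 2-decimal
rounding of the inputs.
"""

from __future__ import annotations

import math

import pandas as pd

# (target, direction, description, quality, mean, sd, n)
_TOP5_ROWS = [
    ("a", "high", "B_soil >1113.6 ∧ K_soil >165.5", 4.53, 0.42, 0.45, 24),
    ("a", "high", "Ca_soil >196.8 ∧ Zn_soil ≤2055.6", 4.25, 0.50, 0.52, 19),
    ("a", "high", "K_soil >308.1 ∧ Zn_soil ≤2082.0", 3.83, 0.39, 0.51, 25),
    ("a", "high", "Fe_soil >324.0 ∧ Fe_soil ≤444.0", 3.66, 0.30, 0.56, 47),
    ("a", "high", "B_soil ≤366.0 ∧ Dryness = wet", 3.54, 0.34, 0.48, 26),
    ("a", "low", "Dryness = average ∧ Zn_soil >6868.8 ∧ Zn_soil ≤11569.2", 4.83, -0.79, 0.64, 15),
    ("a", "low", "S_soil ≤22.8 ∧ Dryness ≠ wet ∧ Fe_soil >446.4", 4.66, -0.52, 0.58, 27),
    ("a", "low", "K_soil ≤308.1 ∧ Dryness ≠ wet ∧ Nutrient_content = poor", 4.62, -0.60, 0.65, 25),
    ("a", "low", "N_soil ≤138.2 ∧ Dryness ≠ wet ∧ Nutrient_content = poor", 4.58, -0.66, 0.66, 21),
    ("a", "low", "Mn_soil >9234.0 ∧ K_soil ≤375.3", 4.48, -0.48, 0.67, 38),
    ("b", "high", "B_soil >564.0 ∧ N_soil >174.2 ∧ K_soil ≤183.1", 5.18, 0.66, 0.55, 19),
    ("b", "high", "S_soil >11.4 ∧ Dryness = average ∧ K_soil ≤166.2", 5.15, 0.53, 0.63, 37),
    ("b", "high", "Dryness = average ∧ S_soil >10.0 ∧ K_soil ≤166.7", 4.84, 0.51, 0.64, 38),
    ("b", "high", "K_soil ≤146.1 ∧ Dryness = average ∧ N_soil >101.6", 4.62, 0.50, 0.51, 22),
    ("b", "high", "Dryness = average ∧ K_soil ≤274.7 ∧ B_soil >453.6", 4.58, 0.51, 0.69, 39),
    ("b", "low", "B_soil ≤564.0 ∧ Dryness = wet", 3.43, -0.34, 0.66, 43),
    ("b", "low", "Dryness = wet ∧ N_soil ≤89.8", 3.00, -0.30, 0.59, 35),
    ("b", "low", "Dryness = wet ∧ B_soil ≤750.0", 2.99, -0.27, 0.65, 52),
    ("b", "low", "Ca_soil >196.8 ∧ Zn_soil ≤2055.6", 2.81, -0.35, 0.55, 19),
    ("b", "low", "Dryness = wet ∧ Zn_soil ≤1290.0", 2.79, -0.45, 0.68, 18),
    ("c", "high", "Fe_soil >324.0 ∧ P_soil >6.0", 3.43, 0.32, 0.44, 22),
    ("c", "high", "Zn_soil >7294.8 ∧ B_soil ≤592.8", 3.33, 0.26, 0.47, 36),
    ("c", "high", "K_soil ≤146.1 ∧ Ca_soil >14.7", 3.01, 0.37, 0.53, 18),
    ("c", "high", "Mn_soil >1454.4 ∧ Mg_soil ≤141.5", 2.93, 0.28, 0.58, 36),
    ("c", "high", "Zn_soil >3906.0 ∧ Mg_soil ≤133.2", 2.77, 0.27, 0.47, 24),
    ("c", "low", "N_soil >40.2 ∧ K_soil ≤234.0", 3.81, -0.21, 0.67, 146),
    ("c", "low", "N_soil >40.2 ∧ Mg_soil >202.2", 3.71, -0.21, 0.68, 141),
    ("c", "low", "Zn_soil ≤3906.0 ∧ Mg_soil >228.0", 3.56, -0.24, 0.68, 104),
    ("c", "low", "Fe_soil ≤324.0 ∧ K_soil ≤216.3", 3.54, -0.24, 0.70, 109),
    ("c", "low", "K_soil ≤146.1 ∧ B_soil >1405.2", 3.38, -0.62, 0.90, 24),
]


def published_subgroup_stats() -> pd.DataFrame:
    """Top-5 subgroup statistics per target and direction (30 rows)."""
    return pd.DataFrame(
        _TOP5_ROWS,
        columns=["target", "direction", "description", "quality", "mean", "sd", "n"],
    )


def published_correlations() -> dict[str, float]:
    """Random-effect correlation estimates of the case-study fit.

    The published a-c entry carries a sign typo (the triple as printed is
    not positive definite and the accompanying text calls the a-c
    correlation weakly *positive*); the magnitudes are returned as printed
    and ``rho_ac`` with the positive sign required for a valid correlation
    matrix.
    """
    return {"rho_ab": -0.65, "rho_ac": 0.49, "rho_bc": -0.73}


def published_r_squared() -> float:
    """R^2 of the case-study growth-curve fit (observed vs predicted)."""
    return 0.92


def t_consistency_errors() -> pd.Series:
    """|recomputed t| - |printed quality| per published row.

    Recomputes t = mean * sqrt(n) / sd from the rounded printed inputs and
    returns the absolute difference from the printed (always positive)
    quality.  Small values confirm the quality measure's definition.
    """
    df = published_subgroup_stats()
    recomputed = (
        df["mean"].abs() * df["n"].pow(0.5) / df["sd"]
    )
    return (recomputed - df["quality"]).abs()


def t_consistency_max_error() -> float:
    """Largest recomputation error across all published rows."""
    return float(t_consistency_errors().max())
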