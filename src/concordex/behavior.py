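"""Behavioral composites: emotionality z-scores and normalized behavioral score.

Every behavioral variable is z-scored against the comparison's control group
and multiplied by a direction sign chosen so that larger z means more
anxiety/depression-like behavior (e.g. less time in the light compartment,
longer grooming latency).  The emotionality composite averages directional
z within each behavioral test, then across tests, weighting the tests
equally.  A second, normalized "behavioral score" rescales the composite so
that the cohort's least-emotional animal scores 1 and an animal at the mean
of the controls scores 0: with z shifted by the cohort minimum and a-bar
the mean shifted z of the controls, score = 1 - z / a-bar.

The social-defeat phenotype is classified from the social-interaction
ratio (time near the aggressor's enclosure with the aggressor present over
absent): ratio > 1 is resilient (RES), otherwise susceptible (SUS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BehaviorTable, DIRECTIONS

__all__ = [
    "zscore_vs_control",
    "score_emotionality",
    "emotionality_score",
    "behavioral_score",
    "classify_si",
    "cohort_proportions",
    "CohortProportions",
]


def zscore_vs_control(
    x, control_mean: float, control_sd: float, direction: int = 1
):
    """Directional control-referenced z: ((x - mean) / sd) * direction."""
    if control_sd <= 0:
        raise ValueError("control sd must be positive")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    return (np.asarray(x, dtype=float) - control_mean) / control_sd * direction


def score_emotionality(
    table: BehaviorTable, control_group: str, variables: list[str] | None = None
) -> pd.DataFrame:
    """Directional z per variable plus the emotionality composite per animal.

    Returns a frame indexed by animal with one ``z_<variable>`` column per
    scored variable and an ``emotionality`` column: the mean directional z
    within each behavioral test, averaged across tests with equal weight.
    The reference mean and SD come from ``control_group``.
    """
    data = table.data
    if control_group not in set(data["group"]):
        raise ValueError(f"control group {control_group!r} not present")
    variables = variables or table.variables
    ctrl = data[data["group"] == control_group]
    out = pd.DataFrame(index=data.index)
    out["group"] = data["group"]
    per_test: dict[str, list[str]] = {}
    for var in variables:
        mu = float(ctrl[var].mean())
        sd = float(ctrl[var].std(ddof=1))
        direction = table.directions.get(var, DIRECTIONS.get(var, 1))
        out[f"z_{var}"] = zscore_vs_control(data[var], mu, sd, direction)
        per_test.setdefault(table.tests[var], []).append(f"z_{var}")
    test_means = pd.DataFrame(
        {t: out[cols].mean(axis=1) for t, cols in per_test.items()}
    )
    out["emotionality"] = test_means.mean(axis=1)
    return out


def emotionality_score(table: BehaviorTable, control_group: str) -> pd.Series:
    """Per-animal emotionality composite (see :func:`score_emotionality`)."""
    return score_emotionality(table, control_group)["emotionality"]


def behavioral_score(
    table: BehaviorTable,
    test_group: str,
    control_group: str,
    normalization: str = "subtract",
) -> pd.DataFrame:
    """Normalized behavioral score 1 - z/a-bar for one comparison.

    The cohort is the union of the test and control animals.  Emotionality
    z is computed against the control group, normalized to the lowest z of
    the cohort (by subtracting the minimum; ``normalization="divide"``
    additionally rescales by the minimum's magnitude, the other reading of
    normalizing "to the lowest z"), and a-bar is the mean normalized z of
    the controls.  An animal at the cohort minimum scores exactly 1 and an
    animal at the control mean scores exactly 0; the score decreases
    strictly with emotionality.
    """
    scored = score_emotionality(table, control_group)
    cohort = scored[scored["group"].isin({test_group, control_group})].copy()
    z = cohort["emotionality"]
    z_min = float(z.min())
    if normalization == "subtract":
        z_norm = z - z_min
    elif normalization == "divide":
        if z_min == 0:
            raise ValueError("cannot rescale by a zero minimum z")
        z_norm = (z - z_min) / abs(z_min)
    else:
        raise ValueError("normalization must be 'subtract' or 'divide'")
    abar = float(z_norm[cohort["group"] == control_group].mean())
    if abar == 0:
        raise ValueError("degenerate control spread: a-bar is zero")
    cohort["z_norm"] = z_norm
    cohort["score"] = 1.0 - z_norm / abar
    return cohort[["group", "emotionality", "z_norm", "score"]]


def classify_si(si_ratio) -> np.ndarray | str:
    """Phenotype from the SI ratio: > 1 -> "RES", otherwise "SUS"."""
    arr = np.asarray(si_ratio, dtype=float)
    if np.any(arr < 0):
        raise ValueError("SI ratio must be non-negative")
    res = np.where(arr > 1.0, "RES", "SUS")
    return res.item() if np.isscalar(si_ratio) or arr.ndim == 0 else res


@dataclass
class CohortProportions:
    counts: pd.DataFrame  # phenotype x housing
    percentages: pd.DataFrame  # full precision, % of grand total
    rounded: pd.DataFrame  # nearest-integer display percentages
    fisher_p: float
    odds_ratio: float


def cohort_proportions(counts: pd.DataFrame) -> CohortProportions:
    """Cell percentages of the grand total plus a two-sided Fisher test.

    ``counts`` is a 2x2 phenotype x housing table of animal counts.  Each
    cell is reported as a percentage of all animals (full precision and
    rounded to the nearest integer for display), with a two-sided Fisher
    exact test of phenotype-by-housing association.
    """
    c = counts.to_numpy(dtype=float)
    if c.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(c < 0) or np.any(c != np.round(c)):
        raise ValueError("counts must be non-negative integers")
    total = c.sum()
    pct = counts / total * 100.0
    odds, p = stats.fisher_exact(c.astype(int), alternative="two-sided")
    return CohortProportions(
        counts=counts.copy(),
        percentages=pct,
        rounded=pct.round(0).astype(int),
        fisher_p=float(p),
        odds_ratio=float(odds),
    )
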