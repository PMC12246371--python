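"""Descriptive SRET tables and the paired one-tailed proportion tests."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS, VALENCES

__all__ = [
    "proportion_table",
    "per_participant_proportions",
    "paired_t_one_tailed",
    "difference_histogram",
]


def _round1(x: float) -> float:
    """Round half-up to one decimal (table formatting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def proportion_table(data: pd.DataFrame) -> pd.DataFrame:
    """Counts, percentages and RT mean(SD) per condition x valence x response.

    Response types are "endorse" (response 0) and "reject" (response 1);
    percentages are within each (condition, valence) cell, rounded half-up
    to one decimal place.  Empty cells report zero counts.
    """
    rows = []
    for cond in CONDITIONS:
        for val in VALENCES:
            cell = data[(data["condition"] == cond) & (data["valence"] == val)]
            total = len(cell)
            for resp_type, code in (("endorse", 0), ("reject", 1)):
                sub = cell[cell["response"] == code]
                n = len(sub)
                pct = _round1(100.0 * n / total) if total else 0.0
                rows.append(
                    {
                        "condition": cond,
                        "valence": val,
                        "response_type": resp_type,
                        "n_trials": n,
                        "percent": pct,
                        "rt_mean": float(sub["rt"].mean()) if n else np.nan,
                        "rt_sd": float(sub["rt"].std(ddof=1)) if n > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def per_participant_proportions(
    data: pd.DataFrame, valence: str, response_type: str
) -> pd.DataFrame:
    """Per-participant proportion of one response type, by condition.

    ``response_type`` is "endorse" or "reject".  Participants missing a
    condition entirely get NaN for that condition (flagged in the output).
    """
    if valence not in VALENCES:
        raise ValueError(f"unknown valence {valence!r}")
    if response_type not in ("endorse", "reject"):
        raise ValueError("response_type must be 'endorse' or 'reject'")
    sub = data[data["valence"] == valence]
    if len(sub) == 0:
        raise ValueError(f"no {valence} trials in the data")
    code = 1 if response_type == "reject" else 0
    pivot = (
        sub.assign(hit=(sub["response"] == code).astype(float))
        .groupby(["participant_id", "condition"], observed=True)["hit"]
        .mean()
        .unstack("condition")
    )
    for cond in CONDITIONS:
        if cond not in pivot.columns:
            pivot[cond] = np.nan
    pivot = pivot[list(CONDITIONS)]
    pivot["complete"] = pivot.notna().all(axis=1)
    return pivot.reset_index()


def paired_t_one_tailed(x, y, direction: str = "greater"):
    """Paired t-test with a one-sided alternative.

    ``direction="greater"`` tests mean(x) > mean(y).  Returns (t, df, p).
    Zero variance of the paired differences has no t statistic and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            # identical vectors: t = 0 by convention, p = 0.5
            return 0.0, x.size - 1, 0.5
        raise ValueError("paired differences have zero variance")
    res = stats.ttest_rel(x, y, alternative=direction)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def difference_histogram(x, y, bins: int = 10) -> pd.DataFrame:
    """Histogram of paired differences, for visual normality inspection.

    Returns bin edges and counts as a tidy table (no test statistic is
    computed; the distributional check is left to the eye).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    counts, edges = np.histogram(d, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
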