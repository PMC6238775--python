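"""Dominance-display rates and the rank-manipulation contrast.

Males housed alone with females ("perceived dominance", PD) are expected
to behave like dominants; the check compares each male's hourly rate of
two display behaviours (crowing; female-directed lateral struts) between
the multi-male social group (SG) and the PD condition with a paired
Wilcoxon signed-rank test.

Crow rates are used as-is. Lateral-strut rates are adjusted for female
density (rate / number of females housed with the male) because the two
conditions differ enormously in available display targets; only struts
clearly directed at females enter the analysis, so the measure is
comparable across conditions.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .stats import WilcoxonResult, wilcoxon_signed_rank


@dataclasses.dataclass
class ContrastResult:
    """Per-male increases (PD - SG) and the paired signed-rank test."""

    increases: pd.Series  # indexed by individual
    test: WilcoxonResult
    n_positive: int
    n_zero: int
    n_negative: int
    excluded: list[str]


def compute_rates(observations: pd.DataFrame) -> pd.DataFrame:
    """Events per hour for each (individual, condition, behaviour).

    Counts are summed over observation records before dividing by total
    hours, so splitting a watch into several records cannot change the
    rate. Lateral-strut records not clearly directed at females are
    excluded; crows have no receiver and are always kept.
    """
    obs = observations.copy()
    if "directed" in obs.columns:
        keep = (obs["behaviour"] != "lateral_strut") | (obs["directed"] == "female")
        obs = obs[keep]
    if (obs["hours"] <= 0).any():
        raise ValueError("non-positive observation hours")
    grouped = obs.groupby(["individual", "condition", "behaviour"], sort=True).agg(
        events=("events", "sum"),
        hours=("hours", "sum"),
        n_females=("n_females", "first"),
    )
    if (grouped["hours"] <= 0).any():
        raise ValueError("zero total hours for a cell")
    grouped["rate"] = grouped["events"] / grouped["hours"]
    return grouped.reset_index()


def adjust_for_female_density(rate, n_females):
    """Display rate per available female: rate / n_females."""
    n = np.asarray(n_females, float)
    if np.any(n < 1):
        raise ValueError("n_females must be >= 1")
    return np.asarray(rate, float) / n


def rate_summary(observations: pd.DataFrame) -> pd.DataFrame:
    """Wide per-male summary: SG rate, PD rate and increase per behaviour.

    Lateral struts are female-density adjusted in both conditions; crows
    are not. Columns: individual, behaviour, sg_rate, pd_rate, increase,
    adjusted.
    """
    rates = compute_rates(observations)
    rates = rates.copy()
    adjusted = rates["behaviour"] == "lateral_strut"
    rates.loc[adjusted, "rate"] = adjust_for_female_density(
        rates.loc[adjusted, "rate"], rates.loc[adjusted, "n_females"]
    )
    wide = rates.pivot_table(
        index=["individual", "behaviour"], columns="condition", values="rate"
    ).reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={"SG": "sg_rate", "PD": "pd_rate"})
    for col in ("sg_rate", "pd_rate"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide["increase"] = wide["pd_rate"] - wide["sg_rate"]
    wide["adjusted"] = wide["behaviour"] == "lateral_strut"
    return wide


def condition_contrast(summary: pd.DataFrame, behaviour: str) -> ContrastResult:
    """Paired SG-vs-PD contrast for one behaviour.

    ``summary`` is a :func:`rate_summary`-shaped table (or any frame
    with individual, behaviour, sg_rate, pd_rate). Individuals missing
    either condition are excluded with a warning.
    """
    sub = summary[summary["behaviour"] == behaviour].copy()
    if sub.empty:
        raise ValueError(f"no rows for behaviour {behaviour!r}")
    missing = sub["sg_rate"].isna() | sub["pd_rate"].isna()
    excluded = sub.loc[missing, "individual"].tolist()
    if excluded:
        warnings.warn(f"excluding individuals missing a condition: {excluded}")
        sub = sub[~missing]
    inc = (sub["pd_rate"] - sub["sg_rate"]).astype(float)
    inc.index = sub["individual"].to_numpy()
    test = wilcoxon_signed_rank(inc.to_numpy())
    return ContrastResult(
        increases=inc,
        test=test,
        n_positive=int((inc > 0).sum()),
        n_zero=int((inc == 0).sum()),
        n_negative=int((inc < 0).sum()),
        excluded=excluded,
    )
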