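"""Baseline descriptive table, grouped by baseline frailty state."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import STATE_LABELS, TRANSIENT_STATES
from .panel import PanelDataset

_CATEGORY_LEVELS = {
    "male": {0: "female", 1: "male"},
    "education": {0: "below_middle_school", 1: "middle_school",
                  2: "high_school_or_above"},
    "married": {0: "other_marital_status", 1: "married_or_partnered"},
    "urban": {0: "rural", 1: "urban"},
    "ever_smoker": {0: "never_smoker", 1: "ever_smoker"},
    "ever_drinker": {0: "never_drinker", 1: "ever_drinker"},
}


def percentage(count: int, total: int) -> float:
    """Share of a group as a percentage (NaN for an empty group)."""
    return 100.0 * count / total if total else np.nan


def baseline_states(data: PanelDataset) -> pd.Series:
    """Each subject's state at their first observation."""
    first = data.observations.groupby("subject_id", sort=True).first()
    return first["state"]


def descriptive_table(data: PanelDataset) -> pd.DataFrame:
    """Counts, percentages and age summaries, overall and per baseline state.

    Mirrors the conventional cohort Table 1 layout: one row per
    characteristic level with ``n (pct)`` per group, plus mean (SD) age.
    Group-difference tests are intentionally not computed.
    """
    states = baseline_states(data)
    groups = {"overall": states.index}
    for s in TRANSIENT_STATES:
        groups[STATE_LABELS[s]] = states.index[states == s]

    rows = [{"characteristic": "n", "level": "",
             **{g: float(len(ids)) for g, ids in groups.items()}}]
    rows.append({"characteristic": "baseline_state_pct", "level": "",
                 **{g: percentage(len(ids), len(states))
                    for g, ids in groups.items()}})

    cov = data.covariates
    if cov is not None:
        if "age" in cov.columns:
            for stat, fn in (("age_mean", np.mean), ("age_sd", np.std)):
                rows.append({
                    "characteristic": stat, "level": "years",
                    **{g: float(fn(cov.loc[cov.index.intersection(ids),
                                           "age"].dropna()))
                       if len(ids) else np.nan
                       for g, ids in groups.items()}})
        for col, levels in _CATEGORY_LEVELS.items():
            if col not in cov.columns:
                continue
            for code, label in levels.items():
                row = {"characteristic": col, "level": label}
                for g, ids in groups.items():
                    sub = cov.loc[cov.index.intersection(ids), col].dropna()
                    row[g] = percentage(int((sub == code).sum()), len(sub))
                rows.append(row)
    return pd.DataFrame(rows)
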