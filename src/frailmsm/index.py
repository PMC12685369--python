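"""Deficit-accumulation frailty index (FI) and frailty-state assignment.

The FI is the Rockwood cumulative-deficit score: the proportion of health
deficits present out of a fixed set of 32 age-related items.  Items 1-31
are binary deficits (present = 1); item 32 is a continuous cognitive
deficit score in [0, 1] with higher values meaning poorer cognition.  Up to
3 missing items (10%) are tolerated per assessment, in which case the FI is
renormalised to the non-missing denominator; more than 3 missing items make
the FI itself missing.

States follow the conventional cutoffs: robust (FI <= 0.10),
pre-frail (0.10 < FI < 0.25), frail (FI >= 0.25).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .model import DEATH
from .panel import COVARIATE_COLUMNS, PanelDataset, PanelValidationError

N_ITEMS = 32
MAX_MISSING = 3

ROBUST_CUT = 0.10   # FI <= 0.10 -> robust
FRAIL_CUT = 0.25    # FI >= 0.25 -> frail


@dataclass(frozen=True)
class DeficitItemSpec:
    """One FI item: identifier, kind, and a human-readable deficit rule."""

    item_id: str
    kind: str                  # "binary" | "continuous_unit_interval"
    deficit_rule: str
    domain: str = ""

    def __post_init__(self):
        if self.kind not in ("binary", "continuous_unit_interval"):
            raise ValueError(f"unknown item kind {self.kind!r}")


def default_item_template() -> list[DeficitItemSpec]:
    """A documented 32-item deficit template.

    Covers the domains conventionally used when constructing an FI from
    ageing-cohort interviews: chronic conditions, activities of daily
    living (ADL), instrumental ADL, physical function, depressive symptoms,
    self-rated health, and a continuous cognitive score.  The concrete
    wording is a package default; any 32-item encoding may be supplied
    instead via :func:`load_item_specs`.
    """
    binary = lambda iid, rule, dom: DeficitItemSpec(iid, "binary", rule, dom)
    items = [
        binary("hypertension", "ever diagnosed with hypertension", "chronic disease"),
        binary("diabetes", "ever diagnosed with diabetes or high blood sugar", "chronic disease"),
        binary("cancer", "ever diagnosed with cancer or malignant tumour", "chronic disease"),
        binary("lung_disease", "ever diagnosed with chronic lung disease", "chronic disease"),
        binary("liver_disease", "ever diagnosed with liver disease", "chronic disease"),
        binary("heart_disease", "ever diagnosed with heart problems", "chronic disease"),
        binary("stroke", "ever diagnosed with stroke", "chronic disease"),
        binary("kidney_disease", "ever diagnosed with kidney disease", "chronic disease"),
        binary("digestive_disease", "ever diagnosed with stomach or digestive disease", "chronic disease"),
        binary("psychiatric_problem", "ever diagnosed with emotional or psychiatric problems", "chronic disease"),
        binary("memory_disease", "ever diagnosed with memory-related disease", "chronic disease"),
        binary("arthritis", "ever diagnosed with arthritis or rheumatism", "chronic disease"),
        binary("dyslipidemia", "ever diagnosed with dyslipidemia", "chronic disease"),
        binary("asthma", "ever diagnosed with asthma", "chronic disease"),
        binary("adl_dressing", "any difficulty dressing", "ADL"),
        binary("adl_bathing", "any difficulty bathing or showering", "ADL"),
        binary("adl_eating", "any difficulty eating", "ADL"),
        binary("adl_bed", "any difficulty getting into or out of bed", "ADL"),
        binary("adl_toilet", "any difficulty using the toilet", "ADL"),
        binary("adl_continence", "any difficulty controlling urination/defecation", "ADL"),
        binary("iadl_housework", "any difficulty doing household chores", "IADL"),
        binary("iadl_cooking", "any difficulty preparing hot meals", "IADL"),
        binary("iadl_shopping", "any difficulty shopping for groceries", "IADL"),
        binary("iadl_money", "any difficulty managing money", "IADL"),
        binary("iadl_medication", "any difficulty taking medications", "IADL"),
        binary("func_walk_100m", "any difficulty walking 100 metres", "physical function"),
        binary("func_climb", "any difficulty climbing a flight of stairs", "physical function"),
        binary("func_stoop", "any difficulty stooping, kneeling or crouching", "physical function"),
        binary("func_lift_5kg", "any difficulty lifting or carrying 5 kg", "physical function"),
        binary("depressive_symptoms", "CES-D 10 score at or above 10", "mental health"),
        binary("poor_self_rated_health", "self-rated health poor or very poor", "self-rated health"),
        DeficitItemSpec("cognitive_score",
                        "continuous_unit_interval",
                        "1 - (cognition test score / maximum score); "
                        "higher values indicate poorer cognition",
                        "cognition"),
    ]
    assert len(items) == N_ITEMS
    return items


def save_item_specs(items: list[DeficitItemSpec], path) -> None:
    payload = [asdict(i) for i in items]
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=2)


def load_item_specs(path) -> list[DeficitItemSpec]:
    path = str(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) \
            else json.load(fh)
    items = [DeficitItemSpec(**d) for d in payload]
    if len(items) != N_ITEMS:
        raise ValueError(f"item template must contain exactly {N_ITEMS} items, "
                         f"got {len(items)}")
    return items


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def compute_fi(item_values) -> float:
    """FI from a vector of 32 deficit values, NaN marking missing items.

    Returns the sum of non-missing deficit values divided by the count of
    non-missing items; NaN when more than 3 items are missing.  Values must
    lie in [0, 1].
    """
    v = np.asarray(item_values, dtype=float)
    if v.shape != (N_ITEMS,):
        raise ValueError(f"expected exactly {N_ITEMS} item slots, got {v.shape}")
    valid = ~np.isnan(v)
    if np.any((v[valid] < 0) | (v[valid] > 1)):
        raise ValueError("deficit values must lie in [0, 1]")
    n_missing = N_ITEMS - int(valid.sum())
    if n_missing > MAX_MISSING:
        return np.nan
    return float(v[valid].sum() / valid.sum())


def compute_fi_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Vectorised FI over a frame whose 32 columns are the item values.

    Returns columns ``fi_value`` and ``n_valid_items``.
    """
    v = items.to_numpy(dtype=float)
    if v.shape[1] != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item columns, got {v.shape[1]}")
    valid = ~np.isnan(v)
    if np.nanmin(v) < 0 or np.nanmax(v) > 1:
        raise ValueError("deficit values must lie in [0, 1]")
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = np.nansum(v, axis=1) / n_valid
    fi[(N_ITEMS - n_valid) > MAX_MISSING] = np.nan
    return pd.DataFrame({"fi_value": fi, "n_valid_items": n_valid},
                        index=items.index)


def categorize_state(fi_value):
    """Frailty state from the FI: robust (<=0.10), pre-frail, frail (>=0.25).

    Accepts scalars or arrays; missing FI propagates to a missing state.
    """
    fi = np.asarray(fi_value, dtype=float)
    if np.any((fi < 0) | (fi > 1)):
        raise ValueError("fi_value must lie in [0, 1]")
    state = np.full(fi.shape, np.nan)
    state[fi <= ROBUST_CUT] = 1
    state[(fi > ROBUST_CUT) & (fi < FRAIL_CUT)] = 2
    state[fi >= FRAIL_CUT] = 3
    if np.isscalar(fi_value) or np.ndim(fi_value) == 0:
        return float(state) if np.isnan(state) else int(state)
    return state


def build_assessments(item_table: pd.DataFrame,
                      item_columns: list[str] | None = None) -> pd.DataFrame:
    """Score a long-format item table into per-subject-wave FI assessments.

    ``item_table`` must carry ``subject_id``, ``wave``, ``time`` plus the 32
    item columns (``item_columns`` or every column named ``item_*`` in
    order).  Returns ``subject_id, wave, time, fi_value, state,
    n_valid_items``.
    """
    if item_columns is None:
        item_columns = [c for c in item_table.columns if c.startswith("item_")]
    if len(item_columns) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item columns, got "
                         f"{len(item_columns)}")
    scored = compute_fi_frame(item_table[item_columns])
    out = item_table[["subject_id", "wave", "time"]].copy()
    out["fi_value"] = scored["fi_value"].to_numpy()
    out["n_valid_items"] = scored["n_valid_items"].to_numpy()
    fi = out["fi_value"].to_numpy()
    state = np.full(len(out), np.nan)
    ok = ~np.isnan(fi)
    state[ok] = categorize_state(fi[ok])
    out["state"] = state
    return out


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------

def assemble_panel(assessments: pd.DataFrame,
                   deaths: pd.DataFrame | None = None,
                   covariates: pd.DataFrame | None = None,
                   death_convention: str = "exact") -> PanelDataset:
    """Assemble scored assessments and death records into a panel dataset.

    Waves with missing FI are dropped from a subject's sequence.  Subjects
    contributing fewer than two usable observations -- counting a death
    record that completes a pair -- are excluded and tallied in the
    ``exclusions`` report.  ``deaths`` has columns ``subject_id`` and
    ``death_time``; observation times must be strictly increasing and death
    must postdate the last living observation.
    """
    required = {"subject_id", "time", "state"}
    if not required.issubset(assessments.columns):
        raise ValueError(f"assessments need columns {sorted(required)}")
    # validate time ordering in the order the waves were supplied, before
    # any sorting can mask a violation
    bad_order = []
    for sid, g in assessments.groupby("subject_id", sort=False):
        if np.any(np.diff(g["time"].to_numpy(dtype=float)) <= 0):
            bad_order.append(sid)
    a = assessments.sort_values(["subject_id", "time"], kind="stable")
    if bad_order:
        raise PanelValidationError(
            f"non-increasing assessment times for subjects {bad_order[:10]}",
            bad_order)

    death_map: dict = {}
    if deaths is not None and len(deaths):
        death_map = dict(zip(deaths["subject_id"], deaths["death_time"]))

    usable = a[~a["state"].isna()][["subject_id", "time", "state"]].copy()
    usable["state"] = usable["state"].astype(int)

    counts = usable.groupby("subject_id")["state"].size()
    all_ids = a["subject_id"].unique()

    bad_death = []
    rows = [usable]
    kept, excluded = [], []
    for sid in all_ids:
        n_obs = int(counts.get(sid, 0))
        dtime = death_map.get(sid)
        if dtime is not None and n_obs > 0:
            last = usable.loc[usable["subject_id"] == sid, "time"].max()
            if dtime <= last:
                bad_death.append(sid)
                continue
        n_usable = n_obs + (1 if dtime is not None and n_obs > 0 else 0)
        if n_usable >= 2:
            kept.append(sid)
            if dtime is not None:
                rows.append(pd.DataFrame({"subject_id": [sid],
                                          "time": [dtime],
                                          "state": [DEATH]}))
        else:
            reason = ("no_valid_assessment" if n_obs == 0
                      else "fewer_than_two_usable_observations")
            excluded.append({"subject_id": sid, "reason": reason,
                             "n_valid_assessments": n_obs})
    if bad_death:
        raise PanelValidationError(
            f"death at or before last observation for subjects {bad_death[:10]}",
            bad_death)

    obs = pd.concat(rows, ignore_index=True)
    obs = obs[obs["subject_id"].isin(kept)]
    exclusions = pd.DataFrame(excluded,
                              columns=["subject_id", "reason",
                                       "n_valid_assessments"])
    cov = None
    if covariates is not None:
        cov = covariates.loc[covariates.index.intersection(kept)]

    ds = PanelDataset(observations=obs.reset_index(drop=True), covariates=cov,
                      death_convention=death_convention,
                      exclusions=exclusions,
                      meta={"n_input_subjects": len(all_ids),
                            "n_retained": len(kept),
                            "n_excluded": len(excluded)})
    ds.validate()
    return ds


def read_long_csv(path, death_convention: str = "exact",
                  item_columns: list[str] | None = None) -> PanelDataset:
    """Read the long-format input CSV and assemble a panel dataset.

    Expected columns: ``subject_id, wave, time`` plus either ``fi_value``
    or the 32 item columns; optional ``death`` (0/1) and ``death_time``;
    optional covariate columns (see :data:`frailmsm.panel.COVARIATE_COLUMNS`).
    Missing values are empty fields.
    """
    df = pd.read_csv(path)
    if "fi_value" in df.columns:
        assessments = df[["subject_id", "wave", "time", "fi_value"]].copy()
        fi = assessments["fi_value"].to_numpy(dtype=float)
        state = np.full(len(df), np.nan)
        ok = ~np.isnan(fi)
        state[ok] = categorize_state(fi[ok])
        assessments["state"] = state
    else:
        assessments = build_assessments(df, item_columns)

    deaths = None
    if "death" in df.columns and "death_time" in df.columns:
        d = df[df["death"] == 1].drop_duplicates("subject_id")
        deaths = d[["subject_id", "death_time"]]

    covariates = None
    present = [c for c in COVARIATE_COLUMNS if c in df.columns]
    if present:
        covariates = (df.sort_values("time").groupby("subject_id")
                      .first()[present])

    return assemble_panel(assessments, deaths, covariates, death_convention)
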