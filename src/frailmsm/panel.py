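"""Panel-data container for interval-censored multi-state observations.

A :class:`PanelDataset` holds, per subject, an ordered sequence of
``(time, state)`` observations among the transient states plus an optional
terminal death record, together with baseline covariates.  Times are years
since each subject's baseline interview.  Death times may be exactly dated
(``death_convention="exact"``) or only known to lie between two waves, in
which case the recorded time is the midpoint of the bracketing interval
(``death_convention="interval"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DEATH, TRANSIENT_STATES

#: baseline covariate columns understood throughout the package.
#: ``education`` is a 3-level code: 0 below middle school (reference),
#: 1 middle school, 2 high school or above.
COVARIATE_COLUMNS = (
    "age", "male", "education", "married", "urban", "ever_smoker", "ever_drinker",
)

#: design-matrix column names derivable from the covariate table
DESIGN_COLUMNS = (
    "age", "male", "edu_middle", "edu_high", "married", "urban",
    "ever_smoker", "ever_drinker",
)


class PanelValidationError(ValueError):
    """Raised when a panel violates ordering or absorbing-state rules."""

    def __init__(self, message: str, subjects: list | None = None):
        super().__init__(message)
        self.subjects = subjects or []


@dataclass
class PanelDataset:
    """Subject-indexed state sequences with covariates and death records.

    Attributes
    ----------
    observations
        Long-format frame with columns ``subject_id``, ``time``, ``state``.
        States 1-3 are panel observations of the living process; a state-4
        row, necessarily terminal, is a death record whose interpretation
        follows ``death_convention``.
    covariates
        One row per subject (indexed by ``subject_id``) with the columns in
        :data:`COVARIATE_COLUMNS`; may be ``None`` for covariate-free data.
    death_convention
        ``"exact"`` (death time known) or ``"interval"`` (midpoint of the
        bracketing wave interval).
    exclusions
        Optional report of subjects dropped during assembly.
    """

    observations: pd.DataFrame
    covariates: pd.DataFrame | None = None
    death_convention: str = "exact"
    exclusions: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.death_convention not in ("exact", "interval"):
            raise ValueError("death_convention must be 'exact' or 'interval'")
        obs = self.observations
        required = {"subject_id", "time", "state"}
        if not required.issubset(obs.columns):
            raise ValueError(f"observations need columns {sorted(required)}")
        self.observations = obs.sort_values(["subject_id", "time"],
                                            kind="stable").reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.observations["subject_id"].nunique()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.observations["subject_id"].unique()

    def validate(self) -> None:
        """Check ordering and absorbing-state invariants; raise on violation."""
        obs = self.observations
        bad_order: list = []
        bad_death: list = []
        for sid, g in obs.groupby("subject_id", sort=False):
            t = g["time"].to_numpy(dtype=float)
            s = g["state"].to_numpy()
            if np.any(np.diff(t) <= 0):
                bad_order.append(sid)
            dead = np.flatnonzero(s == DEATH)
            if dead.size > 1 or (dead.size == 1 and dead[0] != len(s) - 1):
                bad_death.append(sid)
            if not np.all(np.isin(s, list(TRANSIENT_STATES) + [DEATH])):
                raise PanelValidationError(f"invalid state codes for subject {sid}",
                                           [sid])
        if bad_order:
            raise PanelValidationError(
                f"non-increasing observation times for subjects {bad_order[:10]}",
                bad_order)
        if bad_death:
            raise PanelValidationError(
                f"observations at or after death for subjects {bad_death[:10]}",
                bad_death)

    # -- IO ------------------------------------------------------------------

    def to_csv(self, obs_path, covariates_path=None) -> None:
        self.observations.to_csv(obs_path, index=False)
        if covariates_path is not None and self.covariates is not None:
            self.covariates.to_csv(covariates_path, index=True)

    @classmethod
    def from_csv(cls, obs_path, covariates_path=None,
                 death_convention: str = "exact") -> "PanelDataset":
        obs = pd.read_csv(obs_path)
        cov = None
        if covariates_path is not None:
            cov = pd.read_csv(covariates_path, index_col=0)
        return cls(observations=obs, covariates=cov,
                   death_convention=death_convention)


def design_matrix(covariates: pd.DataFrame, names: tuple[str, ...],
                  centers: dict[str, float] | None = None) -> np.ndarray:
    """Expand the covariate table into a design matrix.

    Education expands to two dummies against the below-middle-school
    reference; ``age_x_male`` is the centered-age x male product term.
    """
    centers = centers or {}
    cols = []
    age_c = None
    if "age" in covariates:
        age_c = covariates["age"].to_numpy(dtype=float) - centers.get("age", 0.0)
    for name in names:
        if name == "age":
            cols.append(age_c)
        elif name == "edu_middle":
            cols.append((covariates["education"].to_numpy() == 1).astype(float))
        elif name == "edu_high":
            cols.append((covariates["education"].to_numpy() == 2).astype(float))
        elif name == "age_x_male":
            cols.append(age_c * covariates["male"].to_numpy(dtype=float))
        else:
            cols.append(covariates[name].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.zeros((len(covariates), 0))
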