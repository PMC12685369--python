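"""Continuous-time Markov machinery for the four-state frailty process.

The process has three transient states -- robust (1), pre-frail (2) and
frail (3) -- and one absorbing state, death (4).  Transitions between
transient states are restricted to adjacent severities (no direct
robust <-> frail jumps); death is reachable from every transient state.
The generator is therefore

    Q = [[-(q12+q14),     q12,          0,          q14],
         [ q21,       -(q21+q23+q24),   q23,        q24],
         [ 0,              q32,     -(q32+q34),     q34],
         [ 0,               0,          0,           0 ]]

with covariates acting proportionally on each intensity,
``q_ij(z) = q0_ij * exp(beta_ij' z)``.  Transition probabilities over an
interval follow from the matrix exponential, ``P(t) = expm(t Q)``, and the
interval-censored panel likelihood is a product of such entries over
consecutive observation pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

#: state codes and labels, fixed by convention
STATE_LABELS = {1: "robust", 2: "pre_frail", 3: "frail", 4: "death"}
TRANSIENT_STATES = (1, 2, 3)
DEATH = 4
N_STATES = 4

#: ordered allowed transitions (adjacent severities plus death from anywhere)
TRANSITIONS: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 4), (2, 1), (2, 3), (2, 4), (3, 2), (3, 4),
)
N_TRANSITIONS = len(TRANSITIONS)

_ROW_IDX = np.array([i - 1 for i, _ in TRANSITIONS])
_COL_IDX = np.array([j - 1 for _, j in TRANSITIONS])


def transition_label(pair: tuple[int, int]) -> str:
    i, j = pair
    return f"{STATE_LABELS[i]}->{STATE_LABELS[j]}"


# ---------------------------------------------------------------------------
# intensity model
# ---------------------------------------------------------------------------

@dataclass
class IntensityModel:
    """Proportional-intensity model ``q_ij(z) = exp(log_q0_ij + beta_ij' z)``.

    Parameters
    ----------
    log_q0
        Baseline log-intensities, one per allowed transition, in the order
        of :data:`TRANSITIONS`.  The baseline refers to the covariate
        profile with all (centered) covariates equal to zero.
    beta
        Array of shape ``(7, n_covariates)`` of log hazard ratios; one row
        per allowed transition, one column per covariate.
    covariates
        Names of the covariate columns, in ``beta`` column order.
    centers
        Optional centering constants subtracted from covariates before the
        linear predictor is formed (age is conventionally centered so that
        the baseline intensities refer to a realistic profile).
    """

    log_q0: np.ndarray
    beta: np.ndarray = field(default_factory=lambda: np.zeros((N_TRANSITIONS, 0)))
    covariates: tuple[str, ...] = ()
    centers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.log_q0 = np.asarray(self.log_q0, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim == 1:
            self.beta = self.beta.reshape(N_TRANSITIONS, -1)
        self.covariates = tuple(self.covariates)
        if self.log_q0.shape != (N_TRANSITIONS,):
            raise ValueError(f"log_q0 must have shape ({N_TRANSITIONS},)")
        if self.beta.shape != (N_TRANSITIONS, len(self.covariates)):
            raise ValueError("beta shape inconsistent with covariate names")
        if not np.all(np.isfinite(self.log_q0)) or not np.all(np.isfinite(self.beta)):
            raise ValueError("model parameters must be finite")

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    @property
    def q0(self) -> np.ndarray:
        """Baseline intensities per allowed transition."""
        return np.exp(self.log_q0)

    # -- parameter vector packing ------------------------------------------

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.log_q0, self.beta.ravel()])

    @classmethod
    def from_theta(cls, theta: np.ndarray, covariates: Sequence[str] = (),
                   centers: Mapping[str, float] | None = None) -> "IntensityModel":
        theta = np.asarray(theta, dtype=float)
        n_cov = len(covariates)
        if theta.shape != (N_TRANSITIONS * (1 + n_cov),):
            raise ValueError("theta length inconsistent with covariate count")
        return cls(
            log_q0=theta[:N_TRANSITIONS],
            beta=theta[N_TRANSITIONS:].reshape(N_TRANSITIONS, n_cov),
            covariates=tuple(covariates),
            centers=dict(centers or {}),
        )

    @property
    def parameter_names(self) -> list[str]:
        # theta order is the log_q0 block then beta row-major (transition, cov)
        names = [f"logq[{transition_label(p)}]" for p in TRANSITIONS] + [
            f"beta[{c}][{transition_label(p)}]"
            for p in TRANSITIONS for c in self.covariates
        ]
        return names

    # -- evaluation --------------------------------------------------------

    def centered(self, z: Mapping[str, float]) -> np.ndarray:
        """Covariate vector in ``covariates`` order, centering applied.

        Derived design columns absent from ``z`` are filled in: the
        ``age_x_male`` product uses centered age, and the education dummies
        can be derived from a 3-level ``education`` code.
        """
        out = []
        for c in self.covariates:
            if c in z:
                v = float(z[c]) - self.centers.get(c, 0.0)
            elif c == "age_x_male":
                v = ((float(z["age"]) - self.centers.get("age", 0.0))
                     * float(z["male"]))
            elif c == "edu_middle":
                v = 1.0 if int(z.get("education", 0)) == 1 else 0.0
            elif c == "edu_high":
                v = 1.0 if int(z.get("education", 0)) == 2 else 0.0
            else:
                raise KeyError(f"profile is missing covariate {c!r}")
            out.append(v)
        return np.array(out)

    def intensities(self, z: Mapping[str, float] | None = None) -> np.ndarray:
        """Vector of the 7 transition intensities at covariate profile ``z``."""
        eta = self.log_q0.copy()
        if self.n_covariates:
            if z is None:
                raise ValueError("model has covariates; a profile is required")
            eta = eta + self.beta @ self.centered(z)
        return np.exp(eta)

    def intensity_matrix(self, z: Mapping[str, float] | None = None) -> np.ndarray:
        """Full 4x4 generator at covariate profile ``z``."""
        return build_intensity_matrix(self, z)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "log_q0": {transition_label(p): float(v)
                       for p, v in zip(TRANSITIONS, self.log_q0)},
            "beta": {
                c: {transition_label(p): float(self.beta[t, k])
                    for t, p in enumerate(TRANSITIONS)}
                for k, c in enumerate(self.covariates)
            },
            "covariates": list(self.covariates),
            "centers": dict(self.centers),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IntensityModel":
        covs = tuple(d.get("covariates", ()))
        log_q0 = np.array([d["log_q0"][transition_label(p)] for p in TRANSITIONS])
        beta = np.zeros((N_TRANSITIONS, len(covs)))
        for k, c in enumerate(covs):
            for t, p in enumerate(TRANSITIONS):
                beta[t, k] = d["beta"][c][transition_label(p)]
        return cls(log_q0=log_q0, beta=beta, covariates=covs,
                   centers=dict(d.get("centers", {})))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "IntensityModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def intensity_matrix_from_rates(q: np.ndarray) -> np.ndarray:
    """Assemble a 4x4 generator from the 7 allowed rates (batched on the left)."""
    q = np.asarray(q, dtype=float)
    Q = np.zeros(q.shape[:-1] + (N_STATES, N_STATES))
    Q[..., _ROW_IDX, _COL_IDX] = q
    diag = -Q.sum(axis=-1)
    idx = np.arange(N_STATES)
    Q[..., idx, idx] = diag
    return Q


def build_intensity_matrix(model: IntensityModel,
                           z: Mapping[str, float] | None = None) -> np.ndarray:
    """Generator matrix Q(z) with disallowed entries exactly zero.

    Off-diagonal allowed entries are ``q0_ij * exp(beta_ij' z)``; the
    diagonal is set so every row sums to zero and the death row is zero.
    """
    return intensity_matrix_from_rates(model.intensities(z))


def validate_generator(Q: np.ndarray, atol: float = 1e-10) -> None:
    Q = np.asarray(Q)
    if Q.shape[-2:] != (N_STATES, N_STATES):
        raise ValueError("generator must be 4x4")
    off = Q.copy()
    idx = np.arange(N_STATES)
    off[..., idx, idx] = 0.0
    if np.any(off < -atol):
        raise ValueError("off-diagonal intensities must be non-negative")
    if np.any(np.abs(Q.sum(axis=-1)) > atol):
        raise ValueError("generator rows must sum to zero")
    if np.any(np.abs(Q[..., DEATH - 1, :]) > atol):
        raise ValueError("death must be absorbing (zero row)")


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Interval transition-probability matrix ``P(t) = expm(t Q)``.

    Computed by scaling-and-squaring with Pade approximation (scipy's
    ``expm``); accepts a stacked batch of generators.  ``t`` must be
    non-negative; ``P(0)`` is the identity.
    """
    if t < 0:
        raise ValueError("time interval must be non-negative")
    Q = np.asarray(Q, dtype=float)
    if t == 0:
        return np.broadcast_to(np.eye(N_STATES), Q.shape).copy()
    return expm(t * Q)


def transition_probabilities(Q: np.ndarray, times: np.ndarray) -> np.ndarray:
    """``P(t)`` for a single generator at a vector of times (batched expm)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("time intervals must be non-negative")
    A = times[:, None, None] * np.asarray(Q, dtype=float)
    return expm(A)
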