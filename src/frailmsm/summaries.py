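"""Derived summaries of a fitted frailty transition model.

* interval transition probabilities P(t) at requested horizons,
* mean sojourn time per transient state (reciprocal total exit intensity),
* expected total length of stay per state over a horizon (the integral of
  the occupancy probability), with proportions of time alive.

Confidence intervals for derived scalars use the delta method on the log
scale, propagating the fitted covariance through a numerical gradient.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    DEATH,
    N_STATES,
    STATE_LABELS,
    TRANSIENT_STATES,
    IntensityModel,
    transition_probability,
    transition_probabilities,
    validate_generator,
)
from .fit import FittedMSM

_Z95 = 1.959963984540054
_STATE_NAMES = [STATE_LABELS[i] for i in range(1, N_STATES + 1)]


# ---------------------------------------------------------------------------
# mean sojourn time
# ---------------------------------------------------------------------------

def mean_sojourn_time(Q: np.ndarray, state: int) -> float:
    """Expected single-stay duration in a transient state, in years.

    Holding times in a continuous-time Markov chain are exponential with
    rate equal to the total exit intensity, so the mean sojourn time in
    state i is ``1 / sum_{j != i} q_ij``.  A zero exit rate yields ``inf``.
    """
    if state not in TRANSIENT_STATES:
        raise ValueError("sojourn time is defined for transient states 1-3")
    Q = np.asarray(Q, dtype=float)
    exit_rate = -Q[state - 1, state - 1]
    if exit_rate <= 0:
        return np.inf
    return 1.0 / exit_rate


def sojourn_table(fit: FittedMSM,
                  profile: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Mean sojourn times with delta-method 95% CIs at a covariate profile."""
    Q = fit.model.intensity_matrix(profile)
    rows = []
    for i in TRANSIENT_STATES:
        value = mean_sojourn_time(Q, i)
        lo = hi = np.nan
        if fit.covariance is not None and np.isfinite(value):
            se_log = _delta_se_log(
                fit, lambda m: mean_sojourn_time(m.intensity_matrix(profile), i))
            lo = value * np.exp(-_Z95 * se_log)
            hi = value * np.exp(_Z95 * se_log)
        rows.append({"state": STATE_LABELS[i], "mean_sojourn_years": value,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _delta_se_log(fit: FittedMSM, func, h: float = 1e-5) -> float:
    """SE of log f(model) by numerical gradient through the covariance."""
    theta = fit.theta
    model = fit.model
    grad = np.zeros(theta.size)
    for k in range(theta.size):
        step = h * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += step
        tm = theta.copy(); tm[k] -= step
        fp = func(IntensityModel.from_theta(tp, model.covariates, model.centers))
        fm = func(IntensityModel.from_theta(tm, model.covariates, model.centers))
        grad[k] = (np.log(fp) - np.log(fm)) / (2 * step)
    var = float(grad @ fit.covariance @ grad)
    return np.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# total length of stay
# ---------------------------------------------------------------------------

def total_length_of_stay(Q: np.ndarray, horizon: float, start: int = 1,
                         step: float = 0.05, tol: float = 1e-6,
                         max_halvings: int = 8) -> dict:
    """Expected years spent in each state over [0, horizon] from ``start``.

    ``L_i = integral_0^T P(t)[start, i] dt`` evaluated by composite Simpson
    quadrature on a uniform grid (initial step 0.05 y), halving the step
    until successive estimates agree within ``tol``.  Proportions are
    relative to the expected time alive, ``L_i / sum_{j transient} L_j``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    validate_generator(Q)

    def _simpson(n_half: int) -> np.ndarray:
        n = 2 * n_half
        ts = np.linspace(0.0, horizon, n + 1)
        P = transition_probabilities(Q, ts)            # (n+1, 4, 4)
        f = P[:, start - 1, :]                         # occupancy rows
        wts = np.ones(n + 1)
        wts[1:-1:2] = 4.0
        wts[2:-1:2] = 2.0
        return (horizon / n / 3.0) * (wts @ f)

    n_half = max(1, int(np.ceil(horizon / step / 2.0)))
    est = _simpson(n_half)
    for _ in range(max_halvings):
        n_half *= 2
        new = _simpson(n_half)
        if np.max(np.abs(new - est)) < tol:
            est = new
            break
        est = new
    else:
        raise RuntimeError(
            f"length-of-stay quadrature did not reach tol={tol} "
            f"after {max_halvings} halvings (last change "
            f"{np.max(np.abs(new - est)):.2e})")

    occupancy = dict(zip(_STATE_NAMES, est))
    alive = sum(occupancy[STATE_LABELS[i]] for i in TRANSIENT_STATES)
    proportions = {
        STATE_LABELS[i]: occupancy[STATE_LABELS[i]] / alive if alive > 0 else np.nan
        for i in TRANSIENT_STATES
    }
    return {"years": occupancy, "proportions": proportions,
            "horizon": horizon, "start": STATE_LABELS[start]}


def length_of_stay_table(fit: FittedMSM, horizon: float = 10.0,
                         start: int = 1,
                         profile: Mapping[str, float] | None = None,
                         **kwargs) -> pd.DataFrame:
    Q = fit.model.intensity_matrix(profile)
    res = total_length_of_stay(Q, horizon, start=start, **kwargs)
    rows = [{"state": STATE_LABELS[i],
             "expected_years": res["years"][STATE_LABELS[i]],
             "proportion_of_time_alive": res["proportions"][STATE_LABELS[i]]}
            for i in TRANSIENT_STATES]
    rows.append({"state": STATE_LABELS[DEATH],
                 "expected_years": res["years"][STATE_LABELS[DEATH]],
                 "proportion_of_time_alive": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interval transition tables
# ---------------------------------------------------------------------------

def interval_transition_table(fit_or_model: FittedMSM | IntensityModel,
                              times: tuple[float, ...] = (1.0, 3.0, 5.0),
                              profile: Mapping[str, float] | None = None
                              ) -> dict[float, pd.DataFrame]:
    """Labelled 4x4 transition-probability tables at the requested horizons."""
    model = fit_or_model.model if isinstance(fit_or_model, FittedMSM) \
        else fit_or_model
    Q = model.intensity_matrix(profile)
    out = {}
    for t in times:
        P = transition_probability(Q, float(t))
        out[float(t)] = pd.DataFrame(P, index=_STATE_NAMES,
                                     columns=_STATE_NAMES)
    return out


def reference_profile(covariates: pd.DataFrame) -> dict[str, float]:
    """Cohort-mean age and modal category values, for overall summaries."""
    prof: dict[str, float] = {}
    for col in covariates.columns:
        vals = covariates[col].dropna()
        if col == "age":
            prof[col] = float(vals.mean())
        else:
            prof[col] = float(vals.mode().iloc[0])
    return prof
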