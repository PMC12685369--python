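"""Maximum-likelihood estimation of the frailty transition model.

The interval-censored likelihood is maximised over the baseline
log-intensities and per-transition covariate coefficients by L-BFGS-B with
batched central-difference gradients (all perturbed parameter vectors are
evaluated through one stacked matrix-exponential call, so a gradient costs
little more than a function value).  Standard errors come from the inverse
of the finite-difference observed information at the optimum; hazard ratios
are ``exp(beta)`` with Wald 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import (
    IntervalContext,
    build_interval_context,
    negative_log_likelihood_and_grad,
)
from .model import (
    N_TRANSITIONS,
    TRANSIENT_STATES,
    TRANSITIONS,
    IntensityModel,
    transition_label,
)
from .panel import PanelDataset

_RATE_FLOOR = 1e-3  # per year; floor for crude initial intensities

#: default age bands for stratified refits (closed on the left)
AGE_BANDS = ((45.0, 55.0), (55.0, 65.0), (65.0, np.inf))


class FitWarning(UserWarning):
    pass


@dataclass
class FittedMSM:
    """Result of a maximum-likelihood fit.

    ``covariance`` is the inverse observed information on the packed
    parameter scale (log intensities and log hazard ratios); ``None`` when
    the information matrix was singular, in which case confidence intervals
    are unavailable but point estimates remain valid.
    """

    model: IntensityModel
    log_likelihood: float
    converged: bool
    n_iter: int
    covariance: np.ndarray | None
    n_subjects: int
    n_intervals: int
    message: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def theta(self) -> np.ndarray:
        return self.model.theta

    @property
    def parameter_names(self) -> list[str]:
        return self.model.parameter_names

    def standard_errors(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def summary(self) -> pd.DataFrame:
        se = self.standard_errors()
        return pd.DataFrame({
            "parameter": self.parameter_names,
            "estimate": self.theta,
            "se": se if se is not None else np.full(len(self.theta), np.nan),
        })


# ---------------------------------------------------------------------------
# initial values
# ---------------------------------------------------------------------------

def crude_initial_values(data: PanelDataset,
                         covariates: tuple[str, ...] = (),
                         centers: dict[str, float] | None = None) -> IntensityModel:
    """Occurrence/exposure starting values.

    For each allowed transition i->j, the initial intensity is the count of
    observed adjacent-wave i->j changes divided by the total observed
    person-time spent in state i (interval lengths attributed to the state
    at the interval start), floored at 1e-3 per year.  Covariate
    coefficients start at zero.
    """
    ctx = build_interval_context(data, (), None, age_timevarying=False)
    iv = ctx.intervals
    person_time = {i: 0.0 for i in TRANSIENT_STATES}
    counts = {pair: 0.0 for pair in TRANSITIONS}
    fs = iv["from_state"].to_numpy()
    ts = iv["to_state"].to_numpy()
    dt = iv["dt"].to_numpy()
    for i in TRANSIENT_STATES:
        person_time[i] = float(dt[fs == i].sum())
    for pair in TRANSITIONS:
        counts[pair] = float(np.sum((fs == pair[0]) & (ts == pair[1])))

    q0 = np.empty(N_TRANSITIONS)
    for k, (i, j) in enumerate(TRANSITIONS):
        if person_time[i] <= 0:
            warnings.warn(
                f"state {i} never observed; exit rates floored at {_RATE_FLOOR}",
                FitWarning, stacklevel=2)
            q0[k] = _RATE_FLOOR
        else:
            q0[k] = max(counts[(i, j)] / person_time[i], _RATE_FLOOR)
    return IntensityModel(
        log_q0=np.log(q0),
        beta=np.zeros((N_TRANSITIONS, len(covariates))),
        covariates=tuple(covariates),
        centers=dict(centers or {}),
    )


# ---------------------------------------------------------------------------
# optimisation helpers
# ---------------------------------------------------------------------------

def _value_and_grad(theta: np.ndarray, ctx: IntervalContext
                    ) -> tuple[float, np.ndarray]:
    return negative_log_likelihood_and_grad(theta, ctx)


def _hessian(theta: np.ndarray, ctx: IntervalContext,
             h: float = 1e-5) -> np.ndarray:
    """Observed information by central differences of the exact gradient."""
    p = theta.size
    steps = h * np.maximum(1.0, np.abs(theta))
    H = np.zeros((p, p))
    for a in range(p):
        tp = theta.copy(); tp[a] += steps[a]
        tm = theta.copy(); tm[a] -= steps[a]
        _, gp = negative_log_likelihood_and_grad(tp, ctx)
        _, gm = negative_log_likelihood_and_grad(tm, ctx)
        H[a] = (gp - gm) / (2.0 * steps[a])
    return 0.5 * (H + H.T)


def _covariance(theta: np.ndarray, ctx: IntervalContext) -> np.ndarray | None:
    """Inverse observed information; NaN rows for non-informative parameters.

    Sparse cells can leave individual parameters with (numerically) zero
    curvature at the optimum; those rows/columns are reported as NaN while
    the informative block is inverted normally, so CIs degrade per
    parameter rather than wholesale.
    """
    H = _hessian(theta, ctx)
    d = np.diag(H)
    ok = d > max(1e-10, 1e-10 * float(d.max()))
    if not ok.any():
        return None
    sub = H[np.ix_(ok, ok)]
    try:
        inv = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(sub, hermitian=True)
    bad = np.diag(inv) <= 0
    if bad.any():
        inv[bad, :] = np.nan
        inv[:, bad] = np.nan
    cov = np.full(H.shape, np.nan)
    cov[np.ix_(ok, ok)] = 0.5 * (inv + inv.T)
    if np.all(np.isnan(np.diag(cov))):
        return None
    return cov


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_mle(data: PanelDataset,
            covariates: tuple[str, ...] = (),
            *,
            centers: dict[str, float] | None = None,
            age_timevarying: bool = True,
            initial: IntensityModel | None = None,
            compute_covariance: bool = True,
            maxiter: int = 1000,
            gtol: float = 1e-4) -> FittedMSM:
    """Fit the intensity model by maximum likelihood.

    Parameters
    ----------
    data
        Assembled panel dataset.
    covariates
        Design-column names entering every allowed transition (e.g.
        ``("age", "male", ...)``); empty for the covariate-free model.
    centers
        Centering constants (age defaults to 60 when age is included).
    age_timevarying
        If True (default), age is updated to baseline age + elapsed time at
        each interval start; if False it is fixed at baseline.
    initial
        Starting model; occurrence/exposure values are used when omitted.
    """
    centers = dict(centers or {})
    if "age" in covariates and "age" not in centers:
        centers["age"] = 60.0
    ctx = build_interval_context(data, tuple(covariates), centers,
                                 age_timevarying)
    if initial is None:
        initial = crude_initial_values(data, tuple(covariates), centers)
    theta0 = initial.theta

    with warnings.catch_warnings():
        # scipy warns on line-search stalls that BFGS recovers from
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(
            _value_and_grad, theta0, args=(ctx,), jac=True, method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
    theta = res.x
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"optimizer did not converge: {res.message}",
                      FitWarning, stacklevel=2)

    cov = _covariance(theta, ctx) if compute_covariance else None
    if compute_covariance and cov is None:
        warnings.warn("singular observed information; CIs unavailable",
                      FitWarning, stacklevel=2)

    model = IntensityModel.from_theta(theta, tuple(covariates), centers)
    return FittedMSM(
        model=model,
        log_likelihood=-float(res.fun),
        converged=converged,
        n_iter=int(res.nit),
        covariance=cov,
        n_subjects=ctx.n_subjects,
        n_intervals=ctx.n_intervals,
        message=str(res.message),
        meta={"age_timevarying": age_timevarying,
              "death_convention": data.death_convention},
    )


def fit_interaction_model(data: PanelDataset,
                          covariates: tuple[str, ...],
                          **kwargs) -> FittedMSM:
    """Fit with an added (age - center) x male product term on every transition.

    Requires ``age`` and ``male`` among the covariates; the main effects are
    retained.  Centering age (default 60) keeps the product term roughly
    orthogonal to the male main effect.
    """
    if "age" not in covariates or "male" not in covariates:
        raise ValueError("interaction model requires both age and male")
    covs = tuple(covariates) + ("age_x_male",)
    return fit_mle(data, covs, **kwargs)


def fit_stratified(data: PanelDataset,
                   covariates: tuple[str, ...] = (),
                   *,
                   age_bands: tuple[tuple[float, float], ...] | None = AGE_BANDS,
                   by_gender: bool = False,
                   min_subjects: int = 100,
                   **kwargs) -> dict[str, FittedMSM]:
    """Independent refits on baseline-defined strata.

    Age bands are closed on the left and open on the right, evaluated on
    baseline age; gender strata use the ``male`` indicator.  Strata with
    fewer than ``min_subjects`` subjects are skipped with a warning.
    """
    if data.covariates is None:
        raise ValueError("stratification requires a covariate table")
    cov = data.covariates
    strata: dict[str, pd.Index] = {}
    if age_bands and by_gender:
        for lo, hi in age_bands:
            for male, glab in ((0, "female"), (1, "male")):
                mask = (cov["age"] >= lo) & (cov["age"] < hi) & (cov["male"] == male)
                strata[f"age_{_band_label(lo, hi)}_{glab}"] = cov.index[mask]
    elif age_bands:
        for lo, hi in age_bands:
            mask = (cov["age"] >= lo) & (cov["age"] < hi)
            strata[f"age_{_band_label(lo, hi)}"] = cov.index[mask]
    elif by_gender:
        for male, glab in ((0, "female"), (1, "male")):
            strata[glab] = cov.index[cov["male"] == male]
    else:
        raise ValueError("no stratification requested")

    fits: dict[str, FittedMSM] = {}
    for label, ids in strata.items():
        if len(ids) < min_subjects:
            warnings.warn(f"stratum {label} has {len(ids)} subjects "
                          f"(< {min_subjects}); skipped", FitWarning,
                          stacklevel=2)
            continue
        obs = data.observations[data.observations["subject_id"].isin(ids)]
        sub = PanelDataset(observations=obs.copy(),
                           covariates=cov.loc[cov.index.intersection(ids)],
                           death_convention=data.death_convention)
        fits[label] = fit_mle(sub, covariates, **kwargs)
    return fits


def _band_label(lo: float, hi: float) -> str:
    return f"{lo:.0f}plus" if np.isinf(hi) else f"{lo:.0f}_{hi:.0f}"


# ---------------------------------------------------------------------------
# hazard ratios
# ---------------------------------------------------------------------------

def hazard_ratio_table(fit: FittedMSM, z: float = 1.959963984540054
                       ) -> pd.DataFrame:
    """Per-transition, per-covariate hazard ratios with Wald 95% intervals.

    ``HR = exp(beta_hat)``, ``CI = exp(beta_hat +/- 1.96 SE)``; age effects
    are per one-year increment.  When the covariance is unavailable the CI
    columns are NaN and ``ci_available`` is False.
    """
    model = fit.model
    c = model.n_covariates
    se_all = fit.standard_errors()
    rows = []
    for t, pair in enumerate(TRANSITIONS):
        for k, covname in enumerate(model.covariates):
            b = model.beta[t, k]
            idx = N_TRANSITIONS + t * c + k
            se = se_all[idx] if se_all is not None else np.nan
            rows.append({
                "transition": transition_label(pair),
                "covariate": covname,
                "hr": np.exp(b),
                "ci_low": np.exp(b - z * se) if np.isfinite(se) else np.nan,
                "ci_high": np.exp(b + z * se) if np.isfinite(se) else np.nan,
                "ci_available": bool(np.isfinite(se)),
            })
    return pd.DataFrame(rows)
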