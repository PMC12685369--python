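"""Multiple imputation by chained equations (MICE) for missing covariates.

Only baseline covariates are imputed; the frailty index handles its own
item-level missingness by renormalisation, so FI items are never imputed
here.  Continuous columns use predictive-mean matching (5 donors);
binary and categorical columns use (regularised) logistic or multinomial
sampling, with the conditional models refit on a bootstrap resample in
each cycle so that parameter uncertainty propagates into the draws.
Fits on the completed datasets are pooled with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .fit import FittedMSM, fit_mle
from .model import N_TRANSITIONS, TRANSITIONS, transition_label
from .panel import PanelDataset

_CONTINUOUS = ("age",)
_MIN_OBSERVED = 30
_Z95 = 1.959963984540054


@dataclass
class ImputationSet:
    """Completed datasets plus (optionally) per-dataset fit results."""

    datasets: list[pd.DataFrame]
    fits: list[FittedMSM] | None = None

    @property
    def m(self) -> int:
        return len(self.datasets)


def chained_impute(covariates: pd.DataFrame, m: int = 5, cycles: int = 10,
                   n_donors: int = 5,
                   rng: np.random.Generator | int | None = None
                   ) -> ImputationSet:
    """Draw ``m`` completed covariate tables by chained equations.

    Columns with no missing values are passed through untouched; a fully
    missing column is an error.  Each of the ``m`` chains runs ``cycles``
    rounds of per-column conditional draws from its own sub-seeded
    generator, so chains are independent and the whole procedure is
    reproducible given the seed.
    """
    rng = np.random.default_rng(rng)
    df = covariates.copy()
    missing_cols = [c for c in df.columns if df[c].isna().any()]
    for c in missing_cols:
        n_obs = int(df[c].notna().sum())
        if n_obs == 0:
            raise ValueError(f"column {c!r} is fully missing; cannot impute")
        if n_obs < _MIN_OBSERVED:
            raise ValueError(f"column {c!r} has only {n_obs} observed values "
                             f"(< {_MIN_OBSERVED})")
    if not missing_cols:
        return ImputationSet(datasets=[df.copy() for _ in range(m)])

    seeds = rng.integers(0, 2**31 - 1, size=m)
    datasets = [_impute_chain(df, missing_cols, cycles, n_donors,
                              np.random.default_rng(int(s)))
                for s in seeds]
    return ImputationSet(datasets=datasets)


def _impute_chain(df: pd.DataFrame, missing_cols: list[str], cycles: int,
                  n_donors: int, rng: np.random.Generator) -> pd.DataFrame:
    work = df.copy()
    masks = {c: df[c].isna().to_numpy() for c in missing_cols}
    # initial fill: random draws from the observed marginals
    for c in missing_cols:
        obs = df[c].dropna().to_numpy()
        work.loc[masks[c], c] = rng.choice(obs, size=int(masks[c].sum()))

    for _ in range(cycles):
        for c in missing_cols:
            mask = masks[c]
            predictors = [p for p in df.columns if p != c]
            X = work[predictors].to_numpy(dtype=float)
            y_obs = df.loc[~mask, c].to_numpy(dtype=float)
            X_obs, X_mis = X[~mask], X[mask]
            boot = rng.integers(0, len(y_obs), size=len(y_obs))
            if c in _CONTINUOUS:
                work.loc[mask, c] = _pmm_draw(
                    X_obs, y_obs, X_mis, boot, n_donors, rng)
            else:
                work.loc[mask, c] = _categorical_draw(
                    X_obs, y_obs, X_mis, boot, rng)
    return work


def _pmm_draw(X_obs, y_obs, X_mis, boot, n_donors, rng):
    """Predictive-mean matching: draw an observed value from the donors
    whose fitted predictions are nearest to each missing case's."""
    reg = LinearRegression().fit(X_obs[boot], y_obs[boot])
    pred_obs = reg.predict(X_obs)
    pred_mis = reg.predict(X_mis)
    out = np.empty(len(X_mis))
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    for k, p in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, p)
        lo = max(0, pos - n_donors)
        hi = min(len(sorted_pred), pos + n_donors)
        window = order[lo:hi]
        d = np.abs(pred_obs[window] - p)
        donors = window[np.argsort(d)[:n_donors]]
        out[k] = y_obs[donors[rng.integers(0, len(donors))]]
    return out


def _categorical_draw(X_obs, y_obs, X_mis, boot, rng):
    classes = np.unique(y_obs)
    if len(classes) == 1:
        return np.full(len(X_mis), classes[0])
    yb = y_obs[boot]
    if len(np.unique(yb)) < len(classes):
        yb = y_obs  # bootstrap lost a class; fall back to the full sample
        Xb = X_obs
    else:
        Xb = X_obs[boot]
    clf = LogisticRegression(max_iter=200).fit(Xb, yb)
    probs = clf.predict_proba(X_mis)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(X_mis))
    idx = (u[:, None] > cum).sum(axis=1)
    return clf.classes_[idx].astype(float)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def rubin_pool(estimates: np.ndarray, variances: np.ndarray
               ) -> dict[str, np.ndarray]:
    """Pool per-dataset estimates with Rubin's rules.

    ``estimates`` and ``variances`` have shape ``(m, p)``.  Total variance
    is the mean within-variance plus ``(1 + 1/m)`` times the between-
    imputation variance; the CI is Wald on the pooled scale.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have matching shapes")
    m = est.shape[0]
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    pooled = est.mean(axis=0)
    within = var.mean(axis=0)
    between = est.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    se = np.sqrt(total)
    return {
        "estimate": pooled,
        "variance": total,
        "se": se,
        "ci_low": pooled - _Z95 * se,
        "ci_high": pooled + _Z95 * se,
        "within": within,
        "between": between,
    }


def fit_pooled(data: PanelDataset, covariates: tuple[str, ...],
               m: int = 5, cycles: int = 10, n_donors: int = 5,
               rng: np.random.Generator | int | None = None,
               **fit_kwargs) -> tuple[dict, pd.DataFrame, ImputationSet]:
    """Impute missing covariates, refit per dataset, and pool.

    Returns the Rubin-pooled parameter summary (on the log-intensity /
    log-HR scale), a pooled hazard-ratio table, and the imputation set with
    per-dataset fits attached.
    """
    if data.covariates is None:
        raise ValueError("panel carries no covariates")
    imp = chained_impute(data.covariates, m=m, cycles=cycles,
                         n_donors=n_donors, rng=rng)
    fits = []
    for completed in imp.datasets:
        d = PanelDataset(observations=data.observations.copy(),
                         covariates=completed,
                         death_convention=data.death_convention)
        fits.append(fit_mle(d, covariates, **fit_kwargs))
    imp.fits = fits

    est = np.vstack([f.theta for f in fits])
    var = np.vstack([
        np.diag(f.covariance) if f.covariance is not None
        else np.full(len(f.theta), np.nan)
        for f in fits
    ])
    pooled = rubin_pool(est, var)
    pooled["parameter"] = fits[0].parameter_names

    c = len(covariates)
    rows = []
    for t, pair in enumerate(TRANSITIONS):
        for k, covname in enumerate(covariates):
            idx = N_TRANSITIONS + t * c + k
            b, se = pooled["estimate"][idx], pooled["se"][idx]
            rows.append({
                "transition": transition_label(pair),
                "covariate": covname,
                "hr": np.exp(b),
                "ci_low": np.exp(b - _Z95 * se),
                "ci_high": np.exp(b + _Z95 * se),
                "ci_available": bool(np.isfinite(se)),
            })
    hr = pd.DataFrame(rows)
    return pooled, hr, imp
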