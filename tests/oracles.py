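"""Independent numerical oracles used to validate the implementation.

These deliberately avoid the package's computational paths: transition
probabilities via uniformization (Poisson-subordinated discrete chain) and
via a fine-grid discrete-time approximation, and a naive per-subject
likelihood loop built on scipy's matrix exponential.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def uniformization_P(Q: np.ndarray, t: float, tol: float = 1e-14) -> np.ndarray:
    """P(t) by uniformization: exp(tQ) = sum_k pois(k; L t) M^k, M = I + Q/L."""
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    lam = max(-Q.diagonal().min(), 1e-12)
    M = np.eye(n) + Q / lam
    mu = lam * t
    out = np.zeros_like(Q)
    term = np.exp(-mu)          # pois(0)
    Mk = np.eye(n)
    acc = 0.0
    k = 0
    while acc < 1.0 - tol and k < 10000:
        out += term * Mk
        acc += term
        k += 1
        term *= mu / k
        Mk = Mk @ M
    return out


def discrete_grid_P(Q: np.ndarray, t: float, delta: float = 1e-4) -> np.ndarray:
    """P(t) ~ (I + delta Q)^(t/delta), via binary matrix powers."""
    n_steps = int(round(t / delta))
    step = np.eye(Q.shape[0]) + delta * np.asarray(Q, dtype=float)
    return np.linalg.matrix_power(step, n_steps)


def naive_panel_loglik(model, data, P_func=None, age_timevarying=True) -> float:
    """Per-subject, per-interval likelihood loop (no grouping, no batching).

    ``P_func(Q, dt)`` supplies the interval probability matrix; defaults to
    scipy's expm.  Death handling mirrors the stated conventions.
    """
    if P_func is None:
        P_func = lambda Q, dt: scipy.linalg.expm(dt * Q)
    ll = 0.0
    exact = data.death_convention == "exact"
    for sid, g in data.observations.groupby("subject_id", sort=False):
        times = g["time"].to_numpy(dtype=float)
        states = g["state"].to_numpy(dtype=int)
        for k in range(len(times) - 1):
            dt = times[k + 1] - times[k]
            if model.n_covariates:
                z = data.covariates.loc[sid].to_dict()
                if age_timevarying:
                    z["age"] = z["age"] + times[k]
            else:
                z = None
            Q = model.intensity_matrix(z)
            P = P_func(Q, dt)
            i, j = states[k] - 1, states[k + 1] - 1
            if states[k + 1] == 4 and exact:
                ll += np.log(sum(P[i, m] * Q[m, 3] for m in range(3)))
            else:
                ll += np.log(P[i, j])
    return ll
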