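"""Track generation: CTCRW paths with Argos-style observation and
move-persistence displacement series with covariate-driven persistence."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import WorldConfig, TruthParams

__all__ = ["simulate_ctcrw_track", "simulate_mpm_track"]


def simulate_ctcrw_track(truth: TruthParams, duration_days: float,
                         config: WorldConfig, seed,
                         start=(300.0, 300.0), animal_id: str = "seal_00",
                         t0=None, regular_gap: float | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact discretisation of the OU-velocity walk at irregular times.

    Observation gaps are exponential with mean ``config.mean_obs_gap``
    hours; with probability ``config.long_gap_rate`` a gap longer than 12 h
    is inserted.  ``regular_gap`` replaces the random gaps with a fixed
    interval (hours).  Observations add class-specific Gaussian error;
    classes are drawn from ``config.argos_class_freqs``.  Returns
    ``(true_path, observations)`` tables.
    """
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta, sigma = truth.ctcrw_beta_mov, truth.ctcrw_sigma_mov

    total_h = duration_days * 24.0
    if regular_gap is not None:
        t = np.arange(0.0, total_h + 1e-9, regular_gap)
    else:
        t = [0.0]
        while t[-1] < total_h:
            gap = rng.exponential(config.mean_obs_gap)
            if rng.random() < config.long_gap_rate:
                gap = 12.0 + rng.exponential(6.0)
            t.append(t[-1] + gap)
        t = np.array(t[:-1]) if t[-1] > total_h else np.array(t)
    n = len(t)

    pos = np.zeros((n, 2))
    vel = np.zeros((n, 2))
    pos[0] = start
    vel[0] = rng.normal(0.0, sigma / np.sqrt(2 * beta), 2)
    for k in range(1, n):
        dt = t[k] - t[k - 1]
        a = np.exp(-beta * dt)
        t01 = (1 - a) / beta
        q_vv = sigma ** 2 * (1 - a * a) / (2 * beta)
        q_xv = sigma ** 2 * (1 - a) ** 2 / (2 * beta ** 2)
        q_xx = max(sigma ** 2 / beta ** 2
                   * (dt - 2 * (1 - a) / beta + (1 - a * a) / (2 * beta)), 0.0)
        # Cholesky of the 2x2 transition covariance, shared by coordinates
        l11 = np.sqrt(q_xx)
        l21 = q_xv / l11 if l11 > 0 else 0.0
        l22 = np.sqrt(max(q_vv - l21 ** 2, 0.0))
        e = rng.standard_normal((2, 2))
        pos[k] = pos[k - 1] + t01 * vel[k - 1] + l11 * e[:, 0]
        vel[k] = a * vel[k - 1] + l21 * e[:, 0] + l22 * e[:, 1]

    classes = list(config.argos_class_freqs)
    freqs = np.array([config.argos_class_freqs[c] for c in classes], float)
    lc = rng.choice(classes, size=n, p=freqs / freqs.sum())
    sds = np.array([config.argos_class_sds[c] for c in lc])
    obs_xy = pos + rng.standard_normal((n, 2)) * sds[:, None]

    t0 = np.datetime64(config.time_origin) if t0 is None else np.datetime64(t0)
    dt_ns = (t * 3.6e12).astype("timedelta64[ns]")
    truth_df = pd.DataFrame({"animal_id": animal_id, "datetime": t0 + dt_ns,
                             "t_hours": t, "x": pos[:, 0], "y": pos[:, 1],
                             "vx": vel[:, 0], "vy": vel[:, 1]})
    obs_df = pd.DataFrame({"animal_id": animal_id, "datetime": t0 + dt_ns,
                           "t_hours": t, "lc": lc,
                           "x": obs_xy[:, 0], "y": obs_xy[:, 1]})
    return truth_df, obs_df


def simulate_mpm_track(truth: TruthParams, covariates: pd.DataFrame, seed,
                       b_i: float | None = None, start=(300.0, 300.0),
                       step_hours: float = 2.0) -> pd.DataFrame:
    """Displacement series with covariate-driven persistence.

    ``d_t = gamma_t d_{t-1} + noise`` with ``logit(gamma_t) = x_t' mpm_beta
    + b_i``; ``covariates`` provides one row per regular step with columns
    ``bathymetry``, ``risk``, ``prey`` (missing columns contribute 0).
    Returns positions, displacements and the true gamma series.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b0, b_bath, b_risk, b_prey = truth.mpm_beta
    if b_i is None:
        b_i = rng.normal(0.0, truth.mpm_sigma_b)
    n = len(covariates)
    g = lambda c: covariates[c].to_numpy(float) if c in covariates else np.zeros(n)
    eta = b0 + b_bath * g("bathymetry") + b_risk * g("risk") + b_prey * g("prey") + b_i
    gamma = expit(eta)

    d = np.zeros((n, 2))
    d[0] = rng.normal(0.0, truth.mpm_step_sd, 2)
    for k in range(1, n):
        d[k] = gamma[k] * d[k - 1] + rng.normal(0.0, truth.mpm_step_sd, 2)
    pos = np.vstack([start, start + np.cumsum(d, axis=0)])
    out = covariates.reset_index(drop=True).copy()
    out["gamma"] = gamma
    out["dx"] = d[:, 0]
    out["dy"] = d[:, 1]
    out["x"] = pos[1:, 0]
    out["y"] = pos[1:, 1]
    out["t_hours"] = step_hours * np.arange(1, n + 1)
    out.attrs["b_i"] = float(b_i)
    return out
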