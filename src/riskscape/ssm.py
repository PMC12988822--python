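"""Continuous-time correlated random walk (CTCRW) state-space model.

The latent process is an integrated Ornstein–Uhlenbeck velocity model per
planar coordinate: ``dv = -beta v dt + sigma dW`` with position the time
integral of velocity.  Coordinates are independent and share parameters, so
one covariance recursion serves both.  Observations are positions with
Gaussian error whose SD depends on the Argos location class, optionally
scaled by a shared estimated multiplier.  Exact transition moments over
irregular intervals give the exact marginal likelihood via the Kalman
filter; an RTS smoother yields regular-interval predictions and a
forward-filter backward-sampling pass yields joint posterior track draws.

Tracks are segmented before fitting: cut wherever transmission halted for
more than ``max_gap`` hours, and segments with fewer than ``min_len``
locations are discarded (short segments fit poorly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

from .synthetic.config import DEFAULT_CLASS_SDS

__all__ = ["TrackSegment", "CtcrwParams", "CtcrwModel", "CtcrwResults",
           "split_segments", "ou_transition"]


def ou_transition(beta: float, sigma: float, dt: float):
    """Exact (T, Q) for the (position, velocity) state over a gap ``dt``.

    T = [[1, (1-a)/beta], [0, a]] with a = exp(-beta dt); Q is the exact
    integrated-OU process covariance.
    """
    a = np.exp(-beta * dt)
    s2 = sigma * sigma
    t01 = (1.0 - a) / beta
    q_vv = s2 * (1.0 - a * a) / (2.0 * beta)
    q_xv = s2 * (1.0 - a) ** 2 / (2.0 * beta * beta)
    q_xx = max(s2 / (beta * beta)
               * (dt - 2.0 * (1.0 - a) / beta + (1.0 - a * a) / (2.0 * beta)), 0.0)
    T = np.array([[1.0, t01], [0.0, a]])
    Q = np.array([[q_xx, q_xv], [q_xv, q_vv]])
    return T, Q


# ---------------------------------------------------------------------------
# segmentation

def split_segments(obs: pd.DataFrame, max_gap_hours: float = 12.0,
                   min_len: int = 100) -> list["TrackSegment"]:
    """Cut tracks at every inter-observation gap > ``max_gap_hours`` and
    drop segments shorter than ``min_len`` locations.

    ``obs`` needs columns ``animal_id``, ``datetime``, ``x``, ``y`` and
    optionally ``lc`` (Argos class).  Duplicate timestamps keep the first
    record.  Empty input gives an empty list.
    """
    segments: list[TrackSegment] = []
    if len(obs) == 0:
        return segments
    for aid, g in obs.groupby("animal_id", sort=False):
        g = g.sort_values("datetime").drop_duplicates(subset="datetime", keep="first")
        t = pd.to_datetime(g["datetime"]).astype("int64").to_numpy() / 3.6e12  # hours
        gaps = np.diff(t)
        cut = np.flatnonzero(gaps > max_gap_hours) + 1
        for k, chunk in enumerate(np.split(np.arange(len(g)), cut)):
            if len(chunk) < min_len:
                continue
            sub = g.iloc[chunk]
            segments.append(TrackSegment.from_frame(f"{aid}-{k}", str(aid), sub))
    return segments


@dataclass
class TrackSegment:
    """A gap-free run of observations for one animal."""

    segment_id: str
    animal_id: str
    times: np.ndarray            # datetime64[ns]
    t_hours: np.ndarray          # hours since first obs
    xy: np.ndarray               # (n, 2) planar km
    loc_class: np.ndarray        # class labels, str

    @classmethod
    def from_frame(cls, segment_id: str, animal_id: str, df: pd.DataFrame) -> "TrackSegment":
        t = pd.to_datetime(df["datetime"]).to_numpy()
        th = (t - t[0]) / np.timedelta64(1, "h")
        lc = df["lc"].astype(str).to_numpy() if "lc" in df else np.full(len(df), "3")
        seg = cls(segment_id, animal_id, t, th.astype(float),
                  df[["x", "y"]].to_numpy(float), lc)
        seg.validate()
        return seg

    def validate(self) -> None:
        if np.any(np.diff(self.t_hours) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.t_hours)

    def error_sds(self, class_sds=None) -> np.ndarray:
        table = dict(DEFAULT_CLASS_SDS if class_sds is None else class_sds)
        return np.array([table[str(c)] for c in self.loc_class], dtype=float)


@dataclass
class CtcrwParams:
    beta_mov: float              # velocity reversion rate (1/h)
    sigma_mov: float             # velocity noise scale (km/sqrt(h))
    error_scale: float = 1.0     # shared multiplier on class SDs

    def validate(self) -> None:
        if min(self.beta_mov, self.sigma_mov, self.error_scale) <= 0:
            raise ValueError("CTCRW parameters must be positive")


# ---------------------------------------------------------------------------
# numba kernels (2-state per coordinate; covariances shared across x and y)

@njit(cache=True)
def _kf_pass(dts, z, sd2, miss, beta, sigma, z0x, z0y, p0pos, p0vel):
    """Kalman filter; returns nll and stored moments for smoothing/sampling.

    Stored arrays: filtered mean (n,4: x,vx,y,vy), filtered cov (n,3:
    p11,p12,p22), one-step predicted mean/cov, innovations and their
    variances at observed times.
    """
    n = dts.shape[0] + 1
    fm = np.zeros((n, 4))
    fP = np.zeros((n, 3))
    pm = np.zeros((n, 4))
    pP = np.zeros((n, 3))
    innov = np.zeros((n, 2))
    ivar = np.zeros(n)
    s2 = sigma * sigma
    # prior at first time
    mx, mvx, my, mvy = z0x, 0.0, z0y, 0.0
    p11, p12, p22 = p0pos, 0.0, p0vel
    nll = 0.0
    ln2pi = 1.8378770664093453
    for k in range(n):
        if k > 0:
            dt = dts[k - 1]
            a = np.exp(-beta * dt)
            t01 = (1.0 - a) / beta
            q_vv = s2 * (1.0 - a * a) / (2.0 * beta)
            q_xv = s2 * (1.0 - a) ** 2 / (2.0 * beta * beta)
            q_xx = s2 / (beta * beta) * (dt - 2.0 * (1.0 - a) / beta
                                         + (1.0 - a * a) / (2.0 * beta))
            if q_xx < 0.0:
                q_xx = 0.0
            mx, mvx = mx + t01 * mvx, a * mvx
            my, mvy = my + t01 * mvy, a * mvy
            n11 = p11 + 2.0 * t01 * p12 + t01 * t01 * p22 + q_xx
            n12 = a * (p12 + t01 * p22) + q_xv
            n22 = a * a * p22 + q_vv
            p11, p12, p22 = n11, n12, n22
        pm[k, 0], pm[k, 1], pm[k, 2], pm[k, 3] = mx, mvx, my, mvy
        pP[k, 0], pP[k, 1], pP[k, 2] = p11, p12, p22
        if not miss[k]:
            S = p11 + sd2[k]
            if S < 1e-12:
                S = 1e-12
            ex = z[k, 0] - mx
            ey = z[k, 1] - my
            innov[k, 0], innov[k, 1] = ex, ey
            ivar[k] = S
            nll += ln2pi + np.log(S) + 0.5 * (ex * ex + ey * ey) / S
            k1 = p11 / S
            k2 = p12 / S
            mx += k1 * ex
            mvx += k2 * ex
            my += k1 * ey
            mvy += k2 * ey
            n11 = (1.0 - k1) * p11
            n12 = (1.0 - k1) * p12
            n22 = p22 - k2 * p12
            p11, p12, p22 = n11, n12, n22
        fm[k, 0], fm[k, 1], fm[k, 2], fm[k, 3] = mx, mvx, my, mvy
        fP[k, 0], fP[k, 1], fP[k, 2] = p11, p12, p22
    return nll, fm, fP, pm, pP, innov, ivar


@njit(cache=True)
def _rts_pass(dts, beta, fm, fP, pm, pP):
    """Rauch–Tung–Striebel smoother over stored filter moments."""
    n = fm.shape[0]
    sm = fm.copy()
    sP = fP.copy()
    for k in range(n - 2, -1, -1):
        dt = dts[k]
        a = np.exp(-beta * dt)
        t01 = (1.0 - a) / beta
        p11, p12, p22 = fP[k, 0], fP[k, 1], fP[k, 2]
        # C = P_f T' (cross-covariance with next predicted state)
        c11 = p11 + t01 * p12
        c12 = a * p12
        c21 = p12 + t01 * p22
        c22 = a * p22
        q11, q12, q22 = pP[k + 1, 0], pP[k + 1, 1], pP[k + 1, 2]
        det = q11 * q22 - q12 * q12
        if det < 1e-300:
            det = 1e-300
        i11, i12, i22 = q22 / det, -q12 / det, q11 / det
        j11 = c11 * i11 + c12 * i12
        j12 = c11 * i12 + c12 * i22
        j21 = c21 * i11 + c22 * i12
        j22 = c21 * i12 + c22 * i22
        for c in range(2):
            dx = sm[k + 1, 2 * c] - pm[k + 1, 2 * c]
            dv = sm[k + 1, 2 * c + 1] - pm[k + 1, 2 * c + 1]
            sm[k, 2 * c] = fm[k, 2 * c] + j11 * dx + j12 * dv
            sm[k, 2 * c + 1] = fm[k, 2 * c + 1] + j21 * dx + j22 * dv
        d11 = sP[k + 1, 0] - q11
        d12 = sP[k + 1, 1] - q12
        d22 = sP[k + 1, 2] - q22
        # P_s = P_f + J (P_s(k+1) - P_pred) J'
        sP[k, 0] = p11 + j11 * (d11 * j11 + d12 * j12) + j12 * (d12 * j11 + d22 * j12)
        sP[k, 1] = p12 + j21 * (d11 * j11 + d12 * j12) + j22 * (d12 * j11 + d22 * j12)
        sP[k, 2] = p22 + j21 * (d11 * j21 + d12 * j22) + j22 * (d12 * j21 + d22 * j22)
    return sm, sP


@njit(cache=True)
def _ffbs_pass(dts, beta, fm, fP, pm, pP, normals):
    """Backward sampling given filter moments; one joint draw per call.

    ``normals`` is an (n, 4) standard-normal array (position and velocity
    innovations for both coordinates).
    """
    n = fm.shape[0]
    draw = np.zeros((n, 4))
    # sample last state
    p11, p12, p22 = fP[n - 1, 0], fP[n - 1, 1], fP[n - 1, 2]
    l11 = np.sqrt(max(p11, 0.0))
    l21 = p12 / l11 if l11 > 0 else 0.0
    t = p22 - l21 * l21
    l22 = np.sqrt(max(t, 0.0))
    for c in range(2):
        e1 = normals[n - 1, 2 * c]
        e2 = normals[n - 1, 2 * c + 1]
        draw[n - 1, 2 * c] = fm[n - 1, 2 * c] + l11 * e1
        draw[n - 1, 2 * c + 1] = fm[n - 1, 2 * c + 1] + l21 * e1 + l22 * e2
    for k in range(n - 2, -1, -1):
        dt = dts[k]
        a = np.exp(-beta * dt)
        t01 = (1.0 - a) / beta
        p11, p12, p22 = fP[k, 0], fP[k, 1], fP[k, 2]
        c11 = p11 + t01 * p12
        c12 = a * p12
        c21 = p12 + t01 * p22
        c22 = a * p22
        q11, q12, q22 = pP[k + 1, 0], pP[k + 1, 1], pP[k + 1, 2]
        det = q11 * q22 - q12 * q12
        if det < 1e-300:
            det = 1e-300
        i11, i12, i22 = q22 / det, -q12 / det, q11 / det
        j11 = c11 * i11 + c12 * i12
        j12 = c11 * i12 + c12 * i22
        j21 = c21 * i11 + c22 * i12
        j22 = c21 * i12 + c22 * i22
        # conditional covariance P_f - J C'
        v11 = p11 - (j11 * c11 + j12 * c12)
        v12 = p12 - (j11 * c21 + j12 * c22)
        v22 = p22 - (j21 * c21 + j22 * c22)
        l11 = np.sqrt(max(v11, 0.0))
        l21 = v12 / l11 if l11 > 0 else 0.0
        t = v22 - l21 * l21
        l22 = np.sqrt(max(t, 0.0))
        for c in range(2):
            dx = draw[k + 1, 2 * c] - pm[k + 1, 2 * c]
            dv = draw[k + 1, 2 * c + 1] - pm[k + 1, 2 * c + 1]
            mx = fm[k, 2 * c] + j11 * dx + j12 * dv
            mv = fm[k, 2 * c + 1] + j21 * dx + j22 * dv
            e1 = normals[k, 2 * c]
            e2 = normals[k, 2 * c + 1]
            draw[k, 2 * c] = mx + l11 * e1
            draw[k, 2 * c + 1] = mv + l21 * e1 + l22 * e2
    return draw


# ---------------------------------------------------------------------------
# model / results objects

class CtcrwModel:
    """CTCRW state-space model for one track segment.

    Parameters
    ----------
    segment : TrackSegment
    class_sds : mapping, optional
        Argos-class base error SDs in km.
    estimate_error_scale : bool
        If True (default) a shared multiplier on the class SDs is estimated
        with the movement parameters.
    prior_pos_sd : float
        SD (km) of the position prior at the first observation time.
    """

    def __init__(self, segment: TrackSegment, class_sds=None,
                 estimate_error_scale: bool = True, prior_pos_sd: float = 50.0):
        segment.validate()
        self.segment = segment
        self.base_sds = segment.error_sds(class_sds)
        self.estimate_error_scale = estimate_error_scale
        self.prior_pos_sd = float(prior_pos_sd)

    def _arrays(self, extra_times=None):
        t = self.segment.t_hours
        z = self.segment.xy
        if extra_times is None:
            times = t
            miss = np.zeros(len(t), dtype=np.bool_)
            zz = z
            sds = self.base_sds
        else:
            times = np.union1d(t, np.asarray(extra_times, float))
            miss = ~np.isin(times, t)
            zz = np.zeros((len(times), 2))
            sds = np.zeros(len(times))
            idx = np.searchsorted(times, t)
            zz[idx] = z
            sds[idx] = self.base_sds
        return times, np.diff(times), zz, sds, miss

    def nloglik(self, params: CtcrwParams) -> float:
        """Exact marginal negative log-likelihood."""
        params.validate()
        times, dts, z, sds, miss = self._arrays()
        sd2 = (params.error_scale * sds) ** 2
        p0v = params.sigma_mov ** 2 / (2 * params.beta_mov)
        nll, *_ = _kf_pass(dts, z, sd2, miss, params.beta_mov, params.sigma_mov,
                           z[0, 0], z[0, 1], self.prior_pos_sd ** 2, p0v)
        if not np.isfinite(nll):
            raise FloatingPointError("non-finite CTCRW likelihood")
        return float(nll)

    def fit(self, start: CtcrwParams | None = None, restarts: int = 3,
            gtol: float = 1e-8) -> "CtcrwResults":
        """Maximise the likelihood over log-parameters (quasi-Newton)."""
        est_scale = self.estimate_error_scale

        def obj(theta):
            p = self._theta_to_params(theta)
            try:
                return self.nloglik(p)
            except FloatingPointError:
                return 1e12

        if start is not None:
            inits = [np.log([start.beta_mov, start.sigma_mov, start.error_scale])]
        else:
            inits = [np.log([0.3, 1.0, 1.0])]
        rng = np.random.default_rng(0)
        for _ in range(max(restarts - 1, 0)):
            inits.append(inits[0] + rng.normal(0, 0.7, 3))
        best = None
        for x0 in inits:
            x0 = x0[:3] if est_scale else x0[:2]
            res = minimize(obj, x0, method="L-BFGS-B",
                           options={"gtol": gtol, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        params = self._theta_to_params(best.x)
        grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
        converged = bool(best.success) or grad_norm < 1e-2
        return CtcrwResults(self, params, float(best.fun), converged, grad_norm)

    def _theta_to_params(self, theta) -> CtcrwParams:
        scale = float(np.exp(theta[2])) if self.estimate_error_scale and len(theta) > 2 else 1.0
        return CtcrwParams(float(np.exp(theta[0])), float(np.exp(theta[1])), scale)

    def _moments(self, params: CtcrwParams, extra_times=None):
        times, dts, z, sds, miss = self._arrays(extra_times)
        sd2 = (params.error_scale * sds) ** 2
        sd2 = np.where(miss, 0.0, sd2)
        p0v = params.sigma_mov ** 2 / (2 * params.beta_mov)
        z0 = self.segment.xy[0]
        out = _kf_pass(dts, z, sd2, miss, params.beta_mov, params.sigma_mov,
                       z0[0], z0[1], self.prior_pos_sd ** 2, p0v)
        return times, dts, miss, out


class CtcrwResults:
    """Fitted CTCRW: parameter estimates, smoothed states, predictions, draws."""

    def __init__(self, model: CtcrwModel, params: CtcrwParams, nll: float,
                 converged: bool, grad_norm: float):
        self.model = model
        self.params = params
        self.nll = nll
        self.converged = converged
        self.grad_norm = grad_norm

    def _require_converged(self) -> None:
        if not self.converged:
            raise RuntimeError("CTCRW fit did not converge; refusing downstream use")

    def smoothed_states(self) -> pd.DataFrame:
        """Smoothed positions/velocities at the observation times."""
        times, dts, miss, (nll, fm, fP, pm, pP, *_ ) = self.model._moments(self.params)
        sm, sP = _rts_pass(dts, self.params.beta_mov, fm, fP, pm, pP)
        return pd.DataFrame({
            "t_hours": times, "x": sm[:, 0], "y": sm[:, 2],
            "vx": sm[:, 1], "vy": sm[:, 3],
            "var_pos": sP[:, 0], "var_vel": sP[:, 2]})

    def regular_grid(self, step_hours: float = 2.0) -> np.ndarray:
        t = self.model.segment.t_hours
        n = int(np.floor((t[-1] - t[0]) / step_hours)) + 1
        return t[0] + step_hours * np.arange(n)

    def predict_regular(self, step_hours: float = 2.0) -> pd.DataFrame:
        """Smoothing distribution on the regular grid anchored at the first
        observation time; ``floor(span/step) + 1`` predictions."""
        self._require_converged()
        grid = self.regular_grid(step_hours)
        times, dts, miss, (nll, fm, fP, pm, pP, *_ ) = self.model._moments(self.params, grid)
        sm, sP = _rts_pass(dts, self.params.beta_mov, fm, fP, pm, pP)
        idx = np.searchsorted(times, grid)
        seg = self.model.segment
        dt_ns = (grid - seg.t_hours[0]) * 3.6e12
        return pd.DataFrame({
            "segment_id": seg.segment_id, "animal_id": seg.animal_id,
            "datetime": seg.times[0] + dt_ns.astype("timedelta64[ns]"),
            "t_hours": grid,
            "x": sm[idx, 0], "y": sm[idx, 2],
            "vx": sm[idx, 1], "vy": sm[idx, 3],
            "var_x": sP[idx, 0], "var_y": sP[idx, 0], "cov_xy": 0.0})

    def one_step_ahead_residuals(self) -> pd.DataFrame:
        """Standardised innovations (per coordinate); the first observation
        is excluded because the position prior is centred on it."""
        times, dts, miss, (nll, fm, fP, pm, pP, innov, ivar) = \
            self.model._moments(self.params)
        s = np.sqrt(ivar[1:])
        return pd.DataFrame({
            "t_hours": times[1:],
            "resid_x": innov[1:, 0] / s,
            "resid_y": innov[1:, 1] / s})

    def simulate_posterior_tracks(self, n_draws: int = 100, seed=None,
                                  step_hours: float = 2.0) -> np.ndarray:
        """Joint draws from the smoothing distribution on the regular grid
        (forward-filter backward-sampling), shape (n_draws, n_times, 2)."""
        self._require_converged()
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        grid = self.regular_grid(step_hours)
        times, dts, miss, (nll, fm, fP, pm, pP, *_ ) = self.model._moments(self.params, grid)
        idx = np.searchsorted(times, grid)
        draws = np.empty((n_draws, len(grid), 2))
        for i in range(n_draws):
            normals = rng.standard_normal((len(times), 4))
            d = _ffbs_pass(dts, self.params.beta_mov, fm, fP, pm, pP, normals)
            draws[i, :, 0] = d[idx, 0]
            draws[i, :, 1] = d[idx, 2]
        return draws

    def summary(self) -> str:
        p = self.params
        lines = [
            "CTCRW state-space model",
            f"  segment: {self.model.segment.segment_id}  n={len(self.model.segment)}",
            f"  beta_mov    {p.beta_mov:10.4f}  (1/h velocity reversion)",
            f"  sigma_mov   {p.sigma_mov:10.4f}  (km/sqrt(h))",
            f"  error_scale {p.error_scale:10.4f}",
            f"  -logLik     {self.nll:10.3f}   converged={self.converged}",
        ]
        return "\n".join(lines)
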