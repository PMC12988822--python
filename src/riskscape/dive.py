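"""Dive metrics and AR1 random-intercept linear mixed models.

Transmitted dive summaries (duration, maximum depth, five intermediate
depth points with % elapsed) are reduced to three modelled responses:
duration, ascent speed (depth before the ascent divided by the time from
the last depth point to surfacing) and daily dive frequency.  Each response
is modelled with a Gaussian linear mixed model: per-seal random intercept,
first-order autoregressive (AR1) residuals over the (thinned) dive
sequence, dive depth always a fixed effect.  Records are thinned to every
10th dive per seal before model fitting to reduce autocorrelation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model_selection import aicc, candidate_set, rank_models

__all__ = ["derive_dive_metrics", "daily_frequency_table", "thin_every_kth",
           "Ar1MixedModel", "Ar1LmmResults", "fit_dive_candidates"]


def derive_dive_metrics(dives: pd.DataFrame,
                        ascent_from: str = "last_point") -> pd.DataFrame:
    """Derive per-dive modelling rows from transmitted summaries.

    Ascent speed (m/s) = (depth before the ascent) / (duration x
    (100 - p5)/100), with the depth before the ascent taken as the last
    intermediate point ``d5`` (or ``max_depth`` when ``ascent_from=
    "max_depth"``).  Rows with ``p5 == 100`` have an undefined ascent and
    are dropped.  Dives shallower than 2 m are excluded at ingest.
    """
    d = dives.reset_index(drop=True).copy()
    ok = d["p5"] < 100.0
    d = d.loc[ok].reset_index(drop=True)
    depth_before = d["d5"] if ascent_from == "last_point" else d["max_depth"]
    ascent_time = d["duration_s"] * (100.0 - d["p5"]) / 100.0
    d["ascent_speed"] = depth_before / ascent_time
    d["sequence"] = d.groupby("animal_id").cumcount() + 1
    return d


def daily_frequency_table(dives: pd.DataFrame, tracked_days=None) -> pd.DataFrame:
    """Dives per seal per UTC day, with daily-mean covariates.

    ``tracked_days``: optional mapping animal_id -> iterable of dates; days
    a seal was tracked but logged no dives enter with frequency 0.
    """
    d = dives.copy()
    d["date"] = pd.to_datetime(d["datetime"]).dt.floor("D")
    covs = [c for c in ("ice", "prey", "risk", "max_depth", "bathymetry")
            if c in d.columns]
    agg = d.groupby(["animal_id", "date"]).agg(
        frequency=("datetime", "size"), **{c: (c, "mean") for c in covs}
    ).reset_index()
    if tracked_days is not None:
        rows = []
        for aid, days in tracked_days.items():
            have = set(agg.loc[agg["animal_id"] == aid, "date"])
            for day in pd.to_datetime(list(days)):
                if day not in have:
                    rows.append({"animal_id": aid, "date": day, "frequency": 0})
        if rows:
            agg = pd.concat([agg, pd.DataFrame(rows)], ignore_index=True)
            agg = agg.sort_values(["animal_id", "date"]).reset_index(drop=True)
    agg["sequence"] = agg.groupby("animal_id").cumcount() + 1
    return agg


def thin_every_kth(rows: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Per seal, keep rows whose 1-based sequence index is a multiple of k.

    Retains floor(n/k) rows per seal, order preserved; the first retained
    index is k.
    """
    out = []
    for _, g in rows.groupby("animal_id", sort=False):
        out.append(g.iloc[k - 1::k])
    return pd.concat(out).reset_index(drop=True) if out else rows.iloc[0:0]


# ---------------------------------------------------------------------------
# AR1 random-intercept LMM

def _ar1_corr(n: int, phi: float) -> np.ndarray:
    idx = np.arange(n)
    return phi ** np.abs(idx[:, None] - idx[None, :])


def _ar1_inv_apply(phi: float, M: np.ndarray) -> np.ndarray:
    """R(phi)^-1 @ M in O(n) via the analytic tridiagonal inverse."""
    M = np.atleast_2d(M.T).T if M.ndim == 1 else M
    n = M.shape[0]
    if n == 1:
        return M.copy()
    out = np.empty_like(M)
    out[0] = M[0] - phi * M[1]
    out[-1] = M[-1] - phi * M[-2]
    if n > 2:
        out[1:-1] = -phi * M[:-2] + (1 + phi * phi) * M[1:-1] - phi * M[2:]
    return out / (1 - phi * phi)


def _block_solve(phi, sigma_b, sigma_e, M):
    """(sigma_b^2 J + sigma_e^2 R)^-1 @ M and the block log-determinant,
    via Woodbury over the rank-one random-intercept term."""
    n = M.shape[0]
    se2 = sigma_e ** 2
    AiM = _ar1_inv_apply(phi, M) / se2
    ones = np.ones((n, 1))
    u = _ar1_inv_apply(phi, ones) / se2
    s = float(u.sum())
    c = sigma_b ** 2 / (1.0 + sigma_b ** 2 * s)
    sol = AiM - u @ (c * (ones.T @ AiM))
    logdet = n * np.log(se2) + (n - 1) * np.log(1 - phi * phi) \
        + np.log(1.0 + sigma_b ** 2 * s)
    return sol, logdet


class Ar1MixedModel:
    """Gaussian LMM with per-seal random intercept and AR1 residuals.

    Marginal covariance per seal: ``sigma_b^2 J + sigma_e^2 R(phi)`` with
    ``R`` the AR1 correlation over the thinned sequence order.  Fixed
    effects are profiled out by GLS inside the variance-parameter
    optimisation.  Default criterion is ML (for AICc comparability); REML
    is available.
    """

    def __init__(self, rows: pd.DataFrame, response: str,
                 terms=("ice", "prey", "risk"), include_depth: bool = True):
        self.response = response
        self.terms = tuple(terms)
        self.include_depth = include_depth and "max_depth" in rows.columns
        self.names = ["intercept"] + (["max_depth"] if self.include_depth else []) \
            + list(self.terms)
        self.groups = []
        for aid, g in rows.groupby("animal_id", sort=False):
            y = g[response].to_numpy(float)
            if len(y) < 2:
                continue
            X = self._design(g)
            self.groups.append((str(aid), y, X))
        if len(self.groups) < 2:
            raise ValueError("need at least two seals with >= 2 rows each")
        self.n = sum(len(y) for _, y, _ in self.groups)
        self.p = len(self.names)

    def _design(self, g: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(g))]
        if self.include_depth:
            cols.append(g["max_depth"].to_numpy(float))
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":")
                cols.append(g[a].to_numpy(float) * g[b].to_numpy(float))
            else:
                cols.append(g[t].to_numpy(float))
        return np.column_stack(cols)

    def _profile(self, phi: float, sigma_b: float, sigma_e: float):
        """GLS beta-hat and profiled -2logLik pieces for given variances."""
        XtX = np.zeros((self.p, self.p))
        Xty = np.zeros(self.p)
        pieces = []
        logdet_sum = 0.0
        for _, y, X in self.groups:
            Xy = np.column_stack([X, y])
            sol, logdet = _block_solve(phi, sigma_b, sigma_e, Xy)
            XtX += X.T @ sol[:, :-1]
            Xty += X.T @ sol[:, -1]
            logdet_sum += logdet
            pieces.append((y, X, sol))
        beta = np.linalg.solve(XtX, Xty)
        quad = 0.0
        for y, X, sol in pieces:
            # r' V^-1 r expanded from the precomputed solves
            quad += y @ sol[:, -1] - 2 * beta @ (X.T @ sol[:, -1]) \
                + beta @ (X.T @ sol[:, :-1]) @ beta
        return beta, XtX, quad, logdet_sum

    def nloglik(self, beta, phi, sigma_b, sigma_e) -> float:
        """Exact marginal Gaussian negative log-likelihood at given params."""
        total = 0.0
        for _, y, X in self.groups:
            n = len(y)
            r = y - X @ np.asarray(beta, float)
            sol, logdet = _block_solve(phi, sigma_b, sigma_e, r[:, None])
            total += 0.5 * (n * np.log(2 * np.pi) + logdet + r @ sol[:, 0])
        return float(total)

    def fit(self, reml: bool = False, start=None) -> "Ar1LmmResults":
        def obj(theta):
            phi = np.tanh(theta[0])
            sb = np.exp(theta[1])
            se = np.exp(theta[2])
            try:
                beta, XtX, quad, logdet = self._profile(phi, sb, se)
            except np.linalg.LinAlgError:
                return 1e12
            val = 0.5 * (self.n * np.log(2 * np.pi) + logdet + quad)
            if reml:
                sign, ld = np.linalg.slogdet(XtX)
                val += 0.5 * ld
            return val if np.isfinite(val) else 1e12

        y_all = np.concatenate([y for _, y, _ in self.groups])
        s0 = max(y_all.std(), 1e-6)
        x0 = np.array([np.arctanh(0.2), np.log(0.5 * s0), np.log(0.8 * s0)])
        if start is not None:
            x0 = np.asarray(start, float)
        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"maxiter": 3000, "xatol": 1e-7, "fatol": 1e-9})
        phi = float(np.tanh(res.x[0]))
        sb = float(np.exp(res.x[1]))
        se = float(np.exp(res.x[2]))
        beta, XtX, quad, logdet = self._profile(phi, sb, se)
        loglik = -0.5 * (self.n * np.log(2 * np.pi) + logdet + quad)
        cov_beta = np.linalg.inv(XtX)
        boundary = abs(phi) > 0.995
        return Ar1LmmResults(self, beta, cov_beta, phi, sb, se, float(loglik),
                             bool(res.success) and not boundary)


class Ar1LmmResults:
    """Fitted AR1 mixed model."""

    def __init__(self, model, beta, cov_beta, phi, sigma_b, sigma_e, loglik,
                 converged):
        self.model = model
        self.names = model.names
        self.params = pd.Series(beta, index=self.names)
        self.bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=self.names)
        self.phi = phi
        self.sigma_b = sigma_b
        self.sigma_e = sigma_e
        self.loglik = loglik
        self.converged = converged
        self.k = model.p + 3          # beta, sigma_b, sigma_e, phi
        self.n = model.n
        self.aicc = aicc(loglik, self.k, self.n)
        self.name = "+".join(model.terms) if model.terms else "null"

    def whitened_residuals(self) -> np.ndarray:
        """Residuals premultiplied by the inverse Cholesky of the fitted
        per-seal covariance; white under a correct model."""
        out = []
        beta = self.params.to_numpy()
        for _, y, X in self.model.groups:
            n = len(y)
            V = self.sigma_b ** 2 * np.ones((n, n)) \
                + self.sigma_e ** 2 * _ar1_corr(n, self.phi)
            L = np.linalg.cholesky(V)
            out.append(np.linalg.solve(L, y - X @ beta))
        return np.concatenate(out)

    def summary(self) -> str:
        lines = [f"AR1 random-intercept LMM ({self.model.response} ~ {self.name})",
                 f"  n={self.n}  k={self.k}  logLik={self.loglik:.2f}  AICc={self.aicc:.2f}",
                 f"  phi={self.phi:.4f}  sigma_b={self.sigma_b:.4f}  "
                 f"sigma_e={self.sigma_e:.4f}",
                 f"  {'term':<14}{'coef':>12}{'se':>12}"]
        for t in self.names:
            lines.append(f"  {t:<14}{self.params[t]:>12.4f}{self.bse[t]:>12.4f}")
        return "\n".join(lines)


def fit_dive_candidates(rows: pd.DataFrame, response: str):
    """Fit the 9+null candidate set for one dive response and rank it.

    Every model (the null included) carries dive depth as a fixed effect
    and the seal random intercept; the AR1 structure applies throughout.
    """
    fits = {}
    for cand in candidate_set():
        res = Ar1MixedModel(rows, response, cand.terms).fit()
        res.name = cand.name
        fits[cand.name] = res
    return rank_models(list(fits.values())), fits
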