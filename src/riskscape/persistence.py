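"""Move-persistence mixed model.

Directional persistence gamma_t in (0, 1) links successive displacement
vectors of a regular-interval track: ``d_t = gamma_t d_{t-1} + e_t`` with
isotropic Gaussian noise, ``logit(gamma_t) = x_t' beta + b_i`` and seal-level
random intercepts ``b_i ~ N(0, sigma_b^2)``.  Low gamma marks resident /
area-restricted behaviour, high gamma directed travel.  The marginal
likelihood integrates b_i by a Laplace approximation (exact inner Newton
optimisation with analytic derivatives).  Formulas are first-order only:
interactions are rejected by contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import expit

from .model_selection import aicc, rank_models

__all__ = ["MovePersistenceModel", "MpmResults", "rank_mpm_models",
           "risk_binned_behaviour"]

_LOG2PI = float(np.log(2 * np.pi))


class MovePersistenceModel:
    """Mixed move-persistence model over one or more seals.

    Parameters
    ----------
    data : DataFrame with ``animal_id``, displacement columns ``dx``/``dy``
        (or positions ``x``/``y`` at a regular step, from which displacements
        are differenced per seal) and covariate columns.
    terms : first-order covariate names entering logit(gamma) after the
        intercept; an interaction term raises ``ValueError``.
    """

    def __init__(self, data: pd.DataFrame, terms=("bathymetry", "risk")):
        if any(":" in t or "*" in t for t in terms):
            raise ValueError("move-persistence formulas do not accommodate interactions")
        self.terms = tuple(terms)
        self.groups = []
        for aid, g in data.groupby("animal_id", sort=False):
            g = g.reset_index(drop=True)
            if {"dx", "dy"}.issubset(g.columns):
                d = g[["dx", "dy"]].to_numpy(float)
                X = np.column_stack([np.ones(len(g))] +
                                    [g[t].to_numpy(float) for t in terms])
                seg = g["segment_id"].to_numpy() if "segment_id" in g \
                    else np.zeros(len(g))
            else:
                pos = g[["x", "y"]].to_numpy(float)
                if len(pos) < 3:
                    continue
                d = np.diff(pos, axis=0)
                X = np.column_stack([np.ones(len(d))] +
                                    [g[t].to_numpy(float)[1:] for t in terms])
                seg = (g["segment_id"].to_numpy()[1:] if "segment_id" in g
                       else np.zeros(len(d)))
            if len(d) < 2:
                continue
            # transitions only within a segment
            trans = seg[1:] == seg[:-1]
            if not trans.any():
                continue
            self.groups.append((str(aid), d, X, trans))
        if not self.groups:
            raise ValueError("no usable segments (need >= 3 positions per seal)")
        self.p = 1 + len(self.terms)
        # internal z-scoring of covariate columns for optimiser conditioning;
        # coefficients are reported on the original scale
        allX = np.vstack([X for _, _, X, _ in self.groups])
        self._mu = allX.mean(axis=0)
        self._sd = allX.std(axis=0)
        self._mu[0] = 0.0
        self._sd[0] = 1.0
        self._sd[self._sd == 0] = 1.0
        self.groups = [(aid, d, (X - self._mu) / self._sd, trans)
                       for aid, d, X, trans in self.groups]

    def _beta_to_raw(self, beta_std: np.ndarray) -> np.ndarray:
        raw = beta_std / self._sd
        raw[0] = beta_std[0] - np.sum(beta_std[1:] * self._mu[1:] / self._sd[1:])
        return raw

    def _beta_to_std(self, beta_raw: np.ndarray) -> np.ndarray:
        std = beta_raw * self._sd
        std[0] = beta_raw[0] + np.sum(beta_raw[1:] * self._mu[1:])
        return std

    # -- inner problem: per-seal random intercept -------------------------

    @staticmethod
    def _seal_quad(b, d, eta0, sigma, trans):
        """(loglik, d/db, d2/db2) of the displacement likelihood at offset b."""
        gam = expit(eta0 + b)
        prev = d[:-1][trans]
        cur = d[1:][trans]
        gt = gam[1:][trans]
        r = cur - gt[:, None] * prev
        s2 = sigma * sigma
        ll = -0.5 * np.sum(r * r) / s2 - r.size * 0.5 * (_LOG2PI + np.log(s2))
        g1 = gt * (1 - gt)
        g2 = g1 * (1 - 2 * gt)
        rd = np.sum(r * prev, axis=1)
        d1 = np.sum(rd * g1) / s2
        d2 = np.sum(-g1 * g1 * np.sum(prev * prev, axis=1) + rd * g2) / s2
        return ll, d1, d2

    def _laplace_seal(self, d, X, trans, beta, sigma, sigma_b, b0=0.0):
        eta0 = X @ beta
        if sigma_b <= 1e-8:
            ll, _, _ = self._seal_quad(0.0, d, eta0, sigma, trans)
            return ll, 0.0
        inv_vb = 1.0 / (sigma_b * sigma_b)

        def grad(b):
            _, d1, _ = self._seal_quad(b, d, eta0, sigma, trans)
            return d1 - b * inv_vb

        b = b0
        for _ in range(50):
            _, d1, d2 = self._seal_quad(b, d, eta0, sigma, trans)
            g = d1 - b * inv_vb
            h = d2 - inv_vb
            if h >= 0:
                h = -inv_vb
            step = -g / h
            step = np.clip(step, -1.0, 1.0)
            b = b + step
            if abs(step) < 1e-10:
                break
        else:
            lo, hi = -10 * sigma_b, 10 * sigma_b
            if grad(lo) * grad(hi) < 0:
                b = brentq(grad, lo, hi, xtol=1e-10)
        ll, _, d2 = self._seal_quad(b, d, eta0, sigma, trans)
        H = inv_vb - d2
        if H <= 0:
            H = inv_vb
        return ll - 0.5 * b * b * inv_vb - np.log(sigma_b) - 0.5 * np.log(H), b

    def _nll_std(self, beta_std, sigma, sigma_b, b_cache=None) -> float:
        total = 0.0
        for i, (aid, d, X, trans) in enumerate(self.groups):
            b0 = b_cache[i] if b_cache is not None else 0.0
            ll, b = self._laplace_seal(d, X, trans, beta_std, sigma, sigma_b, b0)
            if b_cache is not None:
                b_cache[i] = b
            total -= ll
        return total

    def nloglik(self, beta, sigma, sigma_b) -> float:
        """Laplace marginal negative log-likelihood at original-scale beta."""
        return self._nll_std(self._beta_to_std(np.asarray(beta, float)),
                             sigma, sigma_b)

    def fit(self, fix_sigma_b: float | None = None, start=None) -> "MpmResults":
        """Maximise the Laplace marginal likelihood; reports convergence."""
        p = self.p
        b_cache = np.zeros(len(self.groups))
        est_sb = fix_sigma_b is None

        def obj(theta):
            beta = theta[:p]
            sigma = np.exp(theta[p])
            sb = np.exp(theta[p + 1]) if est_sb else fix_sigma_b
            try:
                v = self._nll_std(beta, sigma, sb, b_cache)
            except FloatingPointError:
                return 1e12
            return v if np.isfinite(v) else 1e12

        d_all = np.vstack([d for _, d, _, _ in self.groups])
        s0 = np.log(max(d_all.std(), 1e-3))
        x0 = np.zeros(p + (2 if est_sb else 1))
        x0[p] = s0
        if est_sb:
            x0[p + 1] = np.log(0.3)
        if start is not None:
            x0[:len(start)] = start
        res = minimize(obj, x0, method="L-BFGS-B", options={"maxiter": 500})
        if not res.success:
            res2 = minimize(obj, res.x, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
            if res2.fun <= res.fun:
                res = res2
        beta_std = res.x[:p]
        sigma = float(np.exp(res.x[p]))
        sigma_b = float(np.exp(res.x[p + 1])) if est_sb else float(fix_sigma_b)
        nll = self._nll_std(beta_std, sigma, sigma_b, b_cache)
        return MpmResults(self, self._beta_to_raw(beta_std.copy()), sigma,
                          sigma_b, dict(
            zip([aid for aid, *_ in self.groups], b_cache.copy())),
            -float(nll), bool(res.success), est_sb)


class MpmResults:
    """Fitted move-persistence model."""

    def __init__(self, model, beta, sigma, sigma_b, b_i, loglik, converged, est_sb):
        self.model = model
        self.names = ["intercept", *model.terms]
        self.params = pd.Series(beta, index=self.names)
        self.sigma_step = float(sigma)
        self.sigma_b = float(sigma_b)
        self.b_i = b_i
        self.loglik = float(loglik)
        self.converged = converged
        self.k = len(beta) + 1 + (1 if est_sb else 0)
        self.n = sum(int(trans.sum()) for _, _, _, trans in model.groups)
        self.aicc = aicc(self.loglik, self.k, self.n)
        self.name = "+".join(model.terms) if model.terms else "intercept"

    def gamma_series(self) -> pd.DataFrame:
        """Fitted persistence gamma_t per seal/step (empirical-Bayes modes)."""
        rows = []
        beta_std = self.model._beta_to_std(self.params.to_numpy().copy())
        for aid, d, X, _ in self.model.groups:
            gam = expit(X @ beta_std + self.b_i.get(aid, 0.0))
            rows.append(pd.DataFrame({"animal_id": aid,
                                      "step": np.arange(len(gam)), "gamma": gam}))
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        lines = [f"Move-persistence mixed model (~ {self.name})",
                 f"  n_steps={self.n}  k={self.k}  logLik={self.loglik:.2f}  "
                 f"AICc={self.aicc:.2f}  converged={self.converged}"]
        for t in self.names:
            lines.append(f"  {t:<12}{self.params[t]:>10.4f}")
        lines.append(f"  sigma_step  {self.sigma_step:>10.4f} km")
        lines.append(f"  sigma_b     {self.sigma_b:>10.4f} (random intercept SD)")
        return "\n".join(lines)


def rank_mpm_models(data: pd.DataFrame,
                    candidates=(("bathymetry", "risk"),
                                ("bathymetry", "prey"),
                                ("bathymetry", "risk", "prey"))):
    """Fit the candidate persistence formulas and rank by AICc."""
    fits = []
    for terms in candidates:
        fits.append(MovePersistenceModel(data, terms).fit())
    return rank_models(fits), fits


def risk_binned_behaviour(gamma: np.ndarray, risk: np.ndarray, n_bins: int = 5,
                          gamma_breaks=None) -> pd.DataFrame:
    """Distribution of persistence classes across equal-count risk bins.

    Risk values are split into ``n_bins`` equal-sized groups (sizes differ
    by at most one); within each, the share of gamma values per class
    (default: tertiles of the fitted gamma) is reported with the bin sample
    size.
    """
    gamma = np.asarray(gamma, float)
    risk = np.asarray(risk, float)
    order = np.argsort(risk, kind="stable")
    groups = np.array_split(order, n_bins)
    if gamma_breaks is None:
        gamma_breaks = np.quantile(gamma, [1 / 3, 2 / 3])
    edges = np.concatenate([[-np.inf], np.asarray(gamma_breaks), [np.inf]])
    rows = []
    for i, idx in enumerate(groups):
        g = gamma[idx]
        cls = np.digitize(g, edges[1:-1])
        props = np.bincount(cls, minlength=len(edges) - 1) / max(len(g), 1)
        row = {"risk_bin": i, "n": len(g),
               "risk_lo": risk[idx].min() if len(idx) else np.nan,
               "risk_hi": risk[idx].max() if len(idx) else np.nan,
               "mean_gamma": g.mean() if len(g) else np.nan}
        for c, p in enumerate(props):
            row[f"class_{c}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
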