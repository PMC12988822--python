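"""Predator (polar bear) habitat selection and daily risk rasters.

A used/available logistic design over (sea-ice concentration, bathymetry,
distance to coast) is fitted with an L1 (LASSO) penalty on standardised
covariates; the penalty weight is chosen by grouped K-fold cross-validated
deviance (folds blocked by bear to avoid leakage), optionally with the
one-standard-error rule.  The fitted model is pushed through exp() over
each day's fields and min-max normalised over water to a [0, 1] "predator
selection" raster — the predation-risk covariate of every downstream seal
model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression


from .raster import CovariateStack, RasterField

logger = logging.getLogger(__name__)

__all__ = ["build_bear_design", "LassoRSF", "PenalizedRsfFit", "predict_daily_risk"]

BEAR_COVARIATES = ("ice", "bathymetry", "dist_coast")


def build_bear_design(bear_points: pd.DataFrame, stack: CovariateStack,
                      ratio: int = 10, seed=None) -> pd.DataFrame:
    """Used/available table for the predator RSF.

    Available rows are uniform over water cells of the analysis domain and
    uniform over study days (the used/available sampling frame); all
    covariates are extracted bilinearly from the matching day's fields.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .raster import bilinear
    geo = stack.geometry
    water = ~stack.land
    wy, wx = np.where(water)
    used = bear_points.copy()
    used["response"] = 1
    rows = [used]
    n_av = ratio * len(bear_points)
    pick = rng.integers(0, len(wy), n_av)
    jit = rng.uniform(-0.5, 0.5, (n_av, 2)) * geo.cell_size
    ax = np.clip(geo.x0 + wx[pick] * geo.cell_size + jit[:, 0], geo.x0, geo.x_max)
    ay = np.clip(geo.y0 + wy[pick] * geo.cell_size + jit[:, 1], geo.y0, geo.y_max)
    days = rng.choice(np.array(sorted(stack.ice)), n_av)
    avail = pd.DataFrame({"x": ax, "y": ay, "day": days, "response": 0,
                          "animal_id": "avail"})
    rows.append(avail)
    out = pd.concat(rows, ignore_index=True)
    out["bathymetry"] = bilinear(stack.bathymetry, out["x"], out["y"])
    out["dist_coast"] = bilinear(stack.dist_coast, out["x"], out["y"])
    ice = np.empty(len(out))
    for d in np.unique(out["day"]):
        m = (out["day"] == d).to_numpy()
        ice[m] = bilinear(stack.ice[int(d)], out.loc[m, "x"], out.loc[m, "y"])
    out["ice"] = ice
    return out


@dataclass
class PenalizedRsfFit:
    """L1-penalised predator RSF: standardised coefficients + transform."""

    coefficients: pd.Series
    intercept: float
    lam: float
    transform: dict
    cv_table: pd.DataFrame = field(default=None, repr=False)
    separation_warning: bool = False

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        z = np.zeros(len(df)) + self.intercept
        for c, b in self.coefficients.items():
            mu, sd = self.transform[c]
            z += b * (df[c].to_numpy(float) - mu) / sd
        return z

    def summary(self) -> str:
        lines = [f"LASSO predator RSF (lambda={self.lam:.5g})",
                 f"  intercept   {self.intercept:>10.4f}"]
        for c, b in self.coefficients.items():
            lines.append(f"  {c:<12}{b:>10.4f}" + ("  (dropped)" if b == 0 else ""))
        return "\n".join(lines)


class LassoRSF:
    """L1-penalised logistic RSF over standardised covariates."""

    def __init__(self, design: pd.DataFrame, covariates=BEAR_COVARIATES):
        y = design["response"].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("both used and available rows are required")
        self.covariates = list(covariates)
        self.y = y.astype(float)
        X = design[self.covariates].to_numpy(float)
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.sd[self.sd == 0] = 1.0
        self.X = (X - self.mu) / self.sd
        self.groups = design["animal_id"].to_numpy() if "animal_id" in design \
            else np.zeros(len(design))

    def lambda_max(self) -> float:
        """Smallest penalty with all coefficients exactly zero (KKT bound)."""
        ybar = self.y.mean()
        return float(np.max(np.abs(self.X.T @ (self.y - ybar))) / len(self.y))

    def lambda_grid(self, n: int = 20, eps: float = 1e-3) -> np.ndarray:
        lmax = self.lambda_max()
        return np.geomspace(lmax * 1.001, lmax * eps, n)

    def _fit_at(self, lam: float, X=None, y=None):
        X = self.X if X is None else X
        y = self.y if y is None else y
        if lam <= 0:
            clf = LogisticRegression(penalty=None, max_iter=2000, tol=1e-10)
        else:
            clf = LogisticRegression(penalty="l1", solver="saga",
                                     C=1.0 / (lam * len(y)), max_iter=5000,
                                     tol=1e-8, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        return clf.coef_.ravel(), float(clf.intercept_[0])

    def fit(self, lam: float | str = "cv", cv_folds: int = 5, seed=0,
            one_se: bool = False, n_lambda: int = 20) -> PenalizedRsfFit:
        """Fit at a given penalty, or choose it by grouped-CV deviance."""
        sep = self._check_separation()
        cv_table = None
        if lam == "cv":
            grid = self.lambda_grid(n_lambda)
            folds, fold_id = self._fold_assignment(cv_folds, seed)
            dev = np.zeros((len(grid), folds))
            splits = [(np.flatnonzero(fold_id != f), np.flatnonzero(fold_id == f))
                      for f in range(folds)]
            for f, (tr, te) in enumerate(splits):
                for i, l in enumerate(grid):
                    coef, b0 = self._fit_at(l, self.X[tr], self.y[tr])
                    eta = self.X[te] @ coef + b0
                    p = 1.0 / (1.0 + np.exp(-eta))
                    p = np.clip(p, 1e-12, 1 - 1e-12)
                    dev[i, f] = -2 * np.mean(self.y[te] * np.log(p)
                                             + (1 - self.y[te]) * np.log(1 - p))
            mean_dev = dev.mean(axis=1)
            se_dev = dev.std(axis=1) / np.sqrt(folds)
            best = int(np.argmin(mean_dev))
            if one_se:
                thresh = mean_dev[best] + se_dev[best]
                best = int(np.flatnonzero(mean_dev <= thresh)[0])
            lam = float(grid[best])
            cv_table = pd.DataFrame({"lambda": grid, "cv_deviance": mean_dev,
                                     "cv_se": se_dev})
        if sep:
            logger.warning("complete separation detected; returning largest-"
                           "penalty fit")
            lam = self.lambda_max() * 1.001
        coef, b0 = self._fit_at(float(lam))
        coef[np.abs(coef) < 1e-10] = 0.0
        return PenalizedRsfFit(
            pd.Series(coef, index=self.covariates), b0, float(lam),
            {c: (self.mu[i], self.sd[i]) for i, c in enumerate(self.covariates)},
            cv_table, separation_warning=sep)

    def _fold_assignment(self, cv_folds: int, seed) -> tuple[int, np.ndarray]:
        """Folds blocked by bear for used rows; available rows spread evenly."""
        rng = np.random.default_rng(seed if not isinstance(seed, np.random.Generator)
                                    else seed.integers(2 ** 31))
        used = self.y == 1
        bears = np.unique(self.groups[used])
        if len(bears) < 2:
            # no animal blocking possible; plain random row folds
            fold_id = rng.integers(0, cv_folds, len(self.y))
            return int(cv_folds), fold_id
        folds = int(min(cv_folds, len(bears)))
        perm = rng.permutation(len(bears))
        bear_fold = {b: perm[i] % folds for i, b in enumerate(bears)}
        fold_id = np.empty(len(self.y), dtype=int)
        fold_id[used] = [bear_fold[g] for g in self.groups[used]]
        fold_id[~used] = rng.integers(0, folds, int((~used).sum()))
        return folds, fold_id

    def _check_separation(self) -> bool:
        # a single covariate perfectly splitting the classes
        for j in range(self.X.shape[1]):
            x1 = self.X[self.y == 1, j]
            x0 = self.X[self.y == 0, j]
            if x1.min() > x0.max() or x0.min() > x1.max():
                return True
        return False


def predict_daily_risk(fit: PenalizedRsfFit, stack: CovariateStack,
                       day: int) -> RasterField:
    """Daily predator-selection raster: exp(linear predictor) min-max
    normalised to [0, 1] over water nodes; land gets 0.

    A degenerate (constant) surface normalises to 0.5 by convention, logged.
    The normalisation record is stored in the field name metadata-free way:
    returned values are already normalised; min/max recorded on the field.
    """
    geo = stack.geometry
    df = pd.DataFrame({
        "ice": stack.ice[day].values.ravel(),
        "bathymetry": stack.bathymetry.values.ravel(),
        "dist_coast": stack.dist_coast.values.ravel(),
    })
    lin = fit.linear_predictor(df).reshape(geo.values.shape)
    water = ~stack.land
    w = np.exp(lin - lin[water].max())
    lo, hi = float(w[water].min()), float(w[water].max())
    if hi <= lo:
        logger.warning("degenerate risk surface on day %s; returning 0.5", day)
        vals = np.where(water, 0.5, 0.0)
    else:
        vals = np.where(water, (w - lo) / (hi - lo), 0.0)
    fld = geo.like(vals, stamp=day, name="risk")
    fld.normalization = {"min": lo, "max": hi}
    return fld
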