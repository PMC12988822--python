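# riskscape

Joint top-down/bottom-up analysis of mesopredator movement in an Arctic
predator–prey system.  The package is built for movement ecologists who
have satellite telemetry from a mesopredator (here: ringed seals tracked
with Argos tags during the ice season), movement data or a fitted habitat
model for its top predator (polar bears), and gridded environmental and
prey covariates — and who want to quantify how predation risk and prey
availability jointly shape habitat selection, movement behaviour and
diving.

## What it does

1. **Track filtering** — a continuous-time correlated random walk
   state-space model (Ornstein–Uhlenbeck velocity, exact irregular-interval
   likelihood via a Kalman filter) turns noisy, irregular Argos fixes into
   regular 2-h location estimates with uncertainty, one-step-ahead residual
   diagnostics, and joint posterior track draws.  Tracks are split at
   transmission gaps > 12 h; segments with < 100 fixes are dropped.
2. **Predation-risk landscape** — an L1-penalised (LASSO) used/available
   logistic model of predator selection over sea ice, bathymetry and
   distance to coast, with the penalty chosen by bear-blocked
   cross-validation, emits daily risk rasters normalised to [0, 1].
3. **Habitat selection** — a used/available resource selection function
   (RSF): one location per seal per day, 25 available points per used point
   from a 30-km-buffered minimum convex polygon clipped to water, a
   9-model + null candidate set over {ice, prey, risk} including the
   prey × risk interaction, AICc ranking with the parsimony rule,
   Boyce-style leave-one-individual-out validation, and propagation of
   location error through the posterior track draws.
4. **Move persistence** — a mixed model for directional persistence
   `gamma_t` in (0, 1): `d_t = gamma_t d_{t-1} + e_t` with
   `logit(gamma_t) = x_t' beta + b_i` and seal-level random intercepts
   (Laplace-integrated), first-order terms only.
5. **Dive behaviour** — dive duration, ascent speed and daily frequency
   from transmitted five-point dive profiles, modelled with Gaussian
   linear mixed models: seal random intercept, AR1 residuals over every
   10th dive, dive depth as a fixed effect, same candidate set and
   ranking.

A synthetic-world generator (`riskscape.synthetic`) produces landscapes,
predator use, seal tracks, Argos noise and dives from known parameters, so
every stage is validated by parameter recovery (see `riskscape.validation`
and `docs/methods.md`).

## The models in brief

- CTCRW: `dv = -beta_mov v dt + sigma_mov dW`, position integrates
  velocity; observations `z_t = x_t + eps`, `eps ~ N(0, sd_class^2)`.
- RSF: `logit P(used) = beta_0 + x' beta`; relative selection intensity
  `w(x) = exp(x' beta)`; `AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)`.
- Move persistence: `d_t = gamma_t d_{t-1} + e_t`,
  `logit(gamma_t) = x_t' beta + b_i`, `b_i ~ N(0, sigma_b^2)`.
- Dive LMM: `y_it = x_it' beta + b_i + e_it`, `cov(e_i) = sigma_e^2 R(phi)`
  with `R` AR1 over the thinned dive sequence.
- Prey diversity: Gini–Simpson `D = 1 - sum p_i^2`.

## Worked example

Simulate a 12-seal, 45-day world, build the used/available table, fit and
rank the candidate RSFs, and cross-validate:

```python
from riskscape.validation import build_world, rsf_table_from_world
from riskscape.rsf import fit_candidate_set, loio_cross_validate

cfg, stack = build_world(7, n_seals=12, n_days=45)
data = rsf_table_from_world(cfg, stack, 8)
ranking, fits = fit_candidate_set(data)
print(ranking.head(3).to_string(index=False))
best = ranking.loc[ranking["selected"], "model"].iloc[0]
print(fits[best].summary())
cv = loio_cross_validate(data, fits[best].model.terms)
print(f"LOIO mean Spearman rho: {cv['rho'].mean():.3f}")
```

prints

```
        model  k        aicc  delta_aicc  selected
ice+prey*risk  6 4051.325676    0.000000      True
     ice+prey  4 4070.715699   19.390023     False
ice+prey+risk  5 4072.708357   21.382681     False

Resource selection function (ice+prey*risk)
  n=14040  k=6  logLik=-2019.66  AICc=4051.33
  term              coef        se      2.5%     97.5%
  intercept      -4.7515    0.3991   -5.5336   -3.9694
  bathymetry     -0.0071    0.0013   -0.0096   -0.0045
  ice             0.0235    0.0025    0.0186    0.0284
  prey            2.1737    0.6073    0.9833    3.3641
  risk           -3.7736    0.9264   -5.5893   -1.9580
  prey:risk       7.9634    1.6766    4.6773   11.2495

LOIO mean Spearman rho: 0.902
```

The interaction model is top-ranked and its coefficients recover the
world's generative truth (bathymetry −0.008, ice +0.025, prey +2,
risk −4, prey × risk +8) within the Wald intervals: seals avoid risky
areas, but high prey diversity offsets high risk — and held-out
individuals' used locations concentrate in the predicted high-selection
bins (mean Spearman rho 0.90 across seals).

There is also a CLI for the file-based workflow:

```sh
riskscape simulate --out demo --seed 1 --n-seals 5 --n-days 30
riskscape fit-ssm --tracks demo/argos_tracks.csv --out demo/predicted.csv
riskscape run --out demo-run --seed 1
```

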