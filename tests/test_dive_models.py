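"""Dive metric derivation, thinning, and the AR1 random-intercept LMM."""

import numpy as np
import pandas as pd
import pytest

from riskscape.dive import (Ar1MixedModel, daily_frequency_table,
                            derive_dive_metrics, fit_dive_candidates,
                            thin_every_kth)
from riskscape.synthetic import TruthParams, simulate_dive_metrics
from riskscape.validation import dense_ar1_lmm_nll


def dive_rows(truth, n_seals, n, rng):
    rows = []
    for i in range(n_seals):
        df = pd.DataFrame({"animal_id": f"s{i:02d}",
                           "ice": rng.uniform(0, 100, n),
                           "prey": rng.uniform(0.1, 0.8, n),
                           "risk": rng.uniform(0, 1, n)})
        rows.append(simulate_dive_metrics(df, truth, rng,
                                          bathymetry=rng.uniform(50, 250, n)))
    return pd.concat(rows, ignore_index=True)


class TestDeriveMetrics:
    def test_ascent_speed_arithmetic(self):
        # last point 50 m at 90% of a 250-s dive -> 50 / 25 = 2 m/s
        d = pd.DataFrame({"animal_id": "a", "duration_s": [250.0],
                          "max_depth": [60.0], "d5": [50.0], "p5": [90.0],
                          "d1": [30.], "d2": [50.], "d3": [60.], "d4": [55.],
                          "p1": [10.], "p2": [30.], "p3": [50.], "p4": [70.],
                          "datetime": pd.to_datetime(["2011-01-01"])})
        out = derive_dive_metrics(d)
        assert out["ascent_speed"].iloc[0] == pytest.approx(2.0)

    def test_terminal_percentage_dropped(self):
        d = pd.DataFrame({"animal_id": "a", "duration_s": [250.0, 100.0],
                          "max_depth": [60.0, 40.0], "d5": [50.0, 30.0],
                          "p5": [100.0, 90.0],
                          "datetime": pd.to_datetime(["2011-01-01"] * 2)})
        out = derive_dive_metrics(d)
        assert len(out) == 1

    def test_round_trip_recovers_generated_ascent(self, rng):
        truth = TruthParams()
        rows = dive_rows(truth, 2, 200, rng)
        derived = derive_dive_metrics(rows)
        assert np.allclose(derived["ascent_speed"],
                           derived["true_ascent_speed"], atol=1e-9)

    def test_zero_dive_days_recorded(self):
        d = pd.DataFrame({"animal_id": "a",
                          "datetime": pd.to_datetime(["2011-01-01 03:00",
                                                      "2011-01-03 06:00"])})
        tab = daily_frequency_table(
            d, tracked_days={"a": ["2011-01-01", "2011-01-02", "2011-01-03"]})
        assert len(tab) == 3
        assert tab.set_index(tab["date"].dt.day)["frequency"].to_dict() == \
            {1: 1, 2: 0, 3: 1}


class TestThinning:
    def test_every_tenth_one_based(self):
        rows = pd.DataFrame({"animal_id": "a", "v": range(25)})
        out = thin_every_kth(rows, 10)
        assert out["v"].tolist() == [9, 19]   # 1-based indices 10 and 20

    def test_k_one_identity(self):
        rows = pd.DataFrame({"animal_id": "a", "v": range(7)})
        pd.testing.assert_frame_equal(thin_every_kth(rows, 1), rows)

    def test_retained_count_floor(self):
        for n in range(1, 101):
            rows = pd.DataFrame({"animal_id": "a", "v": range(n)})
            assert len(thin_every_kth(rows, 10)) == n // 10

    def test_order_preserved_per_seal(self):
        rows = pd.DataFrame({"animal_id": ["a"] * 30 + ["b"] * 30,
                             "v": list(range(30)) * 2})
        out = thin_every_kth(rows, 10)
        assert out.groupby("animal_id")["v"].apply(
            lambda s: s.is_monotonic_increasing).all()


class TestAr1Lmm:
    def test_likelihood_matches_dense_mvn(self, rng):
        truth = TruthParams()
        rows = dive_rows(truth, 3, 6, rng)
        m = Ar1MixedModel(rows, "duration_s", ("ice", "prey"))
        for _ in range(5):
            beta = rng.normal(0, 1, m.p)
            phi = float(rng.uniform(-0.8, 0.8))
            sb, se = float(rng.uniform(1, 20)), float(rng.uniform(5, 40))
            assert m.nloglik(beta, phi, sb, se) == pytest.approx(
                dense_ar1_lmm_nll(m, beta, phi, sb, se), abs=1e-8)

    def test_iid_limit_matches_ols(self, rng):
        """At phi = 0 and vanishing random-intercept variance the GLS
        profile collapses to ordinary least squares."""
        truth = TruthParams(dive_phi=0.0,
                            dive_sigma_b={"duration": 0.0, "ascent_speed": 0.0})
        rows = dive_rows(truth, 8, 150, rng)
        m = Ar1MixedModel(rows, "duration_s",
                          ("ice", "prey", "risk", "prey:risk"))
        beta, *_ = m._profile(0.0, 1e-9, 30.0)
        X = np.column_stack([np.ones(len(rows)), rows["max_depth"],
                             rows["ice"], rows["prey"], rows["risk"],
                             rows["prey"] * rows["risk"]])
        ols = np.linalg.lstsq(X, rows["duration_s"], rcond=None)[0]
        assert np.max(np.abs(beta - ols)) < 1e-3
        # and the freely fitted variance parameters sit near the boundary
        fit = m.fit()
        assert abs(fit.phi) < 0.1
        assert fit.sigma_b < 5.0

    def test_parameter_recovery(self, rng):
        truth = TruthParams()
        rows = dive_rows(truth, 20, 150, rng)
        fit = Ar1MixedModel(rows, "duration_s",
                            ("ice", "prey", "risk", "prey:risk")).fit()
        assert abs(fit.phi - truth.dive_phi) / truth.dive_phi < 0.2
        assert abs(fit.sigma_e - truth.dive_sigma_e["duration"]) \
            / truth.dive_sigma_e["duration"] < 0.15

    def test_whitening_removes_lag1_autocorrelation(self, rng):
        truth = TruthParams()
        rows = dive_rows(truth, 5, 1000, rng)
        fit = Ar1MixedModel(rows, "duration_s",
                            ("ice", "prey", "risk", "prey:risk")).fit()
        w = fit.whitened_residuals()
        r1 = np.corrcoef(w[:-1], w[1:])[0, 1]
        assert abs(r1) < 0.05

    def test_too_few_seals_rejected(self):
        rows = pd.DataFrame({"animal_id": "a", "duration_s": [1.0, 2.0],
                             "max_depth": [5.0, 6.0], "ice": [0.0, 1.0],
                             "prey": [0.1, 0.2], "risk": [0.3, 0.4]})
        with pytest.raises(ValueError):
            Ar1MixedModel(rows, "duration_s")


class TestDiveCandidates:
    def test_interaction_truth_selected(self, rng):
        truth = TruthParams()
        rows = dive_rows(truth, 12, 120, rng)
        table, fits = fit_dive_candidates(rows, "duration_s")
        best = table.loc[table["selected"], "model"].iloc[0]
        assert "prey*risk" in best

    def test_null_truth_keeps_null_close(self, rng):
        truth = TruthParams(dive_beta={
            "duration": (180.0, 0.5, 0.0, 0.0, 0.0, 0.0),
            "ascent_speed": (1.2, 0.004, 0.0, 0.0, 0.0, 0.0)})
        ok = 0
        for _ in range(3):
            rows = dive_rows(truth, 8, 60, rng)
            table, _ = fit_dive_candidates(rows, "duration_s")
            ok += bool(table.loc[table["model"] == "null",
                                 "delta_aicc"].iloc[0] <= 2.0)
        assert ok >= 2

    def test_aicc_consistent_with_formula(self, rng):
        from riskscape.model_selection import aicc
        truth = TruthParams()
        rows = dive_rows(truth, 6, 40, rng)
        table, fits = fit_dive_candidates(rows, "duration_s")
        for f in fits.values():
            assert f.aicc == pytest.approx(aicc(f.loglik, f.k, f.n))

    def test_qualitative_interaction_pattern(self, rng):
        """Fitted duration rises with prey diversity at high risk and falls
        at low risk when generated so."""
        truth = TruthParams(dive_beta={
            "duration": (180.0, 0.5, 0.0, -60.0, -40.0, 150.0),
            "ascent_speed": (1.2, 0.004, 0.0, 0.0, 0.0, 0.0)})
        rows = dive_rows(truth, 12, 150, rng)
        fit = Ar1MixedModel(rows, "duration_s",
                            ("ice", "prey", "risk", "prey:risk")).fit()
        b = fit.params
        depth = rows["max_depth"].mean()
        ice = rows["ice"].mean()

        def pred(prey, risk):
            return (b["intercept"] + b["max_depth"] * depth + b["ice"] * ice
                    + b["prey"] * prey + b["risk"] * risk
                    + b["prey:risk"] * prey * risk)

        assert pred(0.8, 0.9) > pred(0.1, 0.9)   # rising at high risk
        assert pred(0.8, 0.05) < pred(0.1, 0.05)  # falling at low risk
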