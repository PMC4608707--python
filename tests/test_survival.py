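"""Interval construction, Kaplan-Meier with delayed entry, log-rank,
Cox-frailty fitting against independent oracles, deviance ranking."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy import stats

from fawnscape.coxfrailty import fit_cox_frailty
from fawnscape.survival import (
    SUITE_MODELS,
    build_intervals,
    deviance_explained,
    km_fit,
    logrank,
    run_suite,
)
from tests.conftest import make_cox_data


# ------------------------------------------------------------ oracle: Cox
def newton_cox_oracle(start, stop, event, X, max_iter=200):
    """Independent plain-Cox fit: explicit risk-set loops, Efron ties,
    Newton iteration on the analytic score and information."""
    n, p = X.shape
    beta = np.zeros(p)
    times = np.unique(stop[event == 1])
    for _ in range(max_iter):
        eta = X @ beta
        w = np.exp(eta)
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for t in times:
            risk = (start < t) & (t <= stop)
            dead = (stop == t) & (event == 1)
            dk = dead.sum()
            s0 = w[risk].sum()
            s1 = (w[risk, None] * X[risk]).sum(axis=0)
            s2 = (X[risk] * w[risk, None]).T @ X[risk]
            s0d = w[dead].sum()
            s1d = (w[dead, None] * X[dead]).sum(axis=0)
            s2d = (X[dead] * w[dead, None]).T @ X[dead]
            grad += X[dead].sum(axis=0)
            for j in range(dk):
                f = j / dk
                den = s0 - f * s0d
                num = s1 - f * s1d
                grad -= num / den
                info += (s2 - f * s2d) / den - np.outer(num, num) / den**2
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


class TestCoxAgainstOracles:
    def test_matches_newton_partial_likelihood_oracle(self):
        for seed in range(5):
            iv = make_cox_data(seed, n=200)
            fit = fit_cox_frailty(iv, ["x"], variances={"fawn_id": 0, "year": 0})
            want = newton_cox_oracle(
                iv["start"].to_numpy(), iv["stop"].to_numpy(),
                iv["event"].to_numpy(), iv[["x"]].to_numpy())
            assert np.allclose(fit.coef, want, atol=1e-6)

    def test_matches_lifelines_with_delayed_entry(self):
        from lifelines import CoxTimeVaryingFitter
        iv = make_cox_data(3, n=400)
        rng = np.random.default_rng(0)
        iv["start"] = np.floor(rng.uniform(0, 3, len(iv)))
        iv = iv[iv["start"] < iv["stop"]]
        fit = fit_cox_frailty(iv, ["x"], random=())
        ctv = CoxTimeVaryingFitter().fit(
            iv[["start", "stop", "event", "x"]],
            start_col="start", stop_col="stop", event_col="event")
        assert fit.coef[0] == pytest.approx(ctv.params_.iloc[0], abs=1e-6)
        assert fit.se[0] == pytest.approx(ctv.standard_errors_.iloc[0], rel=1e-4)

    def test_binary_covariate_recovery(self):
        # enough events that the estimate sits within +-0.15 of the truth
        iv = make_cox_data(11, n=900, beta=0.7, binary=True, tied_days=True)
        assert iv["event"].sum() >= 500
        fit = fit_cox_frailty(iv, ["x"], random=())
        assert abs(fit.coef[0] - 0.7) < 0.15

    def test_location_shift_invariance_and_scaling(self):
        iv = make_cox_data(5, n=300)
        fit = fit_cox_frailty(iv, ["x"], random=())
        shifted = iv.assign(x=iv["x"] + 5.0)
        scaled = iv.assign(x=iv["x"] * 2.0)
        f_sh = fit_cox_frailty(shifted, ["x"], random=())
        f_sc = fit_cox_frailty(scaled, ["x"], random=())
        assert f_sh.coef[0] == pytest.approx(fit.coef[0], abs=1e-6)
        assert f_sc.coef[0] == pytest.approx(fit.coef[0] / 2.0, abs=1e-6)

    def test_hazard_ratio_is_exp_coef(self):
        iv = make_cox_data(6, n=250)
        fit = fit_cox_frailty(iv, ["x"], random=())
        assert np.allclose(fit.hazard_ratios, np.exp(fit.coef), atol=1e-9)

    def test_frailty_recovers_cluster_variance(self):
        iv = make_cox_data(7, n=1200, frailty_var=0.5, n_groups=60)
        fit = fit_cox_frailty(iv, ["x"])
        assert 0.15 < fit.variances["fawn_id"] < 1.2
        assert abs(fit.coef[0] - 0.7) < 0.2

    def test_needs_an_event(self):
        iv = make_cox_data(8, n=50)
        iv["event"] = 0
        with pytest.raises(ValueError, match="event"):
            fit_cox_frailty(iv, ["x"], random=())


# ------------------------------------------------------------ intervals
class TestBuildIntervals:
    def _study(self):
        fawns = pd.DataFrame({"fawn_id": [1, 2], "year": 2009,
                              "birth_doy": [0, 10], "birth_mass_kg": [3.0, 4.0]})
        fates = pd.DataFrame({"fawn_id": [1, 2], "year": 2009,
                              "fate_doy": [9, 40], "event": [1, 0]})
        tel = pd.DataFrame({
            "fawn_id": [1, 1, 1, 2],
            "doy": [0, 3, 7, 20],
            "use": [0.5, 0.6, 0.7, 0.2],
        })
        return fawns, fates, tel

    def test_daily_interval_construction(self):
        fawns, fates, tel = self._study()
        iv = build_intervals(fawns, fates, tel, ["use"], mode="daily")
        f1 = iv[iv["fawn_id"] == 1]
        assert list(zip(f1["start"], f1["stop"])) == [(0, 3), (3, 7), (7, 9)]
        assert list(f1["use"]) == [0.5, 0.6, 0.7]
        assert list(f1["event"]) == [0, 0, 1]

    def test_single_relocation_censored(self):
        fawns, fates, tel = self._study()
        iv = build_intervals(fawns, fates, tel, ["use"], mode="daily")
        f2 = iv[iv["fawn_id"] == 2]
        assert list(zip(f2["start"], f2["stop"], f2["event"])) == [
            (10, 20, 0), (20, 40, 0)]

    def test_seasonal_mean_matches_oracle(self):
        fawns, fates, tel = self._study()
        iv = build_intervals(fawns, fates, tel, ["use"], mode="seasonal")
        f1 = iv[iv["fawn_id"] == 1].iloc[0]
        assert f1["use"] == pytest.approx(np.mean([0.5, 0.6, 0.7]))
        assert (f1["start"], f1["stop"], f1["event"]) == (0, 9, 1)

    def test_relocation_after_fate_rejected(self):
        fawns, fates, tel = self._study()
        tel.loc[len(tel)] = {"fawn_id": 1, "doy": 50, "use": 0.9}
        iv = build_intervals(fawns, fates, tel, ["use"], mode="daily")
        assert iv.attrs["n_rejected"] == 1
        assert iv[iv["fawn_id"] == 1]["stop"].max() == 9


# ------------------------------------------------------------ Kaplan-Meier
class TestKaplanMeier:
    def test_product_limit_drop(self):
        iv = pd.DataFrame({"start": [0, 0, 0], "stop": [5, 8, 8],
                           "event": [1, 0, 0]})
        km = km_fit(iv)[None]
        assert km.at(5)[0] == pytest.approx(2 / 3)

    def test_no_events_flat_one(self):
        iv = pd.DataFrame({"start": [0, 0], "stop": [5, 8], "event": [0, 0]})
        km = km_fit(iv)[None]
        assert km.at(10)[0] == 1.0 and km.at(10)[1] == 0.0

    def test_survival_nonincreasing_from_one(self):
        iv = make_cox_data(2, n=150)
        km = km_fit(iv)[None]
        assert km.at(0)[0] == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_delayed_entry_reduces_to_classical(self):
        iv = make_cox_data(4, n=200)
        km = km_fit(iv)[None]
        kmf = KaplanMeierFitter().fit(iv["stop"], iv["event"])
        for t in km.times:
            assert km.at(t)[0] == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)

    def test_matches_lifelines_with_entry(self):
        iv = make_cox_data(9, n=300)
        rng = np.random.default_rng(1)
        iv["start"] = np.floor(rng.uniform(0, 4, len(iv)))
        iv = iv[iv["start"] < iv["stop"]]
        km = km_fit(iv)[None]
        kmf = KaplanMeierFitter().fit(iv["stop"], iv["event"], entry=iv["start"])
        for t in km.times:
            assert km.at(t)[0] == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)


# ------------------------------------------------------------ log-rank
class TestLogrank:
    def test_cloned_groups_zero(self):
        iv = make_cox_data(1, n=80)
        iv2 = pd.concat([iv.assign(year=0), iv.assign(year=1)], ignore_index=True)
        out = logrank(iv2, by="year")
        assert out["chi2"] == pytest.approx(0.0, abs=1e-10)

    def test_two_group_hand_computation(self):
        # 5 vs 5 subjects, all entries at 0, distinct death times
        iv = pd.DataFrame({
            "start": 0.0,
            "stop": [2, 4, 6, 8, 10, 1, 3, 5, 7, 9],
            "event": [1, 1, 0, 1, 0, 1, 1, 1, 0, 1],
            "grp": [0] * 5 + [1] * 5,
        })
        out = logrank(iv, by="grp")
        # hand computation over the shared risk sets
        o_minus_e, var = 0.0, 0.0
        for t in sorted(iv.loc[iv.event == 1, "stop"]):
            risk = iv["stop"] >= t
            n = risk.sum()
            n0 = (risk & (iv["grp"] == 0)).sum()
            d = ((iv["stop"] == t) & (iv["event"] == 1)).sum()
            d0 = ((iv["stop"] == t) & (iv["event"] == 1) & (iv["grp"] == 0)).sum()
            o_minus_e += d0 - d * n0 / n
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / max(n - 1, 1)
        assert out["chi2"] == pytest.approx(o_minus_e**2 / var, abs=1e-10)
        assert out["df"] == 1

    def test_relabeling_invariance(self):
        iv = make_cox_data(10, n=120)
        out1 = logrank(iv, by="year")
        relabeled = iv.assign(year=iv["year"].map({0: "c", 1: "a", 2: "b"}))
        out2 = logrank(relabeled, by="year")
        assert out1["chi2"] == pytest.approx(out2["chi2"], abs=1e-10)
        assert out1["df"] == out2["df"] == 2

    def test_single_group_rejected(self):
        iv = make_cox_data(1, n=40)
        iv["year"] = 0
        with pytest.raises(ValueError, match="2 groups"):
            logrank(iv, by="year")


# ------------------------------------------------------------ ranking
class TestDevianceExplained:
    def test_null_against_itself_zero(self):
        iv = make_cox_data(1, n=200)
        fit = fit_cox_frailty(iv, [], random=())
        out = deviance_explained(fit)
        assert out["deviance_explained"] == pytest.approx(0.0, abs=1e-9)

    def test_chi2_twice_deviance(self):
        iv = make_cox_data(2, n=200)
        fit = fit_cox_frailty(iv, ["x"], random=())
        out = deviance_explained(fit)
        assert out["chi2"] == pytest.approx(2 * out["deviance_explained"], abs=1e-12)

    def test_null_chi2_within_reference_distribution(self):
        """On null data the LR chi-square should look like chi2(df=1)."""
        chis = []
        for seed in range(40):
            iv = make_cox_data(100 + seed, n=120, beta=0.0)
            fit = fit_cox_frailty(iv, ["x"], random=())
            chis.append(2 * (fit.loglik - fit.null_loglik))
        frac = np.mean(np.array(chis) <= stats.chi2.ppf(0.95, 1))
        assert frac >= 0.85  # ~95% expected; tolerate Monte-Carlo noise


def test_suite_contains_seventeen_models():
    assert len(SUITE_MODELS) == 17
    assert "null" in SUITE_MODELS and "non_ideal_use + maternal_effects" in SUITE_MODELS


def test_suite_ranks_informative_model_above_null():
    rng = np.random.default_rng(12)
    n = 500
    iv = make_cox_data(12, n=n, beta=0.0)
    for c in ("resource_use", "predation_risk", "birth_mass", "winter_severity",
              "hiding_cover"):
        iv[c] = rng.normal(size=n)
    # hazard actually driven by birth mass: refresh stop/event accordingly
    lam = 0.05 * np.exp(-0.8 * iv["birth_mass"])
    t = rng.exponential(1 / lam)
    c = rng.uniform(5, 40, n)
    iv["stop"] = np.ceil(np.minimum(t, c))
    iv["event"] = (t <= c).astype(int)
    out = run_suite(iv, outer_sweeps=1)
    assert out.attrs["errors"] == []
    ranks = {m: i for i, m in enumerate(out["model"])}
    assert ranks["birth_mass"] < ranks["null"]
    assert ranks["maternal_effects"] < ranks["null"]
    assert out.iloc[-1]["model"] in ("null", "resource_use", "predation_risk",
                                     "winter_severity", "hiding_cover")
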