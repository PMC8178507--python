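"""Endpoints, eligibility, subsets, quartiles, Cox fits, KM and overall FDR."""

import numpy as np
import pandas as pd
import pytest

import oracles
from piratrue import survival as sv


def clin_row(sid, **kw):
    base = dict(
        sample_id=sid,
        invasive=True,
        in_situ=False,
        metastasis_at_dx=False,
        er="pos",
        pr="pos",
        her2="neg",
        grade="II",
        histology="ductal",
        tumor_size="T1",
        nodal="neg",
        age_at_dx=60.0,
        rt="no",
        ct="no",
        et="no",
        tamoxifen="no",
        dx_date="2000-01-01",
        recurrence_date=None,
        death_date=None,
        death_cause="alive",
        last_followup_date=None,
    )
    base.update(kw)
    return base


CENSOR = "2010-01-01"  # day 3653 from dx


class TestEndpoints:
    def test_other_cause_death(self):
        clin = pd.DataFrame(
            [clin_row("a", death_date="2002-06-19", death_cause="other")]
        )  # day 900
        ep = sv.make_endpoints(clin, CENSOR).set_index("endpoint")
        assert (ep.loc["OS", "time"], ep.loc["OS", "event"]) == (900, 1)
        assert (ep.loc["BCSS", "time"], ep.loc["BCSS", "event"]) == (900, 0)
        assert (ep.loc["RFS", "time"], ep.loc["RFS", "event"]) == (900, 0)

    def test_recurrence_then_bc_death(self):
        clin = pd.DataFrame(
            [
                clin_row(
                    "a",
                    recurrence_date="2001-02-04",  # day 400
                    death_date="2002-03-11",  # day 800
                    death_cause="breast_cancer",
                )
            ]
        )
        ep = sv.make_endpoints(clin, CENSOR).set_index("endpoint")
        assert (ep.loc["RFS", "time"], ep.loc["RFS", "event"]) == (400, 1)
        assert (ep.loc["BCSS", "time"], ep.loc["BCSS", "event"]) == (800, 1)
        assert (ep.loc["OS", "time"], ep.loc["OS", "event"]) == (800, 1)

    def test_alive_censored_at_censor_date(self):
        clin = pd.DataFrame([clin_row("a")])
        ep = sv.make_endpoints(clin, CENSOR)
        assert (ep["event"] == 0).all()
        assert (ep["time"] == 3653).all()

    def test_individual_followup_bounds_censoring(self):
        clin = pd.DataFrame([clin_row("a", last_followup_date="2003-01-01")])
        ep = sv.make_endpoints(clin, CENSOR)
        assert (ep["time"] == 1096).all()

    def test_event_before_diagnosis_errors(self):
        clin = pd.DataFrame([clin_row("a", death_date="1999-12-31", death_cause="other")])
        with pytest.raises(ValueError, match="precedes"):
            sv.make_endpoints(clin, CENSOR)


class TestEligibilityAndSubsets:
    def _clin(self):
        return pd.DataFrame(
            [
                clin_row("inv"),
                clin_row("situ", invasive=False, in_situ=True),
                clin_row("met", metastasis_at_dx=True),
                clin_row("tam", et="yes", tamoxifen="yes"),
                clin_row("tam_ct", et="yes", tamoxifen="yes", ct="yes"),
                clin_row("tam_erneg", er="neg", et="yes", tamoxifen="yes"),
                clin_row("rt_only", rt="yes"),
                clin_row("rt_et", rt="yes", et="yes"),
                clin_row("ct_only", ct="yes"),
                clin_row("surgery"),
            ]
        )

    def test_eligibility(self):
        kept = sv.eligible_cases(self._clin())["sample_id"]
        assert "situ" not in set(kept) and "met" not in set(kept)
        assert "inv" in set(kept)

    def test_tamoxifen_subset(self):
        elig = sv.eligible_cases(self._clin())
        sub, plan = sv.treatment_subset(elig, "tamoxifen_treated")
        assert set(sub["sample_id"]) == {"tam"}  # ER+ tamoxifen, no CT
        assert "er" not in plan and "rt" in plan

    def test_rt_only_subset(self):
        elig = sv.eligible_cases(self._clin())
        sub, plan = sv.treatment_subset(elig, "rt_only")
        assert set(sub["sample_id"]) == {"rt_only"}
        assert "rt" not in plan and "ct" not in plan and "et" not in plan

    def test_rt_treated_with_er_restriction(self):
        elig = sv.eligible_cases(self._clin())
        sub, plan = sv.treatment_subset(elig, "rt_treated", er_restrict="pos")
        assert set(sub["sample_id"]) == {"rt_only", "rt_et"}
        assert "er" not in plan and {"ct", "et"} <= set(plan)

    def test_ct_and_surgery_subsets(self):
        elig = sv.eligible_cases(self._clin())
        sub_ct, plan_ct = sv.treatment_subset(elig, "adj_ct_treated")
        assert set(sub_ct["sample_id"]) == {"ct_only"}
        assert "rt" in plan_ct
        sub_s, _ = sv.treatment_subset(elig, "surgery_only")
        assert set(sub_s["sample_id"]) == {"inv", "surgery"}

    def test_unknown_subset_errors(self):
        with pytest.raises(ValueError, match="unknown treatment subset"):
            sv.treatment_subset(self._clin(), "spa_treated")


class TestQuartiles:
    def test_eight_distinct_values(self):
        v = pd.Series({f"s{i}": float(i) for i in range(8)})
        q = sv.assign_quartiles(v)
        assert list(q[[f"s{i}" for i in range(8)]]) == [
            "Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4",
        ]

    def test_n10_sizes_3322(self):
        v = pd.Series({f"s{i:02d}": float(i) for i in range(10)})
        q = sv.assign_quartiles(v)
        assert q.value_counts().to_dict() == {"Q1": 3, "Q2": 3, "Q3": 2, "Q4": 2}
        assert set(q[["s00", "s01", "s02"]]) == {"Q1"}

    def test_all_ties_deterministic_by_sample_id(self):
        v = pd.Series({f"s{i}": 5.0 for i in range(8)})
        q1 = sv.assign_quartiles(v)
        q2 = sv.assign_quartiles(v.sample(frac=1, random_state=3))
        assert q1.sort_index().equals(q2.sort_index())
        assert q1["s0"] == "Q1" and q1["s7"] == "Q4"

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match=">=8"):
            sv.assign_quartiles(pd.Series({"a": 1.0, "b": 2.0}))


def surv_frame(times, events, sids=None):
    sids = sids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"sample_id": sids, "endpoint": "OS", "time": times, "event": events}
    )


class TestCoxUnivariate:
    def test_exchangeable_groups_give_unit_hazard(self):
        times = [5, 8, 12, 20, 30, 40] * 2
        events = [1, 1, 0, 1, 0, 1] * 2
        quart = pd.Series(
            ["Q1"] * 6 + ["Q4"] * 6, index=[f"s{i}" for i in range(12)]
        )
        fit = sv.cox_univariate(surv_frame(times, events), quart)
        assert abs(np.log(fit.terms.loc["Q4", "hr"])) < 1e-6

    def test_eight_subject_fixture_matches_grid_search(self):
        """Q4-heavy early events; betahat vs golden-section Breslow maximizer."""
        times = [5, 8, 12, 20, 25, 33, 47, 60]
        events = [1, 1, 1, 1, 0, 1, 0, 1]
        quart = pd.Series(
            ["Q4", "Q4", "Q4", "Q1", "Q4", "Q1", "Q1", "Q1"],
            index=[f"s{i}" for i in range(8)],
        )
        fit = sv.cox_univariate(surv_frame(times, events), quart)
        x = (quart == "Q4").astype(float).to_numpy()
        beta_star = oracles.grid_maximize_beta(times, events, x)
        assert fit.terms.loc["Q4", "coef"] == pytest.approx(beta_star, abs=1e-4)
        assert fit.terms.loc["Q4", "hr"] == pytest.approx(np.exp(beta_star), rel=1e-3)
        # AIC definition: -2 * log partial likelihood + 2k (k = 1 term)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2)

    def test_overall_p_is_likelihood_ratio_of_quartile_block(self):
        rng = np.random.default_rng(51)
        n = 80
        quart = pd.Series(
            [f"Q{1 + i % 4}" for i in range(n)], index=[f"s{i}" for i in range(n)]
        )
        lam = np.where(quart == "Q4", 5.0, 1.0)
        times = rng.exponential(1.0 / lam)
        fit = sv.cox_univariate(surv_frame(times, [1] * n), quart)
        x = pd.get_dummies(quart)[["Q2", "Q3", "Q4"]].to_numpy(float)
        from scipy.optimize import minimize
        from scipy.stats import chi2

        res = minimize(
            lambda b: -oracles.breslow_loglik_multi(times, [1] * n, x, b),
            np.zeros(3),
            method="BFGS",
        )
        ll0 = oracles.breslow_loglik_multi(times, [1] * n, x, np.zeros(3))
        expected_p = chi2.sf(2 * (-res.fun - ll0), df=3)
        assert fit.overall_p == pytest.approx(expected_p, rel=1e-3, abs=1e-6)

    def test_no_events_errors(self):
        quart = pd.Series(["Q1", "Q4"] * 4, index=[f"s{i}" for i in range(8)])
        with pytest.raises(ValueError, match="no events"):
            sv.cox_univariate(surv_frame(range(1, 9), [0] * 8), quart)

    def test_empty_reference_quartile_errors(self):
        quart = pd.Series(["Q2", "Q4"] * 4, index=[f"s{i}" for i in range(8)])
        with pytest.raises(ValueError, match="Q1"):
            sv.cox_univariate(surv_frame(range(1, 9), [1] * 8), quart)


class TestCoxStepwise:
    def _simulate(self, rng, n, beta_cov=0.0):
        sids = [f"s{i}" for i in range(n)]
        quart = pd.Series([f"Q{1 + i % 4}" for i in range(n)], index=sids)
        age = rng.normal(60, 8, size=n)
        grade = rng.choice(["I", "II", "III"], size=n)
        nodal = rng.choice(["neg", "pos"], size=n)
        x = (nodal == "pos").astype(float)
        lam = 0.01 * np.exp(beta_cov * x)
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(0, 300, size=n)
        clin = pd.DataFrame(
            {
                "sample_id": sids,
                "age_at_dx": age,
                "grade": grade,
                "nodal": nodal,
            }
        )
        surv = surv_frame(np.minimum(t, c), (t <= c).astype(int), sids)
        return surv, quart, clin

    def test_null_covariates_rarely_selected(self):
        picks = 0
        for rep in range(30):
            rng = np.random.default_rng(600 + rep)
            surv, quart, clin = self._simulate(rng, 120, beta_cov=0.0)
            fit = sv.cox_multivariate_stepwise(
                surv, quart, clin, ["age_at_dx", "grade", "nodal"]
            )
            picks += bool(fit.selected_covariates)
        assert picks <= 30 * 0.45  # each null covariate enters w.p. ~ P(chi2 > 2)

    def test_true_covariate_selected_and_matches_exhaustive_best_aic(self):
        from itertools import combinations

        selected = 0
        for rep in range(15):
            rng = np.random.default_rng(700 + rep)
            surv, quart, clin = self._simulate(rng, 150, beta_cov=1.5)
            covs = ["age_at_dx", "grade", "nodal"]
            fit = sv.cox_multivariate_stepwise(surv, quart, clin, covs)
            selected += "nodal" in fit.selected_covariates
            if rep == 0:
                # forward selection reaches the exhaustive best-AIC subset
                best = (np.inf, None)
                df = surv.set_index("sample_id").join(quart.rename("quartile"))
                for k in range(len(covs) + 1):
                    for combo in combinations(covs, k):
                        f = sv.cox_multivariate_stepwise(
                            surv, quart, clin, list(combo)
                        )
                        # force-fit the combo by giving only those candidates
                        aic_all_in = f.aic
                        if aic_all_in < best[0]:
                            best = (aic_all_in, combo)
                assert fit.aic <= best[0] + 1e-6
        assert selected >= 14

    def test_aic_definition(self):
        rng = np.random.default_rng(52)
        surv, quart, clin = self._simulate(rng, 100, beta_cov=1.0)
        fit = sv.cox_multivariate_stepwise(surv, quart, clin, ["nodal"])
        k = len(fit.terms)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * k)

    def test_separation_yields_flagged_fit_not_crash(self):
        # constant event times with a perfectly separating covariate
        sids = [f"s{i}" for i in range(8)]
        quart = pd.Series(["Q1", "Q4"] * 4, index=sids)
        surv = surv_frame([1, 100] * 4, [1, 1] * 4, sids)
        clin = pd.DataFrame({"sample_id": sids, "nodal": ["pos", "neg"] * 4})
        fit = sv.cox_multivariate_stepwise(surv, quart, clin, ["nodal"])
        assert isinstance(fit, sv.CoxFit)  # no exception raised


class TestOverallFdr:
    def _fit(self, p, endpoint="OS", subset="all"):
        return sv.CoxFit(
            terms=pd.DataFrame(),
            overall_p=p,
            aic=0.0,
            n=10,
            n_events=5,
            log_likelihood=0.0,
            endpoint=endpoint,
            subset=subset,
        )

    def test_single_fit_padj_equals_p(self):
        fits = sv.overall_fdr([self._fit(0.02)])
        assert fits[0].overall_p_adj == pytest.approx(0.02)

    def test_hand_bh_within_family(self):
        fits = [self._fit(p) for p in (0.01, 0.04, 0.9)]
        sv.overall_fdr(fits)
        assert [f.overall_p_adj for f in fits] == pytest.approx([0.03, 0.06, 0.9])

    def test_families_adjusted_separately(self):
        fits = [
            self._fit(0.01, endpoint="OS"),
            self._fit(0.01, endpoint="RFS"),
        ]
        sv.overall_fdr(fits)
        assert all(f.overall_p_adj == pytest.approx(0.01) for f in fits)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        sids = ["a", "b", "c", "d"]
        groups = pd.Series(["Q1", "Q1", "Q4", "Q4"], index=sids)
        curves, p, pairwise = sv.kaplan_meier(
            surv_frame([10, 20, 30, 40], [0, 0, 0, 0], sids), groups
        )
        for c in curves.values():
            assert (c["survival"] == 1.0).all()

    def test_product_limit_by_hand(self):
        sids = ["a", "b"]
        groups = pd.Series(["g", "g"], index=sids)
        curves, _, _ = sv.kaplan_meier(surv_frame([1, 2], [1, 1], sids), groups)
        c = curves["g"].set_index("time")["survival"]
        hand = dict(oracles.km_by_hand([1, 2], [1, 1]))
        assert c.loc[1.0] == pytest.approx(hand[1.0]) == 0.5
        assert c.loc[2.0] == pytest.approx(hand[2.0]) == 0.0

    def test_km_matches_hand_on_censored_mix(self):
        rng = np.random.default_rng(53)
        times = rng.integers(1, 50, size=40).astype(float)
        events = rng.integers(0, 2, size=40)
        sids = [f"s{i}" for i in range(40)]
        groups = pd.Series(["g"] * 40, index=sids)
        curves, _, _ = sv.kaplan_meier(surv_frame(times, events, sids), groups)
        c = curves["g"].set_index("time")["survival"]
        for t, s in oracles.km_by_hand(times, events):
            assert c.loc[t] == pytest.approx(s)

    def test_identical_groups_logrank_near_one(self):
        times = [3, 6, 9, 12, 15, 18] * 2
        events = [1, 0, 1, 1, 0, 1] * 2
        sids = [f"s{i}" for i in range(12)]
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=sids)
        _, p, pairwise = sv.kaplan_meier(surv_frame(times, events, sids), groups)
        assert p > 0.95
        assert pairwise["B"] > 0.95
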