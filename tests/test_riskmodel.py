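"""Univariate screen, LASSO selection and multivariate logistic modelling."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from faerspv import faers_io, riskmodel, synth
from faerspv.errors import InsufficientDataError
from faerspv.riskmodel import (
    bonferroni,
    build_design,
    lasso_select,
    multivariate_logistic,
    univariate_screen,
)


class TestBonferroni:
    def test_single_test_identity(self):
        assert bonferroni([0.001]) == [0.001]

    def test_multiplies_by_family_size(self):
        assert bonferroni([0.001], m=50) == [0.05]

    def test_caps_at_one(self):
        assert bonferroni([0.5, 0.2], m=3) == pytest.approx([1.0, 0.6])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=100)
    def test_never_decreases(self, ps):
        assert all(adj >= p for p, adj in zip(ps, bonferroni(ps)))


def _design_from_counts(a, b, c, d):
    """Report-level design frame realising a given drug-by-outcome 2x2."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)]).astype(int)
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]).astype(int)
    return pd.DataFrame({"case": y, "drugx": x})


class TestUnivariateScreen:
    def test_protective_drug_fails_screen(self):
        design = _design_from_counts(5, 500, 200, 2000)
        (res,) = univariate_screen(design, ["drugx"])
        assert res.ror < 1 and not res.passes_screen

    def test_zero_cell_flagged_non_estimable(self):
        design = _design_from_counts(0, 100, 50, 1000)
        (res,) = univariate_screen(design, ["drugx"])
        assert not res.estimable and not res.passes_screen

    def test_closed_form_matches_iterative_logistic(self):
        design = _design_from_counts(40, 160, 100, 1700)
        (res,) = univariate_screen(design, ["drugx"])
        fit = sm.Logit(
            design["case"], sm.add_constant(design[["drugx"]].astype(float))
        ).fit(disp=0)
        assert math.log(res.ror) == pytest.approx(fit.params["drugx"], rel=1e-5)
        assert res.p_raw == pytest.approx(float(fit.pvalues["drugx"]), rel=1e-3)

    def test_injected_drugs_pass_screen(self, recovery_run):
        screen = univariate_screen(recovery_run["design"], recovery_run["injected"])
        assert all(s.passes_screen for s in screen)
        assert all(s.case_count > 100 for s in screen)

    def test_invariant_to_column_order(self, recovery_run):
        drugs = recovery_run["injected"] + recovery_run["nulls"]
        fwd = univariate_screen(recovery_run["design"], drugs)
        rev = univariate_screen(recovery_run["design"], list(reversed(drugs)))
        assert {s.drug for s in fwd if s.passes_screen} == {
            s.drug for s in rev if s.passes_screen
        }

    def test_null_drug_rarely_passes(self):
        """A 150-case null drug passes the screen in <5% of 200 replicates."""
        rng = np.random.default_rng(77)
        n_exposed, n_other, p = 7500, 42_500, 0.02
        passes = 0
        for _ in range(200):
            a = int(rng.binomial(n_exposed, p))
            c = int(rng.binomial(n_other, p))
            design = _design_from_counts(a, n_exposed - a, c, n_other - c)
            (res,) = univariate_screen(design, ["drugx"])
            passes += bool(res.passes_screen)
        assert passes / 200 <= 0.05


class TestLassoSelect:
    def _toy_design(self, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        strong = rng.random(n) < 0.2
        noise = rng.random(n) < 0.2
        p = np.where(strong, 0.30, 0.05)
        y = rng.random(n) < p
        return pd.DataFrame(
            {"case": y.astype(int), "strong": strong.astype(int),
             "noise": noise.astype(int), "flat": np.zeros(n, dtype=int)}
        )

    def test_dominant_predictor_selected(self):
        res = lasso_select(self._toy_design(), ["strong", "noise"], seed=1)
        assert "strong" in res.selected

    def test_zero_variance_column_dropped(self):
        res = lasso_select(self._toy_design(), ["strong", "flat"], seed=1)
        assert res.dropped == ["flat"] and "flat" not in res.selected

    def test_requires_two_candidates(self):
        with pytest.raises(InsufficientDataError):
            lasso_select(self._toy_design(), ["strong"], seed=1)

    def test_one_se_rule_penalises_at_least_as_hard(self):
        design = self._toy_design()
        res_min = lasso_select(design, ["strong", "noise"], seed=1, rule="min")
        res_1se = lasso_select(design, ["strong", "noise"], seed=1, rule="1se")
        assert res_1se.c_chosen <= res_min.c_chosen

    def test_deterministic_for_fixed_seed(self, recovery_run):
        drugs = recovery_run["injected"] + recovery_run["nulls"]
        r1 = lasso_select(recovery_run["design"], drugs, seed=1)
        r2 = lasso_select(recovery_run["design"], drugs, seed=1)
        assert r1.selected == r2.selected and r1.c_chosen == r2.c_chosen

    def test_recovers_injected_over_null_drugs(self, recovery_run):
        """All injected drugs survive selection; under the parsimonious
        one-standard-error rule almost no null drug does. (The CV-minimum
        rule also retains every injected drug but, with its characteristically
        flat deviance curve, keeps more null noise.)"""
        drugs = recovery_run["injected"] + recovery_run["nulls"]
        res_min = lasso_select(recovery_run["design"], drugs, seed=1, rule="min")
        assert set(recovery_run["injected"]) <= set(res_min.selected)
        res_1se = lasso_select(recovery_run["design"], drugs, seed=1, rule="1se")
        assert set(recovery_run["injected"]) <= set(res_1se.selected)
        assert len(set(res_1se.selected) & set(recovery_run["nulls"])) <= 2


class TestMultivariateLogistic:
    def test_covariate_free_model_equals_univariate(self):
        design = _design_from_counts(40, 160, 100, 1700)
        (term,) = multivariate_logistic(design, ["drugx"], covariates=())
        (uni,) = univariate_screen(design, ["drugx"])
        assert term.odds_ratio == pytest.approx(uni.ror, rel=1e-5)

    def test_empty_selection_rejected(self):
        with pytest.raises(InsufficientDataError):
            multivariate_logistic(_design_from_counts(5, 5, 5, 5), [])

    def test_recovers_injected_conditional_odds(self, recovery_run):
        """The true-OR-10 drug is estimated within [7, 14] at n=50,000."""
        terms = multivariate_logistic(recovery_run["design"], recovery_run["injected"])
        by_name = {t.term: t for t in terms}
        assert 7 <= by_name["riskdrug05"].odds_ratio <= 14
        assert by_name["riskdrug05"].significant

    def test_confounded_null_drug_adjusted_away(self):
        """A null drug preferentially used in a high-risk age group shows a
        marginal association but no conditional one once age enters."""
        confounded = synth.SynthDrugProfile(
            "confdrug", "L01CF01", 0.05, true_ror=1.0,
            age_group_weights={"65-85": 8.0},
        )
        cfg = synth.SynthConfig(
            n_reports=30_000, drug_profiles=[confounded], seed=21,
            baseline_event_rate=0.02,
            age_event_multiplier={"65-85": 5.0},
            missingness={"age": 0.0, "sex": 0.27, "wt": 0.83, "country": 0.05,
                         "event_dt": 0.10},
        )
        reports, _ = synth.generate(cfg)
        dedup, _ = faers_io.deduplicate(reports)
        faers_io.normalize_drugs(dedup, faers_io.load_atc_table(synth.make_atc_table(cfg)))
        flags = faers_io.extract_cases(dedup, cfg.target_pt)
        design = build_design(dedup, flags, ["confdrug"])
        (marginal,) = univariate_screen(design, ["confdrug"])
        assert marginal.ror > 1.2  # confounding inflates the crude odds ratio
        (term, *_rest) = multivariate_logistic(design, ["confdrug"])
        assert term.term == "confdrug"
        assert not term.significant

    def test_mean_log_or_bias_small_across_seeds(self):
        """Mean bias of the injected log-ORs stays within 10% of truth."""
        from conftest import injected_null_config

        biases = []
        for seed in range(2, 7):
            cfg = injected_null_config(seed=seed)
            reports, _ = synth.generate(cfg)
            dedup, _ = faers_io.deduplicate(reports)
            faers_io.normalize_drugs(
                dedup, faers_io.load_atc_table(synth.make_atc_table(cfg))
            )
            flags = faers_io.extract_cases(dedup, cfg.target_pt)
            injected = [p for p in cfg.drug_profiles if p.true_ror > 1]
            design = build_design(dedup, flags, [p.name for p in injected])
            terms = multivariate_logistic(design, [p.name for p in injected])
            by_name = {t.term: t for t in terms}
            for p in injected:
                est = math.log(by_name[p.name].odds_ratio)
                truth = math.log(p.true_ror)
                biases.append((est - truth) / truth)
        assert abs(np.mean(biases)) <= 0.10
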