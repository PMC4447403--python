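"""Survival arm: subtype rules, scoring, cutoff scan, KM, logrank, Cox."""

import warnings

import numpy as np
import pandas as pd
import pytest

from emstate import (
    SyntheticSpec,
    classify_subtype,
    cox_hr,
    evaluate_signature_survival,
    generate_cohort,
    generate_two_group_cohort,
    kaplan_meier,
    logrank_test,
    score_signature,
    select_best_cutoff,
)
from emstate.errors import DegenerateCohortError, InvalidInputError, NoOverlapError


class TestClassifySubtype:
    @pytest.mark.parametrize(
        "esr,mki67,her2,expected",
        [
            (600, 300, 1000, "luminalA"),
            (600, 300, 5000, "luminalB"),  # ESR+, HER2+
            (600, 900, 1000, "luminalB"),  # ESR+, HER2-, MKI67 high
            (100, 900, 100, "basal"),
            (100, 300, 6000, "HER2"),
            (500, 470, 4800, "basal"),  # exactly at cutoffs: strict > means negative
        ],
    )
    def test_rule_table(self, esr, mki67, her2, expected):
        assert classify_subtype(esr, mki67, her2) == expected

    def test_missing_probe_unclassified_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_subtype(600, None, 1000) == "unclassified"

    def test_negative_probe_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_subtype(-1, 300, 1000)

    def test_complete_probes_partition_into_four_labels(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            lab = classify_subtype(*rng.uniform(0, 10000, 3))
            assert lab in ("luminalA", "luminalB", "basal", "HER2")


class TestScoreSignature:
    def test_constant_profile_scores_that_constant(self):
        assert score_signature({"a": 1.0, "b": 1.0}, ["a", "b"]) == 1.0

    def test_mean_of_two_genes(self):
        assert score_signature({"a": 2.0, "b": 4.0}, ["a", "b"]) == 3.0

    def test_missing_genes_mean_over_present_with_warning(self):
        profile = pd.Series({f"g{i}": float(i) for i in range(55)})
        sig = [f"g{i}" for i in range(60)]
        with pytest.warns(UserWarning, match="missing"):
            s = score_signature(profile, sig)
        assert s == pytest.approx(np.mean(range(55)))

    def test_zero_overlap_is_an_error(self):
        with pytest.raises(NoOverlapError):
            score_signature({"a": 1.0}, ["zzz"])


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        s = km.set_index("time")["survival"]
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2: S(1) = 2/3, S(3) = 0
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        s = km.set_index("time")["survival"]
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 50)
        km = kaplan_meier(t, np.ones(50))
        for time, surv in zip(km["time"][1:], km["survival"][1:]):
            assert surv == pytest.approx((t > time).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_give_zero_chi2(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_risk_table_oracle(self):
        # A events at 1,2; B events at 3,4 -> chi2 = 49/17 from the O-E/V table
        chi2, p = logrank_test([1.0, 2.0], [1, 1], [3.0, 4.0], [1, 1])
        assert chi2 == pytest.approx(49 / 17)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(5, 30), rng.exponential(9, 25)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        assert logrank_test(ta, ea, tb, eb) == pytest.approx(
            logrank_test(tb, eb, ta, ea)
        )

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(3)
        for _ in range(5):
            ta, tb = rng.exponential(5, 40), rng.exponential(10, 35)
            ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 35)
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = ll(ta, tb, ea, eb)
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_power_against_hr2(self):
        hits = 0
        for seed in range(200):
            g, t, e = generate_two_group_cohort(300, 2.0, seed=seed)
            _, p = logrank_test(t[g == 0], e[g == 0], t[g == 1], e[g == 1])
            hits += p < 0.05
        assert hits / 200 > 0.8

    def test_zero_events_rejected(self):
        with pytest.raises(DegenerateCohortError):
            logrank_test([1.0], [0], [2.0], [0])


class TestCox:
    def test_identical_groups_hr_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        e = np.ones(10)
        g = np.array([0.0] * 5 + [1.0] * 5)
        # same event pattern in both groups
        hr, lo, hi, _ = cox_hr(g, t, e)
        assert hr == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_large_cohort(self):
        g, t, e = generate_two_group_cohort(1000, 2.0, seed=12)
        hr, lo, hi, flagged = cox_hr(g, t, e)
        assert 1.7 <= hr <= 2.3
        assert not flagged

    def test_ci_always_contains_hr(self):
        for seed in range(20):
            g, t, e = generate_two_group_cohort(80, 1.5, seed=seed)
            hr, lo, hi, _ = cox_hr(g, t, e)
            assert lo <= hr <= hi

    def test_matches_lifelines_breslow(self):
        from lifelines import CoxPHFitter

        for seed in range(3):
            g, t, e = generate_two_group_cohort(200, 2.0, seed=seed)
            hr, lo, hi, _ = cox_hr(g, t, e)
            cph = CoxPHFitter()
            cph.fit(pd.DataFrame({"t": t, "e": e, "x": g}), "t", "e")
            assert hr == pytest.approx(float(np.exp(cph.params_.iloc[0])), rel=1e-6)
            ref_ci = np.exp(cph.confidence_intervals_.iloc[0].to_numpy())
            assert lo == pytest.approx(ref_ci[0], rel=1e-5)
            assert hi == pytest.approx(ref_ci[1], rel=1e-5)

    def test_complete_separation_flagged_not_crashed(self):
        # all events in group 1, none in group 0
        t = np.concatenate([np.full(10, 50.0), np.linspace(1, 10, 10)])
        e = np.concatenate([np.zeros(10), np.ones(10)])
        g = np.concatenate([np.zeros(10), np.ones(10)])
        hr, lo, hi, flagged = cox_hr(g, t, e)
        assert flagged
        assert hr > 100


class TestBestCutoffAndPipeline:
    def test_median_step_cohort_selects_median(self):
        rng = np.random.default_rng(4)
        n = 200
        scores = np.arange(n, dtype=float)
        high = scores > np.quantile(scores, 0.5)
        t = np.where(high, rng.exponential(2, n), rng.exponential(20, n))
        e = np.ones(n)
        q, cut, mask = select_best_cutoff(scores, t, e)
        # oracle: evaluate every candidate directly
        best_direct = min(
            (logrank_test(t[scores <= np.quantile(scores, c)],
                          e[scores <= np.quantile(scores, c)],
                          t[scores > np.quantile(scores, c)],
                          e[scores > np.quantile(scores, c)])[1], c)
            for c in (0.25, 1 / 3, 0.5, 2 / 3, 0.75)
        )[1]
        assert q == best_direct == 0.5

    def test_constant_scores_degenerate(self):
        with pytest.raises(DegenerateCohortError):
            select_best_cutoff(np.ones(20), np.arange(1, 21.0), np.ones(20))

    def test_positive_beta_gives_hr_above_one(self, small_cohort):
        cohort, truth = small_cohort
        fit = evaluate_signature_survival(cohort, truth["signature_genes"])
        assert fit.hr > 1
        assert fit.logrank_p < 0.01

    def test_negative_beta_gives_hr_below_one(self):
        cohort, truth = generate_cohort(SyntheticSpec(seed=8, beta=-0.7))
        fit = evaluate_signature_survival(cohort, truth["signature_genes"])
        assert fit.hr < 1

    def test_null_signature_hr_straddles_one(self, null_cohort):
        cohort, truth = null_cohort
        hrs = []
        for k in range(20):
            genes = list(cohort.genes[10 + 10 * k : 20 + 10 * k])
            hrs.append(evaluate_signature_survival(cohort, genes).hr)
        assert min(hrs) < 1 < max(hrs)

    def test_subtype_filter_restricts_patients(self, small_cohort):
        cohort, truth = small_cohort
        basal = cohort.filter_subtype("basal")
        assert (basal.patients["subtype"] == "basal").all()
        assert len(basal.patients) < len(cohort.patients)
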