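"""Survival, log-rank, hazard-ratio and transition-matrix estimators.

Hand oracles are computed independently inside the tests (explicit
product-limit arithmetic, an observed-minus-expected log-rank loop, a
dense grid search of an independently coded Efron partial likelihood),
and lifelines serves as an external cross-check.  The package codes a
censoring at time t as a loss during the interval ending at t (the
subject is not at risk at t); lifelines keeps censored-at-t subjects at
risk at t, so cross-checks shift censored durations by -0.5 to induce
identical risk sets.
"""

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from dmpacost.cohort import generate_cohort, with_seed
from dmpacost.estimation import (
    EstimationError,
    cumulative_incidence_si,
    estimate_transition_matrix,
    hazard_ratio,
    hazard_ratio_from_times,
    km_continuation,
    logrank_from_times,
    logrank_test,
    mean_days_to_switch,
    product_limit,
    times_and_events,
)
from dmpacost.states import IM, MISSING, NONE, OTHER_METHOD, PA_SC, SI, STATES

from conftest import make_record, small_params

import pandas as pd


def _shift_censor(times, events):
    """Durations for lifelines reproducing the package's risk sets."""
    t = np.asarray(times, float).copy()
    e = np.asarray(events, int)
    t[e == 0] -= 0.5
    return t, e


class TestKaplanMeier:
    def test_hand_product_limit_oracle(self):
        # 5 subjects: events at waves 1, 2; censorings at 2, 3, 4
        curve = product_limit([1, 2, 2, 3, 4], [1, 1, 0, 0, 0])
        assert curve.survival_at(1) == pytest.approx(4 / 5)
        assert curve.survival_at(2) == pytest.approx(4 / 5 * 2 / 3)
        assert curve.survival_at(4) == pytest.approx(8 / 15)
        # Greenwood: S^2 * sum d / (n (n - d))
        expected_var = (8 / 15) ** 2 * (1 / (5 * 4) + 1 / (3 * 2))
        assert curve.variance_at(4) == pytest.approx(expected_var)

    def test_zero_events_survival_stays_one(self):
        records = generate_cohort(
            small_params(hazard_change=0.0, retention_per_wave=0.9, seed=2)
        )
        curve = km_continuation(records, "method_status_change")
        for wave in range(1, 5):
            assert curve.survival_at(wave) == 1.0
            assert curve.variance_at(wave) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        params = small_params(retention_per_wave=1.0, hazard_change=0.3, seed=4)
        records = generate_cohort(params)
        curve = km_continuation(records, "method_status_change")
        times, events = times_and_events(records, "method_status_change")
        for wave in range(1, 5):
            empirical = np.mean((times > wave) | (events == 0))
            assert curve.survival_at(wave) == pytest.approx(empirical)

    def test_all_censored_at_origin_is_no_risk_time(self):
        with pytest.raises(EstimationError, match="no risk time"):
            product_limit([0, 0, 0], [0, 0, 0])

    def test_matches_lifelines_on_study_arm(self, study_cohort):
        subset = [r for r in study_cohort if r.arm == PA_SC]
        curve = km_continuation(subset, "method_status_change")
        t, e = _shift_censor(*times_and_events(subset, "method_status_change"))
        kmf = KaplanMeierFitter().fit(t, e)
        for wave in range(1, 5):
            assert curve.survival_at(wave) == pytest.approx(
                float(kmf.predict(wave)), abs=1e-12
            )


class TestLogrank:
    def test_identical_groups_statistic_zero(self, study_cohort):
        arm = [r for r in study_cohort if r.arm == IM]
        stat, p = logrank_test(arm, list(arm))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        ta, ea = [1, 2, 4], [1, 1, 0]
        tb, eb = [2, 3, 5], [1, 1, 0]
        stat, p = logrank_from_times(ta, ea, tb, eb)

        # independent observed-minus-expected computation
        def risk(times, events, t):
            return sum(
                1
                for u, e in zip(times, events)
                if (e == 1 and u >= t) or (e == 0 and u > t)
            )

        o_minus_e, var = 0.0, 0.0
        for t in (1, 2, 3):
            na, nb = risk(ta, ea, t), risk(tb, eb, t)
            da = sum(1 for u, e in zip(ta, ea) if e == 1 and u == t)
            db = sum(1 for u, e in zip(tb, eb) if e == 1 and u == t)
            n, d = na + nb, da + db
            o_minus_e += da - d * na / n
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        assert stat == pytest.approx(o_minus_e**2 / var)
        assert stat == pytest.approx((11 / 30) ** 2 / (749 / 900))

    def test_label_swap_invariance(self, study_cohort):
        a = [r for r in study_cohort if r.arm == IM]
        b = [r for r in study_cohort if r.arm == PA_SC]
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_matches_lifelines(self, study_cohort):
        a = [r for r in study_cohort if r.arm == IM]
        b = [r for r in study_cohort if r.arm == PA_SC]
        stat, p = logrank_test(a, b)
        ta, ea = _shift_censor(*times_and_events(a, "method_status_change"))
        tb, eb = _shift_censor(*times_and_events(b, "method_status_change"))
        res = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert stat == pytest.approx(res.test_statistic, rel=1e-9)

    def test_detects_large_hazard_separation(self):
        # per-cycle hazards 0.3 vs 0.1 at n = 500/arm: decisive rejection
        for seed in range(10):
            params = small_params(
                n_per_arm=(500, 500, 0),
                hazard_change=(0.1, 0.3, 0.0),
                p_transition_si=0.0,
                retention_per_wave=1.0,
                seed=seed,
            )
            records = generate_cohort(params)
            a = [r for r in records if r.arm == IM]
            b = [r for r in records if r.arm == PA_SC]
            assert logrank_test(a, b)[1] < 0.001

    def test_group_without_risk_time_errors(self):
        with pytest.raises(EstimationError, match="no observed risk time"):
            logrank_from_times([1, 1], [0, 0], [1, 2], [1, 1])


def _efron_loglik_reference(beta, times, events, group):
    """Independent Efron partial log-likelihood (plain loops)."""
    ll = 0.0
    for t in sorted({u for u, e in zip(times, events) if e == 1}):
        r0 = r1 = d0 = d1 = 0
        for u, e, g in zip(times, events, group):
            at_risk = (e == 1 and u >= t) or (e == 0 and u > t)
            if at_risk:
                r1, r0 = (r1 + 1, r0) if g else (r1, r0 + 1)
            if e == 1 and u == t:
                d1, d0 = (d1 + 1, d0) if g else (d1, d0 + 1)
        d = d0 + d1
        ll += d1 * beta
        for j in range(d):
            ll -= np.log(
                r0 + r1 * np.exp(beta) - (j / d) * (d0 + d1 * np.exp(beta))
            )
    return ll


class TestHazardRatio:
    def test_grid_search_oracle_with_heavy_ties(self):
        times = [1, 1, 2, 1, 2, 2]
        events = [1, 1, 0, 1, 1, 1]
        group = [0, 0, 0, 1, 1, 1]
        fit = hazard_ratio_from_times(times, events, group)
        grid = np.arange(-3.0, 3.0001, 1e-4)
        ll = [_efron_loglik_reference(b, times, events, group) for b in grid]
        best = grid[int(np.argmax(ll))]
        assert np.log(fit.hr) == pytest.approx(best, abs=2e-4)

    def test_reciprocity(self, study_cohort):
        ab = hazard_ratio(study_cohort, PA_SC, IM)
        ba = hazard_ratio(study_cohort, IM, PA_SC)
        assert ab.hr * ba.hr == pytest.approx(1.0, abs=1e-9)

    def test_matches_lifelines_cox(self, study_cohort):
        subset = [r for r in study_cohort if r.arm in (IM, PA_SC)]
        times, events = times_and_events(subset, "method_status_change")
        group = np.array([1 if r.arm == PA_SC else 0 for r in subset])
        fit = hazard_ratio_from_times(times, events, group)
        t, e = _shift_censor(times, events)
        df = pd.DataFrame({"t": t, "e": e, "x": group})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.log(fit.hr) == pytest.approx(
            float(cph.params_["x"]), abs=1e-6
        )
        assert fit.log_hr_se == pytest.approx(
            float(cph.standard_errors_["x"]), abs=1e-6
        )

    def test_null_split_ci_covers_one(self, study_cohort):
        # random halves of one arm: the 95% CI should cover HR = 1 ~95% of the time
        times, events = times_and_events(
            [r for r in study_cohort if r.arm == IM], "method_status_change"
        )
        rng = np.random.default_rng(1)
        covered = 0
        n_rep = 40
        for _ in range(n_rep):
            group = rng.integers(0, 2, size=len(times))
            if events[group == 1].sum() == 0 or events[group == 0].sum() == 0:
                covered += 1
                continue
            fit = hazard_ratio_from_times(times, events, group)
            covered += fit.ci_low <= 1.0 <= fit.ci_high
        assert covered / n_rep >= 0.80

    def test_zero_events_in_group_errors(self):
        records = [
            make_record(IM, [IM, IM, IM, IM], pid="P0"),
            make_record(PA_SC, [SI, SI, SI, SI], pid="P1"),
        ]
        with pytest.raises(EstimationError, match="undefined"):
            hazard_ratio(records, PA_SC, IM)


class TestCumulativeIncidence:
    def test_complement_of_hand_product_limit(self):
        # same risk structure as the KM hand oracle, via records
        records = [
            make_record(IM, [SI, SI, SI, SI], pid="P0"),         # event wave 1
            make_record(IM, [IM, SI, SI, SI], pid="P1"),         # event wave 2
            make_record(IM, [IM, MISSING, MISSING, MISSING], pid="P2"),  # censor 2
            make_record(IM, [IM, IM, MISSING, MISSING], pid="P3"),       # censor 3
            make_record(IM, [IM, IM, IM, MISSING], pid="P4"),            # censor 4
        ]
        res = cumulative_incidence_si(records, IM)
        assert res.estimate == pytest.approx(1 - 8 / 15)

    def test_zero_transitions_zero_with_degenerate_ci(self):
        records = generate_cohort(
            small_params(hazard_change=0.0, retention_per_wave=0.95, seed=7)
        )
        res = cumulative_incidence_si(records, IM)
        assert res.estimate == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)


class TestMeanDaysToSwitch:
    def test_midpoint_imputation(self):
        one = [make_record(IM, [IM, SI, SI, SI], pid="P0")]
        assert mean_days_to_switch(one, IM) == pytest.approx(91 * 1.5)
        three = [
            make_record(IM, [IM, IM, SI, SI], pid=f"P{i}") for i in range(3)
        ]
        assert mean_days_to_switch(three, IM) == pytest.approx(91 * 2.5)

    def test_no_switchers_errors(self):
        records = [make_record(IM, [IM, IM, IM, IM])]
        with pytest.raises(EstimationError, match="no switchers"):
            mean_days_to_switch(records, IM)

    def test_earlier_switching_arm_has_smaller_mean(self):
        # PA-SC arm built to switch roughly one wave earlier than IM
        for seed in range(10):
            params = small_params(
                n_per_arm=(300, 300, 0),
                hazard_change=(0.08, 0.45, 0.0),
                p_transition_si=1.0,
                retention_per_wave=1.0,
                seed=seed,
            )
            records = generate_cohort(params)
            assert mean_days_to_switch(records, PA_SC) < mean_days_to_switch(
                records, IM
            )


class TestTransitionMatrix:
    def test_direct_count_oracle(self):
        # 4 observed pairs out of IM: 2 stay, 1 to SI, 1 to NONE
        records = [
            make_record(IM, [IM], pid="P0"),
            make_record(IM, [IM], pid="P1"),
            make_record(IM, [SI], pid="P2"),
            make_record(IM, [NONE], pid="P3"),
        ]
        tm = estimate_transition_matrix(records, IM)
        assert tm.prob(IM, IM) == pytest.approx(0.5)
        assert tm.prob(IM, SI) == pytest.approx(0.25)
        assert tm.prob(IM, NONE) == pytest.approx(0.25)
        assert tm.prob(IM, PA_SC) == 0.0

    def test_static_cohort_gives_identity(self):
        records = generate_cohort(
            small_params(hazard_change=0.0, retention_per_wave=1.0)
        )
        tm = estimate_transition_matrix(records)
        assert np.allclose(tm.p, np.eye(len(STATES)))

    def test_rows_sum_to_one(self, study_cohort):
        for arm in (IM, PA_SC, SI):
            tm = estimate_transition_matrix(study_cohort, arm)
            assert np.abs(tm.p.sum(axis=1) - 1.0).max() <= 1e-12

    def test_pairs_with_missing_excluded(self):
        records = [
            make_record(IM, [IM, MISSING, MISSING, MISSING], pid="P0"),
            make_record(IM, [OTHER_METHOD, OTHER_METHOD, MISSING, MISSING], pid="P1"),
        ]
        tm = estimate_transition_matrix(records)
        # observed pairs: IM->IM, IM->OTHER, OTHER->OTHER only
        assert tm.prob(IM, IM) == pytest.approx(0.5)
        assert tm.prob(IM, OTHER_METHOD) == pytest.approx(0.5)
        assert tm.prob(OTHER_METHOD, OTHER_METHOD) == 1.0

    def test_unobserved_row_defaults_to_self_loop_with_warning(self, caplog):
        records = [make_record(IM, [IM, IM, IM, IM])]
        with caplog.at_level("WARNING"):
            tm = estimate_transition_matrix(records)
        assert tm.prob(SI, SI) == 1.0
        assert "defaulting to self-loop" in caplog.text

    def test_no_pairs_at_all_errors(self):
        records = [make_record(IM, [MISSING, MISSING, MISSING, MISSING])]
        with pytest.raises(EstimationError, match="no observed consecutive"):
            estimate_transition_matrix(records)

    def test_per_cycle_option_uses_single_wave(self):
        records = [
            make_record(IM, [SI, SI, SI, SI], pid="P0"),
            make_record(IM, [IM, IM, IM, IM], pid="P1"),
        ]
        tm0 = estimate_transition_matrix(records, cycle_index=0)
        assert tm0.prob(IM, SI) == pytest.approx(0.5)
        assert tm0.cycle_index == 0
        tm1 = estimate_transition_matrix(records, cycle_index=1)
        assert tm1.prob(IM, IM) == 1.0  # the remaining IM user stayed put
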