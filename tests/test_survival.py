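"""Analysis sets, Kaplan-Meier, log-rank and the endpoint table."""

import numpy as np
import pytest

from aftrial.cohort import PatientRecord, arm_label
from aftrial.survival import (
    SchemaError,
    SurvivalRecord,
    build_analysis_sets,
    endpoint_summary,
    km_estimate,
    logrank_test,
    survival_records,
)


def _patient(pid, **kw):
    defaults = dict(arm="placebo", dose=None, infused=True,
                    flutter_at_randomization=False, dccv_within_90min=False)
    defaults.update(kw)
    return PatientRecord(id=pid, **defaults)


class TestBuildAnalysisSets:
    def test_published_flow(self, fig1_cohort):
        sets = build_analysis_sets(fig1_cohort)
        assert sets.n_safety == 63
        assert sets.n_full_analysis == 59
        assert sets.exclusions == {
            "not_infused": 3, "flutter_at_randomization": 3, "dccv_within_90min": 1,
        }

    def test_no_exclusions(self):
        cohort = [_patient(i) for i in range(1, 11)]
        sets = build_analysis_sets(cohort)
        assert sets.n_safety == sets.n_full_analysis == 10

    def test_precedence_single_primary_reason(self):
        # flutter and in-window DCCV both set: counted once, under flutter
        cohort = [_patient(1, flutter_at_randomization=True, dccv_within_90min=True)]
        sets = build_analysis_sets(cohort)
        assert sets.exclusions["flutter_at_randomization"] == 1
        assert sets.exclusions["dccv_within_90min"] == 0
        assert sets.n_full_analysis == 0

    def test_order_independent_and_idempotent(self, fig1_cohort):
        shuffled = list(fig1_cohort)[::-1]
        a, b = build_analysis_sets(fig1_cohort), build_analysis_sets(shuffled)
        assert a.safety == b.safety and a.full_analysis == b.full_analysis
        assert build_analysis_sets(fig1_cohort) == a

    def test_missing_flag_is_schema_error(self):
        rec = _patient(1)
        rec.infused = None
        with pytest.raises(SchemaError, match="infused"):
            build_analysis_sets([rec])

    def test_nesting_invariant(self, fig1_cohort):
        sets = build_analysis_sets(fig1_cohort)
        ids = {r.id for r in fig1_cohort}
        assert sets.full_analysis <= sets.safety <= ids


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        recs = [SurvivalRecord(t, True) for t in (10, 20, 30)]
        km = km_estimate(recs)
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.survival_at(15) == pytest.approx(2 / 3)
        assert km.survival_at(5) == 1.0

    def test_all_censored_stays_at_one(self):
        recs = [SurvivalRecord(90.0, False) for _ in range(25)]
        km = km_estimate(recs)
        assert km.times.size == 0
        assert all(km.survival_at(t) == 1.0 for t in (0, 45, 90))

    def test_tied_events(self):
        recs = [SurvivalRecord(40.0, True), SurvivalRecord(40.0, True),
                SurvivalRecord(60.0, True), SurvivalRecord(90.0, False),
                SurvivalRecord(90.0, False)]
        km = km_estimate(recs)
        assert km.survival_at(40) == pytest.approx(3 / 5)

    def test_monotone_and_starts_at_one(self, fig1_cohort):
        sets = build_analysis_sets(fig1_cohort)
        km = km_estimate(survival_records(fig1_cohort, sets, arm=arm_label(5.0)))
        assert km.survival_at(0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        times = rng.uniform(1, 89, size=40)
        recs = [SurvivalRecord(float(t), True) for t in times]
        km = km_estimate(recs)
        for t in np.linspace(0, 90, 19):
            assert km.survival_at(t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_matches_lifelines(self, fig1_cohort):
        from lifelines import KaplanMeierFitter

        sets = build_analysis_sets(fig1_cohort)
        recs = survival_records(fig1_cohort, sets, arm=arm_label(5.0))
        km = km_estimate(recs)
        kmf = KaplanMeierFitter().fit([r.time for r in recs], [r.event for r in recs])
        for t in (10, 30, 41, 60, 90):
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestLogRank:
    def _groups(self):
        a = [SurvivalRecord(float(t), True) for t in (10, 20, 30, 40, 50)]
        a += [SurvivalRecord(90.0, False) for _ in range(7)]
        b = [SurvivalRecord(90.0, False) for _ in range(25)]
        return a, b

    def test_identical_groups_null(self):
        a, _ = self._groups()
        res = logrank_test(a, list(a))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_comparator_events_hand_computation(self):
        # with no placebo events the statistic depends only on risk-set sizes:
        # O-E = sum 25/(n_Aj+25), V = sum 25*n_Aj/(n_Aj+25)^2, n_Aj = 12..8
        a, b = self._groups()
        n_a = np.array([12, 11, 10, 9, 8])
        om_e = (25 / (n_a + 25)).sum()
        var = (25 * n_a / (n_a + 25) ** 2).sum()
        res = logrank_test(a, b)
        assert res.statistic == pytest.approx(om_e**2 / var, rel=1e-12)
        assert res.statistic == pytest.approx(12.6239, abs=1e-3)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        a = [SurvivalRecord(float(t), True) for t in rng.uniform(5, 80, 9)]
        a += [SurvivalRecord(90.0, False)] * 6
        b = [SurvivalRecord(float(t), True) for t in rng.uniform(5, 80, 4)]
        b += [SurvivalRecord(90.0, False)] * 12
        res = logrank_test(a, b)
        ll = ll_logrank(
            [r.time for r in a], [r.time for r in b],
            event_observed_A=[r.event for r in a], event_observed_B=[r.event for r in b],
        )
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_group_relabel_invariance(self):
        a, b = self._groups()
        assert logrank_test(a, b).statistic == pytest.approx(
            logrank_test(b, a).statistic, rel=1e-12
        )

    def test_doubling_sharpens_the_test(self):
        a, b = self._groups()
        small = logrank_test(a, b)
        big = logrank_test(a * 2, b * 2)
        assert big.statistic > small.statistic
        assert big.p_value < small.p_value

    def test_zero_events_everywhere_undefined(self):
        b = [SurvivalRecord(90.0, False)] * 5
        with pytest.raises(ValueError):
            logrank_test(b, list(b))

    def test_event_time_domain(self):
        with pytest.raises(ValueError):
            SurvivalRecord(time=95.0, event=True)
        with pytest.raises(ValueError):
            SurvivalRecord(time=60.0, event=False)  # censoring only at 90


@pytest.fixture(scope="module")
def table(fig1_cohort):
    return endpoint_summary(fig1_cohort, build_analysis_sets(fig1_cohort))


class TestEndpointSummary:

    def test_primary_counts(self, table):
        got = [(arm, int(r["primary_x"]), int(r["primary_n"])) for arm, r in table.iterrows()]
        assert got == [("placebo", 0, 25), ("3 mg/kg", 5, 12), ("5 mg/kg", 12, 22)]

    def test_recurrence_within_minute_is_not_success(self):
        rec = _patient(1, converted=True, conversion_time_min=30.0, recurrence_1min=True,
                       dccv_performed=False)
        assert rec.primary_success is False

    def test_secondary_counts(self, table):
        r3, r5, rp = table.loc["3 mg/kg"], table.loc["5 mg/kg"], table.loc["placebo"]
        assert (int(rp["relapse_5min_x"]), int(rp["relapse_5min_n"])) == (1, 25)
        assert (int(rp["sinus_3h_x"]), int(rp["sinus_3h_n"])) == (21, 25)
        assert (int(r3["sinus_3h_x"]), int(r3["sinus_3h_n"])) == (11, 11)
        assert (int(r5["sinus_3h_x"]), int(r5["sinus_3h_n"])) == (20, 21)
        assert (int(rp["sinus_24h_x"]), int(rp["sinus_24h_n"])) == (19, 25)
        assert (int(r5["sinus_24h_x"]), int(r5["sinus_24h_n"])) == (21, 21)
        assert (int(rp["sinus_30d_x"]), int(rp["sinus_30d_n"])) == (16, 25)
        assert (int(r3["sinus_30d_x"]), int(r3["sinus_30d_n"])) == (9, 10)
        assert (int(r5["sinus_30d_x"]), int(r5["sinus_30d_n"])) == (15, 21)

    def test_dccv_counts_all_nonconverters_treated(self, table):
        assert list(table["dccv_performed_x"]) == [25, 7, 10]
        got = [(int(r["dccv_success_x"]), int(r["dccv_success_n"])) for _, r in table.iterrows()]
        assert got == [(22, 25), (7, 7), (10, 10)]

    def test_conversion_conservation(self, table):
        # every full-analysis-set non-converter underwent electrical cardioversion
        for _, row in table.iterrows():
            converters = row["primary_x"]  # no 1-min recurrences in the fixture
            assert converters + row["dccv_performed_x"] == row["fas_n"]

    def test_conversion_time_moments(self, table):
        assert table.loc["3 mg/kg", "conversion_time_mean"] == pytest.approx(47.0)
        assert table.loc["3 mg/kg", "conversion_time_sd"] == pytest.approx(23.0)
        assert table.loc["5 mg/kg", "conversion_time_mean"] == pytest.approx(41.0)
        assert table.loc["5 mg/kg", "conversion_time_sd"] == pytest.approx(24.0)
        assert np.isnan(table.loc["placebo", "conversion_time_mean"])

    def test_empty_full_analysis_set_rejected(self):
        cohort = [_patient(1, infused=False)]
        with pytest.raises(ValueError):
            endpoint_summary(cohort, build_analysis_sets(cohort))
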