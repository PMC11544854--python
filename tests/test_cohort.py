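"""Cohort diagnostics: confusion counts, CIs, kappa, summaries."""

import numpy as np
import pytest
from scipy.stats import binom
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

from octburn.cohort import (
    ConfusionTable,
    Outcome,
    WoundRecord,
    build_confusion,
    cohen_kappa,
    cohort_summary,
    diagnostic_stats,
    interobserver_agreement,
    round_percent,
    threshold_sweep,
)
from octburn.errors import CohortValidationError, EmptyCohortError
from octburn.score import FeatureGrades, SkinType
from octburn.simulate import CohortConfig, generate_cohort


def make_record(wound_id, score_items, outcome, days=None, obs2_items=None,
                skin=SkinType.GLABROUS, patient=None):
    g1 = FeatureGrades(*score_items, skin)
    g2 = FeatureGrades(*obs2_items, skin) if obs2_items else None
    return WoundRecord(
        wound_id=wound_id, patient_id=patient or f"p_{wound_id}",
        skin_type=skin, grades_obs1=g1, grades_obs2=g2,
        outcome=outcome, days_to_graft=days,
    )


HEAL, GRAFT, REFUSED = (Outcome.HEALED_SPONTANEOUSLY, Outcome.GRAFTED,
                        Outcome.DEEP_REFUSED_GRAFT)

# 10-record fixture with hand-countable labels: scores and outcomes chosen
# so the threshold-4 table is a=2 (w5, w6), b=1 (w7), c=1 (w4), d=6
TEN_RECORDS = [
    make_record("w0", (0, 0, 0, 0), HEAL),
    make_record("w1", (1, 0, 1, 0), HEAL),
    make_record("w2", (1, 1, 1, 0), HEAL),
    make_record("w3", (1, 1, 1, 1), HEAL),
    make_record("w4", (1, 1, 2, 0), GRAFT, days=9),   # score 4, missed deep
    make_record("w5", (1, 1, 2, 1), GRAFT, days=12),  # score 5
    make_record("w6", (1, 1, 2, 2), REFUSED),         # score 6, deep course
    make_record("w7", (1, 1, 1, 2), HEAL),            # score 5, healed
    make_record("w8", (0, 1, 1, 1), HEAL),
    make_record("w9", (1, 0, 2, 1), HEAL),
]


def brute_force_table(records, threshold, deep_outcomes):
    a = b = c = d = 0
    for r in records:
        pred_deep = r.score > threshold
        deep = r.outcome in deep_outcomes
        a += pred_deep and deep
        b += pred_deep and not deep
        c += (not pred_deep) and deep
        d += (not pred_deep) and not deep
    return a, b, c, d


class TestBuildConfusion:
    def test_matches_enumeration_at_every_threshold(self):
        for t in range(7):
            table = build_confusion(TEN_RECORDS, threshold=t)
            expected = brute_force_table(TEN_RECORDS, t, {GRAFT, REFUSED})
            assert (table.a, table.b, table.c, table.d) == expected
            assert table.total == len(TEN_RECORDS)

    def test_grafted_only_rule_reclassifies_refusal(self):
        table = build_confusion(TEN_RECORDS, deep_outcome_rule="grafted_only")
        expected = brute_force_table(TEN_RECORDS, 4, {GRAFT})
        assert (table.a, table.b, table.c, table.d) == expected

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(EmptyCohortError):
            build_confusion([])

    def test_study_like_high_score_wounds(self):
        # 17 wounds scoring >=5 (12 at 5, 5 at 6), 9 grafted, none below
        records = []
        for i in range(12):
            out = GRAFT if i < 7 else HEAL
            records.append(make_record(
                f"s5_{i}", (1, 1, 2, 1), out, days=9 if out is GRAFT else None))
        for i in range(5):
            out = GRAFT if i < 2 else HEAL
            records.append(make_record(
                f"s6_{i}", (1, 1, 2, 2), out, days=9 if out is GRAFT else None))
        table = build_confusion(records, deep_outcome_rule="grafted_only")
        assert (table.a, table.b, table.c, table.d) == (9, 8, 0, 0)
        stats = diagnostic_stats(table)
        assert stats.ppv.estimate == pytest.approx(9 / 17)
        assert stats.ppv.percent() == "53%"

    def test_consensus_mode_keeps_agreeing_records_only(self):
        recs = [
            make_record("a", (1, 1, 1, 0), HEAL, obs2_items=(1, 1, 1, 0)),
            make_record("b", (1, 1, 1, 0), HEAL, obs2_items=(1, 0, 1, 0)),
        ]
        table = build_confusion(recs, observer="consensus")
        assert table.total == 1


def grid_search_exact_ci(x, n, alpha=0.05, grid=200001):
    """Clopper-Pearson bounds by scanning binomial tail probabilities."""
    ps = np.linspace(0.0, 1.0, grid)
    lower = 0.0
    if x > 0:
        ge_x = binom.sf(x - 1, n, ps)  # P(X >= x | p), increasing in p
        lower = ps[np.searchsorted(ge_x >= alpha / 2, True)]
    upper = 1.0
    if x < n:
        le_x = binom.cdf(x, n, ps)  # P(X <= x | p), decreasing in p
        upper = ps[np.searchsorted(le_x < alpha / 2, True) - 1]
    return lower, upper


class TestDiagnosticStats:
    def test_perfect_table_gives_unit_metrics(self):
        stats = diagnostic_stats(ConfusionTable(5, 0, 0, 5))
        for name in ("ppv", "npv", "sensitivity", "specificity", "agreement"):
            assert getattr(stats, name).estimate == 1.0

    def test_point_estimates_inside_intervals(self):
        stats = diagnostic_stats(build_confusion(TEN_RECORDS))
        for name in ("ppv", "npv", "sensitivity", "specificity", "agreement"):
            est = getattr(stats, name)
            assert 0.0 <= est.ci_low <= est.estimate <= est.ci_high <= 1.0

    @pytest.mark.parametrize("x,n", [(9, 17), (0, 8), (8, 8), (3, 50)])
    def test_exact_ci_matches_tail_inversion_oracle(self, x, n):
        lo, hi = proportion_confint(x, n, method="beta")
        olo, ohi = grid_search_exact_ci(x, n)
        assert lo == pytest.approx(olo, abs=1e-4)
        assert hi == pytest.approx(ohi, abs=1e-4)

    def test_zero_denominator_reported_absent(self):
        stats = diagnostic_stats(ConfusionTable(0, 0, 3, 7))
        assert stats.ppv is None  # nothing predicted deep
        assert stats.npv.estimate == pytest.approx(0.7)

    def test_all_zero_table_is_an_error(self):
        with pytest.raises(EmptyCohortError):
            diagnostic_stats(ConfusionTable(0, 0, 0, 0))

    def test_label_swap_exchanges_ppv_npv_and_sens_spec(self):
        table = build_confusion(TEN_RECORDS)
        s1 = diagnostic_stats(table)
        s2 = diagnostic_stats(table.swapped())
        assert s1.ppv.estimate == pytest.approx(s2.npv.estimate)
        assert s1.npv.estimate == pytest.approx(s2.ppv.estimate)
        assert s1.sensitivity.estimate == pytest.approx(
            s2.specificity.estimate)
        assert s1.agreement.estimate == pytest.approx(s2.agreement.estimate)

    def test_agreement_is_one_iff_no_discordant_cells(self):
        assert diagnostic_stats(
            ConfusionTable(3, 0, 0, 7)).agreement.estimate == 1.0
        assert diagnostic_stats(
            ConfusionTable(3, 1, 0, 6)).agreement.estimate < 1.0

    def test_wilson_interval_coverage_near_nominal(self):
        # repeated binomial draws at fixed p: ~95% of Wilson CIs cover p
        rng = np.random.default_rng(7)
        n, p, reps = 50, 0.3, 10000
        x = rng.binomial(n, p, reps)
        lo, hi = proportion_confint(x, n, method="wilson")
        coverage = ((lo <= p) & (p <= hi)).mean()
        assert coverage == pytest.approx(0.95, abs=0.02)


class TestThresholdSweep:
    def test_rows_match_direct_computation(self):
        sweep = threshold_sweep(TEN_RECORDS)
        assert list(sweep.index) == list(range(7))
        table = build_confusion(TEN_RECORDS, threshold=4)
        row = sweep.loc[4]
        assert (row.a, row.b, row.c, row.d) == (
            table.a, table.b, table.c, table.d)
        stats = diagnostic_stats(table)
        assert row.ppv == pytest.approx(stats.ppv.estimate)

    def test_partition_at_every_threshold(self):
        sweep = threshold_sweep(TEN_RECORDS)
        assert (sweep[["a", "b", "c", "d"]].sum(axis=1)
                == len(TEN_RECORDS)).all()

    def test_all_superficial_cohort_has_perfect_agreement_at_4(self):
        recs = [make_record(f"w{i}", (1, 1, 1, 0), HEAL) for i in range(5)]
        sweep = threshold_sweep(recs)
        assert sweep.loc[4, "agreement"] == 1.0

    def test_single_deep_record_sensitivity(self):
        rec = make_record("only", (1, 1, 2, 2), GRAFT, days=5)
        sweep = threshold_sweep([rec])
        assert sweep.loc[5, "a"] == 1
        assert sweep.loc[5, "sensitivity"] == 1.0


class TestCohortSummary:
    def test_hand_injury_percent_one_decimal(self):
        recs = [make_record(f"w{i}", (1, 1, 1, 0), HEAL, patient=f"p{i}")
                for i in range(171)]
        summary = cohort_summary(recs, admissions_total=461)
        assert summary["hand_injury_percent"] == "37.1%"

    def test_single_record_counts(self):
        summary = cohort_summary([TEN_RECORDS[5]])
        assert summary["n_wounds"] == summary["n_patients"] == 1
        assert summary["score_counts"][5] == 1
        assert summary["outcome_counts"]["grafted"] == 1
        assert summary["median_days_to_graft"] == 12

    def test_per_score_counts_match_direct_tally(self):
        summary = cohort_summary(TEN_RECORDS)
        tally = {s: sum(r.score == s for r in TEN_RECORDS) for s in range(7)}
        assert summary["score_counts"] == tally

    def test_admissions_below_patient_count_rejected(self):
        with pytest.raises(CohortValidationError):
            cohort_summary(TEN_RECORDS, admissions_total=3)


class TestInterobserverAgreement:
    def test_identical_gradings_give_perfect_agreement(self):
        recs = [
            make_record(f"w{i}", items, HEAL, obs2_items=items)
            for i, items in enumerate(
                [(0, 0, 0, 0), (1, 1, 1, 1), (1, 0, 2, 1), (0, 1, 1, 2),
                 (1, 1, 2, 2)] * 2)
        ]
        result = interobserver_agreement(recs)
        for item_res in result["items"].values():
            assert item_res["percent_agreement"] == 1.0
            assert item_res["kappa"] == 1.0
        assert result["total_score"]["percent_agreement"] == 1.0

    def test_kappa_matches_hand_formula_on_fixed_table(self):
        # [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        table = np.array([[20, 5], [10, 15]])
        assert cohen_kappa(table) == pytest.approx(0.4)

    def test_kappa_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        r1 = rng.integers(0, 3, 200)
        r2 = np.where(rng.random(200) < 0.7, r1, rng.integers(0, 3, 200))
        table = np.zeros((3, 3), int)
        np.add.at(table, (r1, r2), 1)
        assert cohen_kappa(table) == pytest.approx(
            cohen_kappa_score(r1, r2))

    def test_constant_observers_have_absent_kappa(self):
        recs = [make_record(f"w{i}", (0, 0, 0, 0), HEAL,
                            obs2_items=(0, 0, 0, 0)) for i in range(10)]
        result = interobserver_agreement(recs)
        for item_res in result["items"].values():
            assert item_res["percent_agreement"] == 1.0
            assert item_res["kappa"] is None  # p_e = 1

    def test_random_independent_gradings_concentrate_near_zero(self):
        rng = np.random.default_rng(5)
        recs = []
        for i in range(4000):
            items1 = (int(rng.integers(2)), int(rng.integers(2)),
                      int(rng.integers(3)), int(rng.integers(3)))
            items2 = (int(rng.integers(2)), int(rng.integers(2)),
                      int(rng.integers(3)), int(rng.integers(3)))
            recs.append(make_record(f"w{i}", items1, HEAL, obs2_items=items2))
        result = interobserver_agreement(recs)
        for item_res in result["items"].values():
            assert abs(item_res["kappa"]) < 0.05

    def test_single_observer_records_excluded_and_counted(self):
        recs = [
            make_record("a", (1, 1, 1, 0), HEAL, obs2_items=(1, 1, 1, 0)),
            make_record("b", (1, 1, 1, 0), HEAL, obs2_items=(1, 1, 1, 1)),
            make_record("c", (1, 1, 1, 0), HEAL),
        ]
        result = interobserver_agreement(recs)
        assert result["n_dual"] == 2
        assert result["n_excluded"] == 1

    def test_requires_two_dual_graded_records(self):
        with pytest.raises(EmptyCohortError):
            interobserver_agreement([TEN_RECORDS[0]])


class TestRecordInvariants:
    def test_days_to_graft_requires_grafted_outcome(self):
        with pytest.raises(CohortValidationError):
            make_record("bad", (1, 1, 1, 0), HEAL, days=5)
        with pytest.raises(CohortValidationError):
            make_record("bad", (1, 1, 2, 1), GRAFT)  # no days


@pytest.mark.parametrize("p,decimals,expected", [
    (9 / 17, 0, "53%"),
    (171 / 461, 1, "37.1%"),
    (0.555, 0, "56%"),     # half-up on the percent scale
    (0.005, 1, "0.5%"),
    (1.0, 0, "100%"),
])
def test_round_percent_half_up(p, decimals, expected):
    assert round_percent(p, decimals) == expected


def test_synthetic_cohort_partition_property():
    records = generate_cohort(CohortConfig(n_wounds=500, seed=3))
    for t in (0, 3, 6):
        assert build_confusion(records, threshold=t).total == 500
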