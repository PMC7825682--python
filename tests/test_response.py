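"""Community response cross-tabulation, response-class labels, and
NC-threshold contingency evaluation."""

import dataclasses

import numpy as np
import pytest

from cpapnet import (
    ClassProfile,
    PatientRecord,
    ResponseModelSpec,
    ahi_improvement,
    contingency_from_counts,
    evaluate_nc_threshold,
    generate_clustered_cohort,
    improvements_by_community,
    label_response_classes,
    parameter_community_map,
    severity_transition_table,
)
from conftest import GOOD_COMMUNITIES


def rec(pid, ahi_before, ahi_after=None, nc=44.0, gender="male"):
    return PatientRecord(
        id=pid,
        gender=gender,
        age=50.0,
        bmi=32.0,
        neck_circumference=nc,
        ess=12,
        ahi_before=ahi_before,
        ahi_after=ahi_after,
        hbp_flag=True,
    )


class TestTransitionTable:
    def test_two_severe_to_norm_patients(self):
        records = [rec("a", 50, 2), rec("b", 40, 3)]
        t = severity_transition_table(records, {"a": 0, "b": 0})
        assert t.loc[0, ("before", "sev")] == 1.0
        assert t.loc[0, ("after", "norm")] == 1.0

    def test_blocks_sum_to_one(self):
        cohort = generate_clustered_cohort(seed=0, response=ResponseModelSpec())
        part = {r.id: i % 3 for i, r in enumerate(cohort.records)}
        t = severity_transition_table(cohort.records, part)
        assert np.allclose(t["before"].sum(axis=1), 1.0)
        assert np.allclose(t["after"].sum(axis=1), 1.0)

    def test_certain_improvement_leaves_no_severe_after(self):
        cohort = generate_clustered_cohort(
            seed=1, response=ResponseModelSpec(1.0, 1.0)
        )
        part = {r.id: 0 for r in cohort.records}
        t = severity_transition_table(cohort.records, part)
        assert t.loc[0, ("after", "sev")] == 0.0

    def test_missing_after_ahi_excluded(self):
        records = [rec("a", 50, 2), rec("b", 40, None)]
        t = severity_transition_table(records, {"a": 0, "b": 0})
        assert t.loc[0, ("after", "norm")] == 1.0  # only 'a' counted


class TestAhiImprovement:
    def test_three_of_four_severe_improved_is_75(self):
        records = [rec("a", 50, 2), rec("b", 45, 7), rec("c", 60, 12), rec("d", 35, 40)]
        assert ahi_improvement(records) == pytest.approx(75.0)

    def test_no_improvement_is_zero(self):
        records = [rec("a", 50, 50), rec("b", 45, 35)]
        assert ahi_improvement(records) == pytest.approx(0.0)

    def test_undefined_without_severe_patients(self):
        with pytest.raises(ValueError):
            ahi_improvement([rec("a", 10, 5)])

    def test_sev_reduction_mode(self):
        # 2 severe before, 1 severe after -> 50% head-count reduction
        records = [rec("a", 50, 40), rec("b", 45, 3), rec("c", 20, 10)]
        assert ahi_improvement(records, mode="sev_reduction") == pytest.approx(50.0)
        with pytest.raises(ValueError):
            ahi_improvement(records, mode="bogus")

    def test_community_level_rates_track_response_model(self):
        cohort = generate_clustered_cohort(
            sizes=(200, 200, 200, 200),
            seed=3,
            response=ResponseModelSpec(0.9, 0.7),
        )
        imps = improvements_by_community(cohort.records, cohort.labels)
        from scipy import stats

        for c, imp in imps.items():
            members = [p for pid, p in cohort.profiles.items() if cohort.labels[pid] == c]
            p = np.mean([0.9 if m.thick_neck else 0.7 for m in members])
            lo, hi = stats.binom.interval(0.99, len(members), p)
            assert lo / len(members) * 100 <= imp <= hi / len(members) * 100


class TestLabeling:
    def test_published_improvements_split_best_and_good(self):
        imps = {1: 89.29, 2: 87.50, 3: 68.75, 4: 77.78}
        lab = label_response_classes(imps, best_threshold=85.0)
        assert lab.communities("best") == {1, 2}
        assert lab.communities("good") == {3, 4}

    def test_equal_improvements_share_a_label(self):
        lab = label_response_classes({1: 70.0, 2: 70.0}, best_threshold=85.0)
        assert set(lab.labels.values()) == {"good"}

    def test_zero_threshold_labels_everything_best(self):
        lab = label_response_classes({1: 10.0, 2: 0.0}, best_threshold=0.0)
        assert set(lab.labels.values()) == {"best"}

    def test_empty_improvements_rejected(self):
        with pytest.raises(ValueError):
            label_response_classes({})


class TestParameterCommunityMap:
    def test_pure_community_is_representative(self):
        profiles = {
            f"p{i}": ClassProfile("M", 2, True, True, True, True) for i in range(10)
        }
        df = parameter_community_map(profiles, {p: 0 for p in profiles})
        gender = df[(df.community == 0) & (df.parameter == "gender")].iloc[0]
        assert gender.display == "M" and bool(gender.representative)

    def test_even_split_is_marked_dash(self):
        profiles = {
            f"p{i}": ClassProfile("M", 2, i < 5, True, True, True) for i in range(10)
        }
        df = parameter_community_map(profiles, {p: 0 for p in profiles})
        hbp = df[(df.parameter == "hbp")].iloc[0]
        assert hbp.display == "-" and not bool(hbp.representative)

    def test_prevalence_exactly_at_threshold_is_representative(self):
        profiles = {
            f"p{i}": ClassProfile("M", 2, i < 7, True, True, True) for i in range(10)
        }
        df = parameter_community_map(
            profiles, {p: 0 for p in profiles}, representative_threshold=0.70
        )
        hbp = df[(df.parameter == "hbp")].iloc[0]
        assert bool(hbp.representative) and hbp.display == "1"


class TestNcThreshold:
    def test_published_counts_reproduce_published_rates(self, reported_nc_counts):
        good41, best41 = reported_nc_counts[41]
        ev = contingency_from_counts(good41, best41, GOOD_COMMUNITIES, cutoff=41)
        assert ev.good.ppv == pytest.approx(51 / 53)
        assert ev.good.tpr == pytest.approx(51 / 58)
        assert ev.best.tpr == pytest.approx(85 / 87)
        assert ev.best.ppv == pytest.approx(85 / 92)
        good39, best39 = reported_nc_counts[39]
        ev39 = contingency_from_counts(good39, best39, GOOD_COMMUNITIES, cutoff=39)
        assert ev39.good.tpr == pytest.approx(0.500, abs=5e-4)
        assert ev39.good.tnr == pytest.approx(1.000, abs=5e-4)

    def test_orientations_are_complementary(self, reported_nc_counts):
        good41, best41 = reported_nc_counts[41]
        ev = contingency_from_counts(good41, best41, GOOD_COMMUNITIES)
        assert ev.good.tpr == ev.best.tnr
        assert ev.good.tnr == ev.best.tpr

    def test_rates_recompute_from_stored_counts(self, reported_nc_counts):
        good41, best41 = reported_nc_counts[41]
        ev = contingency_from_counts(good41, best41, GOOD_COMMUNITIES)
        m = ev.good
        assert m.tpr == m.tp / (m.tp + m.fn)
        assert m.tnr == m.tn / (m.tn + m.fp)
        assert m.ppv == m.tp / (m.tp + m.fp)
        assert m.npv == m.tn / (m.tn + m.fn)
        assert m.tp + m.fp + m.tn + m.fn == 145

    def test_cutoff_below_all_nc_predicts_everyone_best(self):
        records = [rec("a", 50, 5, nc=42), rec("b", 50, 40, nc=45)]
        lab = label_response_classes({0: 90.0, 1: 50.0})
        ev = evaluate_nc_threshold(records, lab, {"a": 0, "b": 1}, cutoff=30)
        assert sum(ev.pred_good_counts.values()) == 0
        assert ev.good.tpr == 0.0

    def test_cutoff_sweep_moves_patients_monotonically(self):
        cohort = generate_clustered_cohort(seed=5, response=ResponseModelSpec())
        part = cohort.labels
        imps = improvements_by_community(cohort.records, part)
        lab = label_response_classes(imps)
        prev = -1
        for cutoff in (38, 40, 42, 44, 46):
            ev = evaluate_nc_threshold(cohort.records, lab, part, cutoff)
            n_good = sum(ev.pred_good_counts.values())
            assert n_good >= prev
            prev = n_good

    def test_unlabeled_community_rejected(self):
        records = [rec("a", 50, 5)]
        lab = label_response_classes({1: 90.0})
        with pytest.raises(ValueError):
            evaluate_nc_threshold(records, lab, {"a": 99}, cutoff=41)
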