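"""Diel binning, standardization, cohort-day detection, aging, recovery."""
import numpy as np
import pytest

from pofkit import (PofStage, SimulationConfig, analyze_records,
                    assign_female_cohorts, bin_records, detect_cohort_day,
                    estimate_stage_age, recover_parameters, simulate_population,
                    standardize_all, standardize_occurrence)
from pofkit.cohort import DataIntegrityError, IntervalSummary
from pofkit.io import load_fixture_table
from .conftest import make_record


def make_summary(interval, counts, n_females_with_pofs, n_females=None):
    raw = np.zeros(6, int)
    for stage, c in counts.items():
        raw[int(PofStage[stage]) - 1] = c
    return IntervalSummary(
        interval_index=interval, midpoint=2.0 * interval + 1.0,
        n_females=n_females if n_females is not None else max(n_females_with_pofs, 1),
        n_females_with_pofs=n_females_with_pofs,
        n_pofs=int(raw.sum()), raw_counts=raw)


class TestBinRecords:
    def test_half_open_two_hour_bins(self):
        recs = [make_record(1, 8.5, [(1, 10.0)]),   # 08:30 -> bin 4
                make_record(2, 0.0, [(1, 10.0)]),   # 00:00 -> bin 0
                make_record(3, 23.99, [(1, 10.0)])]  # 23:59 -> bin 11
        summaries = bin_records(recs)
        hit = {s.interval_index for s in summaries if s.n_pofs}
        assert hit == {4, 0, 11}

    def test_counts_conserved(self, default_records):
        summaries = bin_records(default_records)
        total = sum(len(r.pofs) for r in default_records)
        assert sum(s.n_pofs for s in summaries) == total
        assert all(s.n_pofs == s.raw_counts.sum() for s in summaries)

    def test_replaying_the_diel_fixture_reproduces_its_pof_column(self):
        """Pseudo-records built from the packaged diel table bin back to it."""
        diel = load_fixture_table("diel_sampling")
        recs = []
        for b, row in diel.iterrows():
            recs.append(make_record(b, 2.0 * b,
                                    [(1, 10.0)] * int(row["n_pofs"])))
        summaries = bin_records(recs)
        assert [s.n_pofs for s in summaries] == diel["n_pofs"].tolist()


class TestStandardize:
    def test_two_step_hand_example(self):
        s = standardize_occurrence(make_summary(4, {"I": 3, "II": 1}, 4))
        assert s.std_occurrence[0] == pytest.approx(0.75)
        assert s.std_occurrence[1] == pytest.approx(0.25)

    def test_single_stage_goes_to_one(self):
        s = standardize_occurrence(make_summary(4, {"I": 5}, 2))
        assert s.std_occurrence[0] == 1.0

    def test_three_stage_hand_example(self):
        s = standardize_occurrence(
            make_summary(4, {"I": 2, "III": 2, "IV": 4}, 10))
        got = [s.std_occurrence[i] for i in (0, 2, 3)]
        assert got == pytest.approx([0.25, 0.25, 0.5])

    def test_empty_interval_yields_missing_vector(self):
        s = standardize_occurrence(make_summary(4, {}, 0, n_females=3))
        assert s.std_occurrence is None

    def test_pofs_without_females_is_integrity_error(self):
        with pytest.raises(DataIntegrityError):
            standardize_occurrence(make_summary(4, {"I": 2}, 0))

    def test_proportions_sum_to_one_over_stages(self, default_records):
        for s in standardize_all(bin_records(default_records)):
            if s.n_pofs:
                assert s.std_occurrence.sum() == pytest.approx(1.0)


class TestDetectCohortDay:
    def _summaries(self, present_bins, sampled_bins=range(12)):
        out = []
        for b in range(12):
            if b not in sampled_bins:
                out.append(make_summary(b, {}, 0, n_females=0))
            elif b in present_bins:
                out.append(make_summary(b, {"I": 3}, 2))
            else:
                out.append(make_summary(b, {"II": 3}, 2))
        return out

    def test_night_window_around_peak_is_day_zero(self):
        # present only 22:00-06:00 (bins 11, 0, 1, 2): absent >= 6 h
        day = detect_cohort_day(PofStage.I, self._summaries({11, 0, 1, 2}))
        assert day == 0

    def test_full_cycle_presence_is_day_one(self):
        day = detect_cohort_day(PofStage.I, self._summaries(set(range(12))))
        assert day == 1

    def test_absence_block_is_circular(self):
        # empty bins 10, 11, 0: contiguous only across midnight
        present = set(range(1, 10))
        assert detect_cohort_day(PofStage.I, self._summaries(present)) == 0

    def test_unsampled_bins_do_not_count_as_absence(self):
        # bins 4-6 unsampled; stage present in every sampled bin
        present = set(range(12)) - {4, 5, 6}
        day = detect_cohort_day(PofStage.I,
                                self._summaries(present, sampled_bins=present))
        assert day == 1

    def test_stage_never_observed_raises(self):
        with pytest.raises(ValueError, match="not observed"):
            detect_cohort_day(PofStage.VI, self._summaries({1, 2}))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_unambiguous_presence_windows_recovered(self, seed):
        """Contiguous presence < 18 h -> Day 0; full-cycle presence -> Day 1."""
        rng = np.random.default_rng(seed)
        start, length = rng.integers(0, 12), rng.integers(1, 9)
        window = {(start + k) % 12 for k in range(length)}
        assert detect_cohort_day(PofStage.I, self._summaries(window)) == 0
        assert detect_cohort_day(PofStage.I,
                                 self._summaries(set(range(12)))) == 1


class TestEstimateStageAge:
    def _with_occurrence(self, weights_by_bin):
        out = []
        for b in range(12):
            c = weights_by_bin.get(b, 0)
            out.append(make_summary(b, {"I": c} if c else {}, 2 if c else 0,
                                    n_females=2))
        return standardize_all(out)

    def test_single_bin_next_to_peak(self):
        s = self._with_occurrence({11: 4})  # midpoint 23:00, ASP 22:00
        est = estimate_stage_age(PofStage.I, s, asp_hour=22.0, cohort_day=0,
                                 n_boot=0)
        assert est.mean_age == pytest.approx(1.0)

    def test_day_one_adds_a_full_day(self):
        s = self._with_occurrence({3: 4})  # midpoint 07:00 -> 9 h + 24 h
        est = estimate_stage_age(PofStage.I, s, asp_hour=22.0, cohort_day=1,
                                 n_boot=0)
        assert est.mean_age == pytest.approx(33.0)

    def test_equal_occurrence_averages_offsets(self):
        s = self._with_occurrence({11: 3, 1: 3})  # 1 h and 5 h
        est = estimate_stage_age(PofStage.I, s, asp_hour=22.0, cohort_day=0,
                                 n_boot=0)
        assert est.mean_age == pytest.approx(3.0)

    def test_invariant_to_uniform_rescaling_of_weights(self):
        a = self._with_occurrence({11: 1, 1: 2, 3: 1})
        b = self._with_occurrence({11: 5, 1: 10, 3: 5})
        ea = estimate_stage_age(PofStage.I, a, cohort_day=0, n_boot=0)
        eb = estimate_stage_age(PofStage.I, b, cohort_day=0, n_boot=0)
        assert ea.mean_age == pytest.approx(eb.mean_age)

    def test_pre_peak_bin_counts_as_tonight_not_yesterday(self):
        # 21:00 midpoint, one hour before the 22:00 peak: offset -1, not +23
        s = self._with_occurrence({10: 1, 11: 1})
        est = estimate_stage_age(PofStage.I, s, cohort_day=0, n_boot=0)
        assert est.mean_age == pytest.approx(0.0)

    def test_all_zero_occurrence_raises(self):
        s = self._with_occurrence({11: 3})
        with pytest.raises(ValueError, match="all-zero"):
            estimate_stage_age(PofStage.II, s, cohort_day=0, n_boot=0)

    def test_max_persistence_reaches_latest_occupied_bin_edge(self):
        s = self._with_occurrence({11: 3, 1: 1})
        est = estimate_stage_age(PofStage.I, s, cohort_day=0, n_boot=0)
        assert est.max_persistence == pytest.approx(6.0)  # bin 1 ends 6 h post-peak

    def test_bootstrap_ci_brackets_point_and_reproduces(self, default_records):
        res1 = analyze_records(default_records, n_boot=200, seed=3)
        res2 = analyze_records(default_records, n_boot=200, seed=3)
        for s, est in res1["stage_ages"].items():
            assert est.ci_low <= est.mean_age <= est.ci_high
            other = res2["stage_ages"][s]
            assert (est.ci_low, est.ci_high) == (other.ci_low, other.ci_high)


class TestAssignFemaleCohorts:
    DAYS = {PofStage.I: 0, PofStage.II: 0, PofStage.III: 0,
            PofStage.IV: 1, PofStage.V: 1, PofStage.VI: 1}

    def test_early_stage_is_day_zero(self):
        rec = make_record(1, 23.0, [(2, 10.0)])
        assert assign_female_cohorts(rec, self.DAYS).labels == {"Day0"}

    def test_late_stage_is_day_one(self):
        rec = make_record(1, 9.0, [(5, 10.0)])
        assert assign_female_cohorts(rec, self.DAYS).labels == {"Day1"}

    def test_consecutive_night_spawner_gets_both_labels(self):
        rec = make_record(1, 23.0, [(1, 10.0), (4, 8.0)])
        lab = assign_female_cohorts(rec, self.DAYS)
        assert lab.labels == {"Day0", "Day1"}
        assert lab.basis == (PofStage.I, PofStage.IV)

    def test_pof_without_day_assignment_raises(self):
        rec = make_record(1, 23.0, [(6, 10.0)])
        with pytest.raises(ValueError, match="VI"):
            assign_female_cohorts(rec, {PofStage.I: 0})

    def test_female_without_pofs_raises(self):
        with pytest.raises(ValueError):
            assign_female_cohorts(make_record(1, 23.0, []), self.DAYS)


class TestRecoverParameters:
    def test_no_spawning_gives_empty_report_without_crash(self):
        cfg = SimulationConfig(seed=1, spawning_fraction=0.0, n_females=100)
        rep = recover_parameters(simulate_population(cfg), cfg)
        assert rep.empty

    def test_records_without_truth_are_rejected(self, default_config):
        rec = make_record(1, 23.0, [(1, 10.0)])
        with pytest.raises(ValueError, match="truth"):
            recover_parameters([rec], default_config)

    def test_cohort_days_recovered_exactly_on_default_simulator(self):
        cfg = SimulationConfig(seed=13)
        rep = recover_parameters(simulate_population(cfg), cfg, n_boot=0)
        assert len(rep) == 6
        assert rep["day_match"].all()


def test_mean_ages_strictly_increase_with_stage(default_records):
    res = analyze_records(default_records, n_boot=0)
    ages = [res["stage_ages"][s].mean_age for s in sorted(res["stage_ages"])]
    assert len(ages) == 6
    assert all(a < b for a, b in zip(ages, ages[1:]))
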