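import datetime

import numpy as np
import pytest

from pvsignal.descriptives import (
    challenge_counts,
    pct,
    round_half_up,
    summarize_cohort,
    time_to_onset,
)

from conftest import make_report

D = datetime.date


@pytest.mark.parametrize(
    "x,expected",
    [(44.81, 44.8), (75.549, 75.5), (46.48, 46.5), (0.05, 0.1), (2.1894, 2.2), (69.65, 69.7)],
)
def test_round_half_up(x, expected):
    assert round_half_up(x, 1) == expected


def test_pct_recomputes_from_count_and_denominator():
    assert pct(6134, 13688) == 44.8
    assert pct(9223, 12208) == 75.5
    assert pct(4287, 9223) == 46.5
    assert pct(0, 0) is None


class TestSummarizeCohort:
    def test_single_case_all_fields_100(self, vocab):
        case = make_report("R1", terms=["Hypertension"], age_group="18-44", sex="female")
        s = summarize_cohort([case], vocab)
        assert s.pct_female == 100.0
        assert s.age_pcts["18-44"] == 100.0
        assert s.n_serious_known == 0 and s.pct_serious is None

    def test_small_cohort_counts(self, vocab):
        cases = []
        for i in range(10):
            cases.append(
                make_report(
                    f"R{i}",
                    terms=["Hypertension"] + (["Cerebrovascular accident"] if i < 2 else []),
                    drugs=[("N06AB06", "suspect")] + ([("C02AC01", "concomitant")] if i < 3 else []),
                    age_group="45-64" if i < 6 else "75plus",
                    sex="female" if i < 7 else "male",
                    serious="yes" if i < 8 else "no",
                    criteria=["hospitalization"] if i < 4 else ([] if i >= 8 else ["other"]),
                )
            )
        s = summarize_cohort(cases, vocab, n_total_reports=500)
        assert s.n_cases == 10
        assert s.pct_female == 70.0
        assert s.age_counts["45-64"] == 6 and s.age_pcts["45-64"] == 60.0
        assert s.n_serious == 8 and s.n_serious_known == 10 and s.pct_serious == 80.0
        assert s.criteria_counts["hospitalization"] == 4
        assert s.criteria_pcts["hospitalization"] == 50.0  # over serious reports
        assert s.n_stroke == 2 and s.pct_stroke == 20.0
        assert s.n_antihypertensive == 3 and s.pct_antihypertensive == 30.0
        assert s.n_cvd == 2
        assert s.prevalence_pct == 2.0

    def test_percentages_recompute_from_counts(self, vocab):
        """Every emitted percentage equals 100*count/denominator rounded
        half-up to one decimal."""
        cases = [
            make_report(f"R{i}", terms=["Hypertension"], sex="female" if i % 3 else "male",
                        serious="yes" if i % 2 else "no",
                        criteria=["death"] if i % 2 else [])
            for i in range(23)
        ]
        s = summarize_cohort(cases, vocab)
        for row in s.rows():
            if row["percent"] is not None and row["denominator"]:
                assert row["percent"] == round_half_up(
                    100.0 * row["count"] / row["denominator"], 1
                )


class TestTimeToOnset:
    def test_no_dates_is_na(self, vocab):
        cases = [make_report("R1", terms=["Hypertension"], drugs=[("N06AB06", "suspect")])]
        tto = time_to_onset(cases, "sertraline", vocab)
        assert tto.n_available == 0 and tto.median_days is None

    def test_same_day_onset_is_zero(self, vocab):
        cases = [
            make_report(
                "R1",
                terms=[("Hypertension", D(2020, 1, 1))],
                drugs=[("N06AB06", "suspect", {"start_date": D(2020, 1, 1)})],
            )
        ]
        tto = time_to_onset(cases, "sertraline", vocab)
        assert tto.n_available == 1 and tto.median_days == 0.0

    def test_midpoint_quartiles(self, vocab):
        start = D(2020, 1, 1)
        cases = [
            make_report(
                f"R{i}",
                terms=[("Hypertension", start + datetime.timedelta(days=d))],
                drugs=[("N06AB06", "suspect", {"start_date": start})],
            )
            for i, d in enumerate([1, 1, 4, 1, 5])
        ]
        tto = time_to_onset(cases, "sertraline", vocab)
        assert tto.n_available == 5
        assert tto.median_days == 1.0
        assert (tto.iqr_low_days, tto.iqr_high_days) == (1.0, 4.0)

    def test_negative_tto_excluded(self, vocab):
        cases = [
            make_report(
                "R1",
                terms=[("Hypertension", D(2020, 1, 1))],
                drugs=[("N06AB06", "suspect", {"start_date": D(2020, 2, 1)})],
            )
        ]
        tto = time_to_onset(cases, "sertraline", vocab)
        assert tto.n_available == 0

    def test_earliest_matching_onset_used(self, vocab):
        cases = [
            make_report(
                "R1",
                terms=[
                    ("Hypertension", D(2020, 3, 1)),
                    ("Blood pressure increased", D(2020, 1, 10)),
                    ("Nausea", D(2020, 1, 2)),  # non-matching: ignored
                ],
                drugs=[("N06AB06", "suspect", {"start_date": D(2020, 1, 1)})],
            )
        ]
        tto = time_to_onset(cases, "sertraline", vocab)
        assert tto.median_days == 9.0

    def test_permutation_invariant_and_noncases_irrelevant(self, vocab):
        start = D(2020, 1, 1)
        cases = [
            make_report(
                f"R{i}",
                terms=[("Hypertension", start + datetime.timedelta(days=d))],
                drugs=[("N06AB06", "suspect", {"start_date": start})],
            )
            for i, d in enumerate([3, 9, 27])
        ]
        t1 = time_to_onset(cases, "sertraline", vocab)
        t2 = time_to_onset(cases[::-1], "sertraline", vocab)
        assert (t1.median_days, t1.iqr_low_days) == (t2.median_days, t2.iqr_low_days)


class TestChallengeCounts:
    def test_zero_exposed(self, vocab):
        cases = [make_report("R1", terms=["Hypertension"], drugs=[("A02BC01", "suspect")])]
        assert challenge_counts(cases, "sertraline", vocab) == (0, 0)

    def test_positive_flags(self, vocab):
        cases = [
            make_report(
                "R1",
                terms=["Hypertension"],
                drugs=[("N06AB06", "suspect", {"dechallenge": "positive", "rechallenge": "positive"})],
            )
        ]
        assert challenge_counts(cases, "sertraline", vocab) == (1, 1)

    def test_two_target_entries_counted_once_per_drug(self, vocab):
        cases = [
            make_report(
                "R1",
                terms=["Hypertension"],
                drugs=[
                    ("N06AB06", "suspect", {"dechallenge": "positive"}),
                    ("N06AB06", "concomitant", {"dechallenge": "positive"}),
                    ("N06AB03", "suspect", {"rechallenge": "positive"}),
                ],
            )
        ]
        assert challenge_counts(cases, "sertraline", vocab) == (1, 0)
        assert challenge_counts(cases, "fluoxetine", vocab) == (0, 1)
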