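import math

import numpy as np
import pandas as pd
import pytest

from motr.trajectory import (
    FilterPolicy,
    assign_nearest_word,
    compute_measures,
    filter_associations,
    filter_participants,
    measures_from_samples,
    merge_associations,
)

from _oracles import oracle_measures, random_association_sequence

MEASURES = ("gaze_duration", "go_past", "total_duration", "fp_reg", "reg_in")


def _nan_eq(a, b):
    return (math.isnan(a) and math.isnan(b)) or (
        not math.isnan(a) and not math.isnan(b) and abs(a - b) < 1e-9
    )


class TestAssignNearestWord:
    def test_sample_inside_box_maps_to_that_word(self, five_word_layout):
        s = pd.DataFrame({"t": [0.0], "x": [240.0], "y": [15.0]})
        assert assign_nearest_word(s, five_word_layout)[0] == 2

    def test_equidistant_tie_goes_to_leftmost_word(self, five_word_layout):
        # x=90 is 10 px from word 0's box [0, 80) and 10 px from word 1's [100, 180)
        s = pd.DataFrame({"t": [0.0], "x": [90.0], "y": [15.0]})
        assert assign_nearest_word(s, five_word_layout)[0] == 0

    def test_matches_exhaustive_search_on_random_clouds(self, five_word_layout):
        rng = np.random.default_rng(5)
        s = pd.DataFrame(
            {"t": np.arange(500) * 50.0,
             "x": rng.uniform(-100, 700, 500),
             "y": rng.uniform(-50, 120, 500)}
        )
        got = assign_nearest_word(s, five_word_layout)
        for i, (x, y) in enumerate(zip(s["x"], s["y"])):
            best, best_d = None, np.inf
            for w in five_word_layout.itertuples():
                dx = max(w.x_min - x, x - w.x_max, 0.0)
                dy = max(w.y_min - y, y - w.y_max, 0.0)
                d = dx * dx + dy * dy
                if d < best_d - 1e-12:
                    best, best_d = w.word_index, d
            assert got[i] == best

    def test_empty_layout_is_an_error(self, five_word_layout):
        s = pd.DataFrame({"t": [0.0], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="empty layout"):
            assign_nearest_word(s, five_word_layout.iloc[0:0])


class TestMergeAssociations:
    def test_run_of_ten_samples_merges_to_500ms(self):
        s = pd.DataFrame({"t": np.arange(11) * 50.0})
        w = np.array([3] * 10 + [4])
        a = merge_associations(s, w)
        assert a.iloc[0].word_index == 3 and a.iloc[0].duration == 500.0

    def test_alternating_words_yield_one_association_per_sample(self):
        s = pd.DataFrame({"t": np.arange(6) * 50.0})
        w = np.array([0, 1, 0, 1, 0, 1])
        a = merge_associations(s, w)
        assert len(a) == 6 and (a["duration"] == 50.0).all()

    def test_single_sample_trial_gets_one_nominal_period(self):
        s = pd.DataFrame({"t": [0.0]})
        a = merge_associations(s, np.array([2]))
        assert len(a) == 1 and a.iloc[0].duration == 50.0

    def test_durations_span_gaps_to_next_onset(self):
        # a 200 ms gap in sampling is credited to the association before it
        s = pd.DataFrame({"t": [0.0, 50.0, 250.0]})
        a = merge_associations(s, np.array([0, 1, 1]))
        assert a["duration"].tolist() == [50.0, 250.0]


class TestFilterAssociations:
    @pytest.mark.parametrize(
        "duration,kept",
        [(150.0, False), (160.0, True), (4000.0, True), (4001.0, False)],
    )
    def test_exclusion_boundaries_are_strict(self, duration, kept):
        """Only associations strictly shorter than 160 ms or strictly longer
        than 4000 ms are excluded."""
        a = pd.DataFrame({"word_index": [0], "onset": [0.0], "duration": [duration]})
        out = filter_associations(a)
        assert (len(out) == 1) is kept

    def test_remerge_sums_adjacent_same_word_runs(self):
        a = pd.DataFrame(
            {"word_index": [0, 1, 0], "onset": [0.0, 300.0, 400.0],
             "duration": [300.0, 100.0, 200.0]}
        )
        out = filter_associations(a, FilterPolicy())
        assert out["word_index"].tolist() == [0]
        assert out["duration"].tolist() == [500.0]

    def test_remerge_can_be_disabled(self):
        a = pd.DataFrame(
            {"word_index": [0, 1, 0], "onset": [0.0, 300.0, 400.0],
             "duration": [300.0, 100.0, 200.0]}
        )
        out = filter_associations(a, FilterPolicy(remerge_after_filter=False))
        assert out["word_index"].tolist() == [0, 0]

    def test_remerged_run_rechecked_against_maximum_only(self):
        a = pd.DataFrame(
            {"word_index": [0, 1, 0], "onset": [0.0, 2500.0, 2600.0],
             "duration": [2500.0, 100.0, 2000.0]}
        )
        out = filter_associations(a, FilterPolicy())
        assert len(out) == 0  # merged 4500 ms exceeds the 4000 ms cap

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            FilterPolicy(min_duration=500.0, max_duration=100.0)


class TestComputeMeasures:
    def test_left_to_right_pass_collapses_all_durations(self, five_word_layout):
        a = pd.DataFrame(
            {"word_index": np.arange(5), "onset": np.arange(5) * 300.0,
             "duration": [300.0] * 5}
        )
        m = compute_measures(a, five_word_layout, granularity="word")
        assert (m["gaze_duration"] == m["total_duration"]).all()
        # every unit but the last is passed rightward
        assert (m["go_past"].iloc[:4] == m["gaze_duration"].iloc[:4]).all()
        assert (m["fp_reg"].iloc[:4] == 0).all() and (m["reg_in"] == 0).all()

    def test_regression_sequence_worked_example(self, five_word_layout):
        """w1(300) w2(250) w1(200) w2(300) w3(400): the regression from w2
        splits its gaze (250) from its go-past (750) and total (550)."""
        a = pd.DataFrame(
            {"word_index": [0, 1, 0, 1, 2],
             "onset": [0.0, 300.0, 550.0, 750.0, 1050.0],
             "duration": [300.0, 250.0, 200.0, 300.0, 400.0]}
        )
        m = compute_measures(a, five_word_layout, granularity="word").set_index("word")
        assert m.loc[1, "gaze_duration"] == 250.0
        assert m.loc[1, "go_past"] == 750.0
        assert m.loc[1, "total_duration"] == 550.0
        assert m.loc[1, "fp_reg"] == 1.0 and m.loc[1, "reg_in"] == 0.0
        assert m.loc[0, "total_duration"] == 500.0
        assert m.loc[0, "reg_in"] == 1.0 and m.loc[0, "fp_reg"] == 0.0
        assert m.loc[2, "gaze_duration"] == 400.0
        assert math.isnan(m.loc[2, "go_past"])  # never passed rightward
        assert math.isnan(m.loc[3, "total_duration"])  # never fixated

    def test_oracle_equivalence_on_random_sequences(self):
        """Pipeline measures equal the literal brute-force walk exactly."""
        rng = np.random.default_rng(202)
        for _ in range(250):
            units, durs, all_units = random_association_sequence(rng)
            lay = pd.DataFrame(
                {"trial": "x", "word_index": np.arange(len(all_units)),
                 "text": "w", "x_min": np.arange(len(all_units)) * 100.0,
                 "x_max": np.arange(len(all_units)) * 100.0 + 80.0,
                 "y_min": 0.0, "y_max": 30.0, "region": all_units}
            )
            a = pd.DataFrame(
                {"word_index": [u - 1 for u in units],
                 "onset": np.arange(len(units)) * 100.0, "duration": durs}
            )
            got = compute_measures(a, lay, granularity="region").set_index("region")
            exp = oracle_measures(units, durs, all_units)
            for u in all_units:
                for meas in MEASURES:
                    assert _nan_eq(got.loc[u, meas], exp[u][meas]), (units, u, meas)

    def test_total_duration_is_conserved(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            units, durs, all_units = random_association_sequence(rng)
            lay = pd.DataFrame(
                {"trial": "x", "word_index": np.arange(len(all_units)), "text": "w",
                 "x_min": np.arange(len(all_units)) * 100.0,
                 "x_max": np.arange(len(all_units)) * 100.0 + 80.0,
                 "y_min": 0.0, "y_max": 30.0, "region": all_units}
            )
            a = pd.DataFrame(
                {"word_index": [u - 1 for u in units],
                 "onset": np.arange(len(units)) * 100.0, "duration": durs}
            )
            m = compute_measures(a, lay, granularity="region")
            assert np.isclose(m["total_duration"].sum(), sum(durs))

    def test_region_totals_equal_summed_word_totals(self, five_word_layout):
        lay = five_word_layout.copy()
        lay["region"] = [1, 1, 2, 2, 3]  # multi-word regions
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(3, 25))
            a = pd.DataFrame(
                {"word_index": rng.integers(0, 5, n),
                 "onset": np.arange(n) * 100.0,
                 "duration": rng.uniform(50, 500, n)}
            )
            a = a[a["word_index"].shift() != a["word_index"]].reset_index(drop=True)
            mw = compute_measures(a, lay, granularity="word")
            mr = compute_measures(a, lay, granularity="region")
            word_sum = (
                mw.join(lay.set_index("word_index")["region"], on="word")
                .groupby("region")["total_duration"].sum(min_count=1)
            )
            for r in (1, 2, 3):
                got = mr.set_index("region").loc[r, "total_duration"]
                exp = word_sum.get(r, np.nan)
                assert _nan_eq(got, exp)

    def test_revisit_monotonicity(self, five_word_layout):
        """Adding a post-first-pass rightward-exit revisit raises total
        duration, sets RegIn, and leaves gaze duration unchanged."""
        base = pd.DataFrame(
            {"word_index": [0, 1, 2], "onset": [0.0, 300.0, 600.0],
             "duration": [300.0, 300.0, 300.0]}
        )
        revisit = pd.DataFrame(
            {"word_index": [0, 1, 2, 1, 2], "onset": np.arange(5) * 300.0,
             "duration": [300.0] * 5}
        )
        m0 = compute_measures(base, five_word_layout, granularity="word").set_index("word")
        m1 = compute_measures(revisit, five_word_layout, granularity="word").set_index("word")
        assert m1.loc[1, "total_duration"] > m0.loc[1, "total_duration"]
        assert m1.loc[1, "reg_in"] == 1.0 and m0.loc[1, "reg_in"] == 0.0
        assert m1.loc[1, "gaze_duration"] == m0.loc[1, "gaze_duration"]

    def test_association_to_unknown_word_raises(self, five_word_layout):
        a = pd.DataFrame({"word_index": [9], "onset": [0.0], "duration": [100.0]})
        with pytest.raises(KeyError, match="9"):
            compute_measures(a, five_word_layout)


class TestFilterParticipants:
    def _measures(self, pids):
        return pd.DataFrame(
            {"participant_id": pids, "item_id": "i1", "region": 3,
             "total_duration": 400.0}
        )

    def _comp(self, acc_by_pid, n=100):
        rows = []
        for pid, acc in acc_by_pid.items():
            k = int(round(acc * n))
            rows += [(pid, f"q{i}", 1) for i in range(k)]
            rows += [(pid, f"q{k + i}", 0) for i in range(n - k)]
        return pd.DataFrame(rows, columns=["participant_id", "item_id", "correct"])

    def test_accuracy_below_threshold_excluded_at_threshold_retained(self):
        meas = self._measures(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        comp = self._comp({"a": 0.79, "b": 0.80, "c": 0.95})
        kept, report = filter_participants(meas, comp)
        assert set(kept["participant_id"]) == {"b", "c"}
        rep = report.set_index("participant_id")
        assert rep.loc["a", "excluded"] and not rep.loc["b", "excluded"]
        assert np.isclose(rep.loc["a", "accuracy"], 0.79)

    def test_all_above_threshold_gives_empty_exclusions(self):
        meas = self._measures(["a", "b"])
        kept, report = filter_participants(meas, self._comp({"a": 0.9, "b": 1.0}))
        assert len(kept) == len(meas) and not report["excluded"].any()

    def test_participant_without_records_is_an_error(self):
        meas = self._measures(["a", "zz"])
        with pytest.raises(ValueError, match="zz"):
            filter_participants(meas, self._comp({"a": 0.9}))


def test_pipeline_runs_on_simulated_study(small_study):
    measures, assocs = measures_from_samples(
        small_study["samples"], small_study["layouts"]
    )
    assert set(measures["region"].dropna()) <= {1, 2, 3, 4, 5}
    assert (assocs["duration"] >= 160.0).all()
    gaze, gp = measures["gaze_duration"], measures["go_past"]
    both = gaze.notna() & gp.notna()
    assert (gaze[both] <= gp[both] + 1e-9).all()
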