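"""Tests for alignment, disagreement detection, and the adjudication merge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tstscore import (
    RescoreSettings,
    TrialClock,
    ValidationError,
    align,
    apply_decisions,
    estimate_lag,
    filter_clips,
    find_disagreements,
    marks_to_table,
    rescore_pipeline,
    table_to_timeline,
    timeline_to_table,
    total_immobility,
)
from tstscore.rescore import DisagreementClip

from .conftest import majority_oracle, random_table, timeline_from


def brute_force_lag(x: np.ndarray, y: np.ndarray, max_lag: int) -> int:
    """Independent oracle: argmax of matching-frame count over all lags,
    smallest |lag| then negative lag on ties."""
    best, best_lag = -1, 0
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        if lag >= 0:
            matches = int(np.sum(x[: x.size - lag] == y[lag:]))
        else:
            matches = int(np.sum(x[-lag:] == y[: y.size + lag]))
        if matches > best:
            best, best_lag = matches, lag
    return best_lag


def brute_force_disagreements(x: np.ndarray, y: np.ndarray):
    """Independent oracle: per-frame loop collecting (start, end) runs of
    differing frames, 1-based inclusive."""
    runs, start = [], None
    for f in range(x.size):
        if x[f] != y[f]:
            if start is None:
                start = f + 1
        elif start is not None:
            runs.append((start, f))
            start = None
    if start is not None:
        runs.append((start, x.size))
    return runs


class TestEstimateLag:
    def test_identity_lag_zero(self):
        rng = np.random.default_rng(0)
        tl = table_to_timeline(random_table(rng, TrialClock(30.0, 2000)))
        assert estimate_lag(tl, tl, 60) == 0

    def test_pure_delay_recovered(self):
        rng = np.random.default_rng(1)
        tl = table_to_timeline(random_table(rng, TrialClock(30.0, 2000)))
        delayed = align(tl, -7)  # shift content later by 7 frames
        got = estimate_lag(tl, delayed, 30)
        assert got == brute_force_lag(tl.states, delayed.states, 30) == 7

    def test_constant_timeline_warns_lag_zero(self):
        tl = timeline_from([0] * 200)
        other = timeline_from([0] * 199 + [1])
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_lag(tl, other, 10) == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), lag=st.integers(-12, 12))
    def test_matches_brute_force_argmax(self, seed, lag):
        rng = np.random.default_rng(seed)
        t1 = table_to_timeline(random_table(rng, TrialClock(30.0, 1500)))
        if t1.states.std() == 0:
            return
        t2 = align(t1, -lag)
        assert estimate_lag(t1, t2, 15) == brute_force_lag(t1.states, t2.states, 15)


class TestAlign:
    def test_lag_zero_unchanged(self):
        tl = timeline_from([0, 1, 0, 1])
        assert align(tl, 0) == tl

    def test_positive_lag_hand_shift(self):
        tl = timeline_from([0, 0, 1, 1, 1])
        assert align(tl, 1).states.tolist() == [0, 1, 1, 1, 1]

    def test_negative_lag_replicates_start(self):
        tl = timeline_from([0, 0, 1, 1, 1])
        assert align(tl, -2).states.tolist() == [0, 0, 0, 0, 1]

    def test_shift_algebra_boundary_only(self):
        rng = np.random.default_rng(5)
        tl = table_to_timeline(random_table(rng, TrialClock(30.0, 500)))
        for k in (1, 4, 9):
            back = align(align(tl, k), -k)
            assert int(np.sum(back.states != tl.states)) <= k


class TestFindDisagreements:
    def test_identical_timelines_no_clips(self):
        tl = timeline_from([1, 0, 1, 0, 1])
        assert find_disagreements(tl, tl) == []

    def test_hand_example_two_single_frame_clips(self):
        t1 = timeline_from([1, 1, 0, 0, 1])
        t2 = timeline_from([1, 0, 0, 1, 1])
        clips = find_disagreements(t1, t2)
        assert [(c.start_frame, c.end_frame) for c in clips] == [(2, 2), (4, 4)]
        assert clips[0].state_scorer1 == 1 and clips[0].state_scorer2 == 0

    def test_complementary_timelines_single_full_clip(self):
        t1 = timeline_from([1, 0, 1, 0])
        t2 = timeline_from([0, 1, 0, 1])
        clips = find_disagreements(t1, t2)
        assert len(clips) == 1
        assert (clips[0].start_frame, clips[0].end_frame) == (1, 4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_per_frame_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 2000))
        clock = TrialClock(30.0, n)
        t1 = table_to_timeline(random_table(rng, clock))
        t2 = table_to_timeline(random_table(rng, clock))
        clips = find_disagreements(t1, t2)
        assert [(c.start_frame, c.end_frame) for c in clips] == \
            brute_force_disagreements(t1.states, t2.states)


class TestFilterClips:
    def _clip(self, start, end, fps=30.0):
        n = end - start + 1
        return DisagreementClip(start, end, n, n / fps, 0, 1)

    def test_min_zero_everything_presented(self, clock30):
        clips = [self._clip(1, 10), self._clip(100, 200)]
        to_rescore, skipped = filter_clips(
            clips, RescoreSettings(min_disagreement_sec=0.0), clock30)
        assert to_rescore == clips and skipped == []

    def test_threshold_partitions(self, clock30):
        short = self._clip(1, 15)      # 0.5 s
        long = self._clip(100, 189)    # 3.0 s
        to_rescore, skipped = filter_clips(
            [short, long], RescoreSettings(min_disagreement_sec=1.0), clock30)
        assert to_rescore == [long] and skipped == [short]

    def test_min_above_duration_all_skipped(self, clock30):
        clips = [self._clip(1, 300)]
        to_rescore, skipped = filter_clips(
            clips, RescoreSettings(min_disagreement_sec=400.0), clock30)
        assert to_rescore == [] and skipped == clips

    def test_strict_inequality_at_boundary(self, clock30):
        exactly = self._clip(1, 30)  # exactly 1.0 s
        to_rescore, skipped = filter_clips(
            [exactly], RescoreSettings(min_disagreement_sec=1.0), clock30)
        assert to_rescore == [] and skipped == [exactly]


class TestApplyDecisions:
    def test_no_clips_identity(self):
        tl = timeline_from([1, 0, 1, 0])
        assert apply_decisions(tl, []) == tl

    def test_decisions_matching_primary_idempotent(self):
        tl = timeline_from([1] * 10 + [0] * 10)
        clip = DisagreementClip(3, 6, 4, 4 / 30, 1, 0, decision=1)
        assert apply_decisions(tl, [clip]) == tl

    def test_flip_changes_exactly_clip_frames(self):
        tl = timeline_from([1] * 30)
        clip = DisagreementClip(11, 20, 10, 10 / 30, 1, 0, decision=0)
        merged = apply_decisions(tl, [clip])
        assert int(np.sum(merged.states != tl.states)) == 10
        assert merged.states[10:20].tolist() == [0] * 10

    def test_undecided_clip_named_in_error(self):
        tl = timeline_from([1] * 30)
        clip = DisagreementClip(11, 20, 10, 10 / 30, 1, 0)
        with pytest.raises(ValidationError, match="11-20"):
            apply_decisions(tl, [clip])


class TestRescorePipeline:
    def test_identical_tables_pass_through(self, clock30):
        table = marks_to_table([500, 2000, 7000], 1, clock30)
        result = rescore_pipeline(table, table, decide=lambda c: 1)
        assert result.clips == [] and result.skipped_clips == []
        assert result.merged_table.segments == table.segments
        assert result.t_full_sec == pytest.approx(
            total_immobility(table_to_timeline(table)))

    def test_hand_merge_always_immobile(self):
        clock = TrialClock(10.0, 20)
        t1 = marks_to_table([6], 1, clock)        # mobile 1-5, immobile 6-20
        t2 = marks_to_table([11], 1, clock)       # mobile 1-10, immobile 11-20
        result = rescore_pipeline(
            t1, t2, decide=lambda c: 0,
            settings=RescoreSettings(min_disagreement_sec=0.0, max_lag_sec=0.0))
        # scorers disagree on frames 6-10; decision immobile everywhere there
        assert [(c.start_frame, c.end_frame, c.decision)
                for c in result.clips] == [(6, 10, 0)]
        expect = [1] * 5 + [0] * 15
        assert result.merged_timeline.states.tolist() == expect

    def test_decide_primary_state_returns_primary_totals(self, clock30):
        rng = np.random.default_rng(21)
        t1 = random_table(rng, clock30)
        t2 = random_table(rng, clock30)
        result = rescore_pipeline(
            t1, t2, decide=lambda c: c.state_scorer1,
            settings=RescoreSettings(min_disagreement_sec=0.0))
        assert result.merged_timeline == table_to_timeline(t1)
        assert result.t_full_sec == total_immobility(table_to_timeline(t1))

    def test_merge_conservation_outside_clips(self, clock30):
        rng = np.random.default_rng(22)
        t1 = random_table(rng, clock30)
        t2 = random_table(rng, clock30)
        result = rescore_pipeline(t1, t2, decide=lambda c: c.state_scorer2,
                                  settings=RescoreSettings(min_disagreement_sec=0.0))
        primary = table_to_timeline(t1)
        inside = np.zeros(clock30.n_frames, dtype=bool)
        for c in result.clips:
            inside[c.start_frame - 1: c.end_frame] = True
        assert np.array_equal(result.merged_timeline.states[~inside],
                              primary.states[~inside])

    def test_scorer_swap_symmetry_of_clip_spans(self, clock30):
        rng = np.random.default_rng(23)
        t1 = random_table(rng, clock30)
        t2 = random_table(rng, clock30)
        a = rescore_pipeline(t1, t2, decide=lambda c: 0,
                             settings=RescoreSettings(primary_scorer=1,
                                                      max_lag_sec=0.0))
        b = rescore_pipeline(t2, t1, decide=lambda c: 0,
                             settings=RescoreSettings(primary_scorer=2,
                                                      max_lag_sec=0.0))
        assert [(c.start_frame, c.end_frame) for c in a.clips] == \
            [(c.start_frame, c.end_frame) for c in b.clips]

    def test_mismatched_clock_rejected(self, clock30, small_clock):
        t1 = marks_to_table([500], 1, clock30)
        t2 = marks_to_table([50], 1, small_clock)
        with pytest.raises(ValidationError):
            rescore_pipeline(t1, t2, decide=lambda c: 1, clock=clock30)

    def test_oracle_rescore_reduces_cohort_error(self, clock30):
        """Core fidelity claim: adjudicating disagreements against ground
        truth cuts the cohort-mean immobility-time error well below either
        rater's, and the merged timeline mismatches truth on fewer frames
        than either rater's timeline on every trial."""
        from tstscore.simulate import (DEFAULT_PROCESS, DEFAULT_SCORER_1,
                                       DEFAULT_SCORER_2, simulate_cohort)
        cohort = simulate_cohort(30, DEFAULT_PROCESS, DEFAULT_SCORER_1,
                                 DEFAULT_SCORER_2, clock30, seed=99)
        errs = []
        for truth, s1, s2 in cohort:
            result = rescore_pipeline(s1, s2, decide=majority_oracle(truth))
            t_true = total_immobility(truth)
            errs.append((
                abs(result.t_full_sec - t_true),
                abs(total_immobility(table_to_timeline(s1)) - t_true),
                abs(total_immobility(table_to_timeline(s2)) - t_true),
            ))
            mism_m = int(np.sum(result.merged_timeline.states != truth.states))
            mism_1 = int(np.sum(table_to_timeline(s1).states != truth.states))
            mism_2 = int(np.sum(table_to_timeline(s2).states != truth.states))
            assert mism_m <= min(mism_1, mism_2)
        mean_m, mean_1, mean_2 = np.mean(errs, axis=0)
        assert mean_m < 0.7 * min(mean_1, mean_2)
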