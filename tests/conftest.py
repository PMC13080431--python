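"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tstscore import (
    MobilityStatusTable,
    MobilityTimeline,
    TrialClock,
    marks_to_table,
)


@pytest.fixture
def clock30() -> TrialClock:
    """Standard 6-min trial at 30 fps."""
    return TrialClock(fps=30.0, n_frames=10800)


@pytest.fixture
def small_clock() -> TrialClock:
    return TrialClock(fps=10.0, n_frames=100)


def random_table(rng: np.random.Generator,
                 clock: TrialClock | None = None,
                 max_marks: int = 20) -> MobilityStatusTable:
    """A random valid status table: random clock, random toggle stream."""
    if clock is None:
        fps = float(rng.choice([24.0, 25.0, 30.0]))
        n_frames = int(rng.integers(10, 3000))
        clock = TrialClock(fps, n_frames)
    n_marks = int(rng.integers(0, min(max_marks, clock.n_frames - 1) + 1))
    marks = sorted(rng.choice(np.arange(2, clock.n_frames + 1),
                              size=n_marks, replace=False).tolist())
    return marks_to_table(marks, int(rng.integers(0, 2)), clock,
                          scorer="rand", trial_id="rand_trial")


def timeline_from(states, fps: float = 30.0) -> MobilityTimeline:
    states = np.asarray(states, dtype=np.int8)
    return MobilityTimeline(states, TrialClock(fps, states.size))


def majority_oracle(truth: MobilityTimeline):
    """Adjudicator that looks up ground truth and returns the majority
    state inside the clip (ties go to mobile)."""
    def decide(clip):
        window = truth.states[clip.start_frame - 1: clip.end_frame]
        return int(window.mean() >= 0.5)
    return decide
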