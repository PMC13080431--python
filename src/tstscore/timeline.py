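"""Domain model for tail-suspension-test mobility timelines.

A trial is scored as an alternating sequence of mobility states: 0 for
immobility (hanging without movement, two-foot paddling, momentum swinging)
and 1 for mobility (climbing attempts, four-foot running, jolting). Two
equivalent representations are used throughout the package:

* :class:`MobilityStatusTable` — the run-length form, one row per maximal
  constant-state segment, mirroring the five-column CSV a scorer produces
  (``Mobility_state, Mark_frames, Interval_frames, Mark_sec, Interval_sec``);
* :class:`MobilityTimeline` — the per-frame binary vector used by the
  alignment and disagreement machinery.

Frame indexing is 1-based and inclusive everywhere a frame number crosses a
public interface, matching the ``Mark_frames`` dialect of the CSV files.
Seconds columns are always derived from frames as ``frame / fps``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "TrialClock",
    "Mark",
    "StatusSegment",
    "MobilityStatusTable",
    "MobilityTimeline",
    "ImmobilitySummary",
    "Violation",
    "marks_to_table",
    "table_to_timeline",
    "timeline_to_table",
    "total_immobility",
    "partial_immobility",
    "validate_table",
]


@dataclass(frozen=True)
class TrialClock:
    """Timing of a trial: frame rate and total frame count.

    ``duration_sec`` is derived (``n_frames / fps``); the video itself is
    never read, so fps and frame count are supplied by the caller.
    """

    fps: float
    n_frames: int

    def __post_init__(self):
        if not self.fps > 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if not (isinstance(self.n_frames, (int, np.integer)) and self.n_frames >= 1):
            raise ValidationError(f"n_frames must be a positive integer, got {self.n_frames}")

    @property
    def duration_sec(self) -> float:
        return self.n_frames / self.fps

    @property
    def frame_period_sec(self) -> float:
        return 1.0 / self.fps

    def to_sec(self, frames: float) -> float:
        return frames / self.fps

    def to_frames(self, sec: float) -> int:
        """Nearest-frame conversion of a duration in seconds."""
        return int(round(sec * self.fps))


@dataclass(frozen=True)
class Mark:
    """A scorer's toggle event: the frame (1-based) at which the recorded
    mobility state changed, with its frame time in seconds."""

    frame: int
    time_sec: float

    @classmethod
    def at(cls, frame: int, clock: TrialClock) -> "Mark":
        if not 1 <= frame <= clock.n_frames:
            raise ValidationError(
                f"mark frame {frame} outside trial [1, {clock.n_frames}]"
            )
        return cls(frame=int(frame), time_sec=frame / clock.fps)


@dataclass(frozen=True)
class StatusSegment:
    """One maximal constant-state run: state, start frame, length, and the
    paired seconds columns (always ``frames / fps``)."""

    mobility_state: int
    mark_frame: int
    interval_frames: int
    mark_sec: float
    interval_sec: float

    @classmethod
    def build(cls, state: int, mark_frame: int, interval_frames: int,
              clock: TrialClock) -> "StatusSegment":
        return cls(
            mobility_state=int(state),
            mark_frame=int(mark_frame),
            interval_frames=int(interval_frames),
            mark_sec=mark_frame / clock.fps,
            interval_sec=interval_frames / clock.fps,
        )

    @property
    def end_frame(self) -> int:
        """Last frame of the segment (inclusive)."""
        return self.mark_frame + self.interval_frames - 1


@dataclass(frozen=True)
class Violation:
    """One broken table invariant, localised to a row (0-based segment
    index; -1 for table-level invariants)."""

    row: int
    invariant: str
    observed: object
    expected: object

    def __str__(self) -> str:
        where = f"row {self.row}" if self.row >= 0 else "table"
        return (f"{where}: {self.invariant} violated "
                f"(observed {self.observed}, expected {self.expected})")


@dataclass
class MobilityStatusTable:
    """Ordered run-length record of a scored trial."""

    segments: list[StatusSegment]
    clock: TrialClock
    scorer: str = ""
    trial_id: str = ""

    def __post_init__(self):
        self.segments = list(self.segments)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MobilityStatusTable):
            return NotImplemented
        return (self.segments == other.segments and self.clock == other.clock
                and self.scorer == other.scorer and self.trial_id == other.trial_id)

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every broken invariant."""
        violations = validate_table(self)
        if violations:
            raise ValidationError(
                "invalid mobility status table: "
                + "; ".join(str(v) for v in violations),
                violations=violations,
            )


@dataclass
class MobilityTimeline:
    """Per-frame mobility vector: ``states[f-1]`` is the state at frame ``f``."""

    states: np.ndarray
    clock: TrialClock

    def __post_init__(self):
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 1:
            raise ValidationError("timeline states must be a 1-D sequence")
        if states.size != self.clock.n_frames:
            raise ValidationError(
                f"timeline length {states.size} != n_frames {self.clock.n_frames}"
            )
        if states.size and not np.isin(states, (0, 1)).all():
            bad = states[~np.isin(states, (0, 1))][0]
            raise ValidationError(f"timeline contains non-binary state {bad}")
        self.states = states

    def __eq__(self, other) -> bool:
        if not isinstance(other, MobilityTimeline):
            return NotImplemented
        return self.clock == other.clock and np.array_equal(self.states, other.states)

    def copy(self) -> "MobilityTimeline":
        return MobilityTimeline(self.states.copy(), self.clock)


@dataclass(frozen=True)
class ImmobilitySummary:
    """Cumulative immobility times plus trial provenance.

    ``t_full_sec`` is the full-trial cumulative immobility time (T_f);
    ``t_partial_sec`` excludes the first two minutes (T_p).
    """

    t_full_sec: float
    t_partial_sec: float
    trial_id: str = ""
    scorer: str = ""
    scored_on_date: str = ""
    video_path: str = ""
    results_path: str = ""

    def __post_init__(self):
        if not (0 <= self.t_partial_sec <= self.t_full_sec):
            raise ValidationError(
                f"require 0 <= t_partial_sec ({self.t_partial_sec}) "
                f"<= t_full_sec ({self.t_full_sec})"
            )


def marks_to_table(
    marks: Sequence[int | Mark],
    initial_state: int,
    clock: TrialClock,
    scorer: str = "",
    trial_id: str = "",
) -> MobilityStatusTable:
    """Turn a scorer's toggle stream into a mobility status table.

    Each mark flips the state, opening a new segment at the mark's frame;
    the table therefore has ``len(marks) + 1`` segments and covers
    ``[1, n_frames]`` exactly. Marks must be strictly increasing and lie in
    ``[2, n_frames]`` — a mark at frame 1 would make the first segment
    empty and is rejected rather than reinterpreted as a changed initial
    state.
    """
    if initial_state not in (0, 1):
        raise ValidationError(f"initial_state must be 0 or 1, got {initial_state}")
    frames = [m.frame if isinstance(m, Mark) else int(m) for m in marks]
    for i, f in enumerate(frames):
        if not 2 <= f <= clock.n_frames:
            raise ValidationError(
                f"mark {i}: frame {f} outside valid range [2, {clock.n_frames}]"
            )
        if i > 0 and f <= frames[i - 1]:
            kind = "duplicate" if f == frames[i - 1] else "non-monotonic"
            raise ValidationError(
                f"mark {i}: frame {f} is {kind} (previous mark at {frames[i - 1]})"
            )

    bounds = [1, *frames, clock.n_frames + 1]
    segments = []
    state = initial_state
    for start, nxt in zip(bounds[:-1], bounds[1:]):
        segments.append(StatusSegment.build(state, start, nxt - start, clock))
        state ^= 1
    return MobilityStatusTable(segments, clock, scorer=scorer, trial_id=trial_id)


def table_to_timeline(table: MobilityStatusTable) -> MobilityTimeline:
    """Expand a run-length table into its per-frame binary vector."""
    table.validate()
    states = np.empty(table.clock.n_frames, dtype=np.int8)
    for seg in table.segments:
        states[seg.mark_frame - 1: seg.end_frame] = seg.mobility_state
    return MobilityTimeline(states, table.clock)


def timeline_to_table(
    timeline: MobilityTimeline, scorer: str = "", trial_id: str = ""
) -> MobilityStatusTable:
    """Run-length encode a per-frame vector back into a status table.

    Exact inverse of :func:`table_to_timeline`.
    """
    states = timeline.states
    if states.size == 0:
        raise ValidationError("cannot tabulate an empty timeline")
    clock = timeline.clock
    change = np.flatnonzero(np.diff(states)) + 1  # 0-based start of each new run
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [states.size])))
    segments = [
        StatusSegment.build(int(states[s]), s + 1, int(n), clock)
        for s, n in zip(starts, lengths)
    ]
    return MobilityStatusTable(segments, clock, scorer=scorer, trial_id=trial_id)


def total_immobility(timeline: MobilityTimeline) -> float:
    """Cumulative immobility time in seconds: immobile-frame count / fps."""
    return float(np.count_nonzero(timeline.states == 0)) / timeline.clock.fps


def partial_immobility(timeline: MobilityTimeline, exclude_sec: float = 120.0) -> float:
    """Cumulative immobility time excluding the first ``exclude_sec`` seconds.

    A frame is counted iff its time ``frame / fps`` is strictly greater
    than ``exclude_sec``; boundary segments are split at the frame level.
    With ``exclude_sec=0`` this equals :func:`total_immobility`.
    """
    clock = timeline.clock
    if not 0 <= exclude_sec <= clock.duration_sec:
        raise ValidationError(
            f"exclude_sec {exclude_sec} outside [0, {clock.duration_sec}]"
        )
    # frame f has time f/fps; first counted frame is the smallest f with f/fps > exclude_sec
    first = int(np.floor(exclude_sec * clock.fps)) + 1
    return float(np.count_nonzero(timeline.states[first - 1:] == 0)) / clock.fps


# seconds columns written by other tools may carry round-off; tolerate up to
# half a frame period when checking, but never trust them over the frames
_SEC_SLACK_FRAMES = 0.5


def validate_table(table: MobilityStatusTable) -> list[Violation]:
    """Check every table invariant; return the violations (empty if valid).

    Checked per row: binary state, strict alternation with the previous
    row, interval >= 1, contiguity (each segment starts where the previous
    ended), and agreement of the seconds columns with ``frames / fps`` to
    within half a frame period. Checked per table: first segment starts at
    frame 1 and the intervals cover exactly ``n_frames``.
    """
    v: list[Violation] = []
    clock = table.clock
    segs = table.segments
    if not segs:
        return [Violation(-1, "non-empty", 0, ">= 1 segment")]

    if segs[0].mark_frame != 1:
        v.append(Violation(0, "first-frame", segs[0].mark_frame, 1))
    expected_next = segs[0].mark_frame
    prev_state = None
    for i, seg in enumerate(segs):
        if seg.mobility_state not in (0, 1):
            v.append(Violation(i, "binary-state", seg.mobility_state, "0 or 1"))
        if prev_state is not None and seg.mobility_state == prev_state:
            v.append(Violation(i, "alternation", seg.mobility_state,
                               f"!= previous state {prev_state}"))
        prev_state = seg.mobility_state
        if seg.interval_frames < 1:
            v.append(Violation(i, "positive-interval", seg.interval_frames, ">= 1"))
        if i > 0 and seg.mark_frame != expected_next:
            v.append(Violation(i, "contiguity", seg.mark_frame, expected_next))
        expected_next = seg.mark_frame + seg.interval_frames
        tol = _SEC_SLACK_FRAMES / clock.fps
        if abs(seg.mark_sec - seg.mark_frame / clock.fps) > tol:
            v.append(Violation(i, "mark-sec-consistency", seg.mark_sec,
                               seg.mark_frame / clock.fps))
        if abs(seg.interval_sec - seg.interval_frames / clock.fps) > tol:
            v.append(Violation(i, "interval-sec-consistency", seg.interval_sec,
                               seg.interval_frames / clock.fps))
    covered = sum(s.interval_frames for s in segs)
    if covered != clock.n_frames:
        v.append(Violation(-1, "coverage", covered, clock.n_frames))
    return v
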