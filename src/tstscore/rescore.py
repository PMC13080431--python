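"""Two-scorer adjudication: align, detect disagreements, merge.

The pipeline mirrors the workflow in which two raters independently score a
trial and a third rater resolves their disagreements:

1. expand both status tables to per-frame timelines;
2. estimate the constant reaction-time offset between the raters by
   cross-correlating the mean-centered timelines, and shift scorer 2 into
   scorer 1's frame of reference;
3. find disagreement clips — maximal runs of frames where the per-frame sum
   of the two binary timelines equals 1;
4. partition clips by the minimum-disagreement-length setting; only clips
   strictly longer are presented for adjudication;
5. start from the primary scorer's timeline and overwrite each adjudicated
   clip with its decided state (skipped clips default to the primary);
6. re-tabulate and compute the full (T_f) and partial (T_p) immobility
   times.

The adjudicator is an injected callback (``decide``) taking a
:class:`DisagreementClip` and returning 0 or 1, so a human, a scripted
rule, or a simulation ground-truth oracle are interchangeable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .timeline import (
    MobilityStatusTable,
    MobilityTimeline,
    TrialClock,
    partial_immobility,
    table_to_timeline,
    timeline_to_table,
    total_immobility,
)

__all__ = [
    "DisagreementClip",
    "RescoreSettings",
    "RescoreResult",
    "estimate_lag",
    "align",
    "find_disagreements",
    "filter_clips",
    "apply_decisions",
    "rescore_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class DisagreementClip:
    """A maximal contiguous frame interval where the two timelines differ.

    Frames are 1-based inclusive, in scorer 1's frame of reference (clips
    are defined after alignment). ``decision`` is the adjudicated state, or
    None while undecided.
    """

    start_frame: int
    end_frame: int
    n_frames: int
    duration_sec: float
    state_scorer1: int
    state_scorer2: int
    decision: int | None = None

    def __post_init__(self):
        if self.start_frame > self.end_frame:
            raise ValidationError(
                f"clip start {self.start_frame} > end {self.end_frame}"
            )
        if self.state_scorer1 == self.state_scorer2:
            raise ValidationError("a disagreement clip needs differing states")


@dataclass(frozen=True)
class RescoreSettings:
    """Adjudication settings.

    min_disagreement_sec
        Shortest duration a clip must exceed (strictly) to be presented
        for rescoring; shorter clips default to the primary scorer.
        Sub-second disagreements are dominated by residual reaction-time
        jitter, hence the 1 s default.
    primary_scorer
        1 or 2 — whose timeline seeds the merge and fills unadjudicated
        frames.
    max_lag_sec
        Bound on the cross-correlation lag search. Reaction-time
        differences are sub-second; a tight bound avoids spurious global
        alignments of quasi-periodic bout patterns.
    initial_state
        Expected state at trial start (1 = mobile: subjects initially
        struggle to escape). Used by score-mode mark conversion.
    """

    min_disagreement_sec: float = 1.0
    primary_scorer: int = 1
    max_lag_sec: float = 2.0
    initial_state: int = 1

    def __post_init__(self):
        if self.min_disagreement_sec < 0:
            raise ValidationError("min_disagreement_sec must be >= 0")
        if self.max_lag_sec < 0:
            raise ValidationError("max_lag_sec must be >= 0")
        if self.primary_scorer not in (1, 2):
            raise ValidationError("primary_scorer must be 1 or 2")
        if self.initial_state not in (0, 1):
            raise ValidationError("initial_state must be 0 or 1")


@dataclass
class RescoreResult:
    """Output of the full adjudication pipeline."""

    merged_timeline: MobilityTimeline
    merged_table: MobilityStatusTable
    clips: list[DisagreementClip]
    skipped_clips: list[DisagreementClip]
    lag_frames: int
    t_full_sec: float
    t_partial_sec: float


def estimate_lag(
    t1: MobilityTimeline, t2: MobilityTimeline, max_lag_frames: int
) -> int:
    """Estimate scorer 2's constant reaction-time offset relative to scorer 1.

    Returns the integer lag in ``[-max_lag_frames, +max_lag_frames]``
    maximizing the cross-correlation of the mean-centered state vectors;
    positive lag means scorer 2's toggles trail scorer 1's, i.e.
    ``t2[f] ~= t1[f - lag]``. Ties break toward the smallest ``|lag|``,
    then the negative lag. A constant timeline has no correlation
    structure; lag 0 is returned with a warning.
    """
    if t1.clock.n_frames != t2.clock.n_frames:
        raise ValidationError("timelines must have equal length")
    if not 0 <= max_lag_frames < t1.clock.n_frames:
        raise ValidationError(
            f"max_lag_frames {max_lag_frames} must be in [0, n_frames)"
        )
    x = t1.states.astype(np.float64)
    y = t2.states.astype(np.float64)
    if x.std() == 0 or y.std() == 0:
        warnings.warn(
            "constant timeline: cross-correlation undefined, assuming lag 0",
            stacklevel=2,
        )
        return 0
    x -= x.mean()
    y -= y.mean()
    n = x.size
    # candidates ordered so argmax tie-breaks to smallest |lag|, negative first
    lags = sorted(range(-max_lag_frames, max_lag_frames + 1),
                  key=lambda k: (abs(k), k))
    best_lag, best_score = 0, -np.inf
    for lag in lags:
        if lag >= 0:
            score = float(np.dot(x[: n - lag], y[lag:]))
        else:
            score = float(np.dot(x[-lag:], y[: n + lag]))
        if score > best_score:
            best_lag, best_score = lag, score
    return best_lag


def align(t2: MobilityTimeline, lag_frames: int) -> MobilityTimeline:
    """Shift scorer 2's timeline by ``-lag_frames`` into scorer 1's frame
    of reference. Frames shifted in from outside the trial replicate the
    nearest boundary state (a scorer's state before their first toggle is
    their initial state); length is preserved."""
    y = t2.states
    n = y.size
    if lag_frames == 0:
        return t2.copy()
    k = min(abs(int(lag_frames)), n)
    if lag_frames > 0:
        shifted = np.concatenate((y[k:], np.full(k, y[-1], dtype=y.dtype)))
    else:
        shifted = np.concatenate((np.full(k, y[0], dtype=y.dtype), y[: n - k]))
    return MobilityTimeline(shifted, t2.clock)


def find_disagreements(
    t1: MobilityTimeline, t2_aligned: MobilityTimeline
) -> list[DisagreementClip]:
    """Locate disagreement clips between two aligned timelines.

    The per-frame sum of the two binary vectors is formed; frames where it
    equals 1 are disagreement frames (one scorer says mobile, the other
    immobile), and maximal contiguous runs of them become clips, ordered by
    start frame.
    """
    if t1.clock.n_frames != t2_aligned.clock.n_frames:
        raise ValidationError("timelines must have equal length")
    clock = t1.clock
    disagree = (t1.states + t2_aligned.states) == 1
    padded = np.concatenate(([False], disagree, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # 0-based half-open runs
    clips = []
    for s, e in zip(starts, ends):
        clips.append(DisagreementClip(
            start_frame=int(s) + 1,
            end_frame=int(e),
            n_frames=int(e - s),
            duration_sec=(e - s) / clock.fps,
            state_scorer1=int(t1.states[s]),
            state_scorer2=int(t2_aligned.states[s]),
        ))
    return clips


def filter_clips(
    clips: Sequence[DisagreementClip],
    settings: RescoreSettings,
    clock: TrialClock,
) -> tuple[list[DisagreementClip], list[DisagreementClip]]:
    """Partition clips into (to_rescore, skipped) by the minimum
    disagreement length; a clip is rescored iff its duration is strictly
    longer than ``min_disagreement_sec``."""
    to_rescore = [c for c in clips if c.duration_sec > settings.min_disagreement_sec]
    skipped = [c for c in clips if c.duration_sec <= settings.min_disagreement_sec]
    return to_rescore, skipped


def apply_decisions(
    primary: MobilityTimeline,
    clips: Sequence[DisagreementClip],
    skipped: Sequence[DisagreementClip] = (),
) -> MobilityTimeline:
    """Overwrite each decided clip's frames with its decision on a copy of
    the primary scorer's timeline. Skipped clips are left untouched — those
    frames already carry the primary scorer's state by construction."""
    merged = primary.states.copy()
    for clip in clips:
        if clip.decision not in (0, 1):
            raise ValidationError(
                f"undecided clip at frames {clip.start_frame}-{clip.end_frame}"
            )
        if not (1 <= clip.start_frame and clip.end_frame <= merged.size):
            raise ValidationError(
                f"clip {clip.start_frame}-{clip.end_frame} outside trial bounds"
            )
        merged[clip.start_frame - 1: clip.end_frame] = clip.decision
    return MobilityTimeline(merged, primary.clock)


def rescore_pipeline(
    table1: MobilityStatusTable,
    table2: MobilityStatusTable,
    decide: Callable[[DisagreementClip], int],
    settings: RescoreSettings | None = None,
    clock: TrialClock | None = None,
    exclude_first_sec: float = 120.0,
) -> RescoreResult:
    """Run the full adjudication pipeline on two scorers' tables.

    ``decide`` is invoked once per presented clip, in temporal order, and
    must return the adjudicated state (0 or 1). Scorer 2 is always shifted
    into scorer 1's frame of reference; ``settings.primary_scorer`` only
    selects which timeline seeds the merge. Clip boundaries and the merged
    table are in scorer-1 frame coordinates.
    """
    settings = settings or RescoreSettings()
    clock = clock or table1.clock

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"rescore stage '{name}': {exc}") from exc

    if table1.clock != clock or table2.clock != clock:
        raise ValidationError("both tables must share the pipeline clock")
    t1 = _stage("expand-scorer1", table_to_timeline, table1)
    t2 = _stage("expand-scorer2", table_to_timeline, table2)

    max_lag = clock.to_frames(settings.max_lag_sec)
    lag = _stage("estimate-lag", estimate_lag, t1, t2, max_lag)
    logger.info("rescore: estimated lag %d frames (%.3f s)", lag, lag / clock.fps)
    t2a = _stage("align", align, t2, lag)

    clips = _stage("find-disagreements", find_disagreements, t1, t2a)
    to_rescore, skipped = _stage("filter-clips", filter_clips, clips, settings, clock)
    logger.info("rescore: %d disagreement clips (%d presented, %d skipped)",
                len(clips), len(to_rescore), len(skipped))

    decided = []
    for clip in to_rescore:
        decision = int(decide(clip))
        if decision not in (0, 1):
            raise ValidationError(
                f"decide returned {decision!r} for clip "
                f"{clip.start_frame}-{clip.end_frame}; must be 0 or 1"
            )
        decided.append(replace(clip, decision=decision))

    primary = t1 if settings.primary_scorer == 1 else t2a
    merged = _stage("apply-decisions", apply_decisions, primary, decided, skipped)
    merged_table = _stage(
        "tabulate", timeline_to_table, merged,
        scorer="rescore", trial_id=table1.trial_id,
    )
    t_full = total_immobility(merged)
    # trials shorter than the exclusion window have no post-window time
    t_partial = partial_immobility(merged,
                                   min(exclude_first_sec, clock.duration_sec))
    logger.info("rescore: T_f=%.2f s, T_p=%.2f s", t_full, t_partial)
    return RescoreResult(
        merged_timeline=merged,
        merged_table=merged_table,
        clips=decided,
        skipped_clips=skipped,
        lag_frames=lag,
        t_full_sec=t_full,
        t_partial_sec=t_partial,
    )
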