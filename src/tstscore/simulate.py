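"""Synthetic mobility timelines and parametric noisy scorers.

The generator provides ground truth the real assay cannot: a known
per-frame mobility timeline against which scorer output and adjudication
can be checked exactly.

Ground truth is an alternating-renewal bout process: the subject switches
between mobile and immobile bouts with exponentially distributed dwell
times (discretized to whole frames, minimum one). An optional linear trend
captures the qualitative course of the assay — escape attempts subside and
immobility bouts emerge as the trial proceeds.

A scorer watching the trial is modelled with four error sources:

* a constant reaction-time lag applied to every toggle;
* zero-mean Gaussian jitter on each toggle, independently;
* missed short bouts — a bout shorter than ``min_detectable_sec`` is merged
  into its neighbours with probability ``miss_prob``;
* state-call flips — with probability ``flip_prob`` a detected bout's state
  is inverted, which in a strictly alternating record is equivalent to
  merging it with both neighbours.

Everything is seeded explicitly; no global random state is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .timeline import (
    MobilityStatusTable,
    MobilityTimeline,
    TrialClock,
    marks_to_table,
    timeline_to_table,
)

__all__ = [
    "BoutProcess",
    "ScorerModel",
    "DEFAULT_CLOCK",
    "DEFAULT_PROCESS",
    "DEFAULT_SCORER_1",
    "DEFAULT_SCORER_2",
    "simulate_truth",
    "simulate_scorer",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoutProcess:
    """Alternating-renewal description of ground-truth behavior.

    Dwell times in each state are exponential with the given means (in
    seconds). ``immobility_trend`` >= 0 linearly scales the hazard of
    leaving the mobile state up (and of leaving the immobile state down)
    over the trial, so that by trial end the effective mobile-bout mean is
    divided by ``1 + trend`` and the immobile mean multiplied by it.
    """

    mean_mobile_bout_sec: float = 10.0
    mean_immobile_bout_sec: float = 10.0
    initial_state: int = 1
    immobility_trend: float = 0.0

    def __post_init__(self):
        if self.mean_mobile_bout_sec <= 0 or self.mean_immobile_bout_sec <= 0:
            raise ValidationError("bout means must be positive")
        if self.initial_state not in (0, 1):
            raise ValidationError("initial_state must be 0 or 1")
        if self.immobility_trend < 0:
            raise ValidationError("immobility_trend must be >= 0")


@dataclass(frozen=True)
class ScorerModel:
    """Parametric description of one human rater's observation noise."""

    lag_frames: int = 0
    jitter_sd_frames: float = 0.0
    miss_prob: float = 0.0
    flip_prob: float = 0.0
    min_detectable_sec: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.miss_prob <= 1 or not 0 <= self.flip_prob <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.jitter_sd_frames < 0:
            raise ValidationError("jitter_sd_frames must be >= 0")


# Study conditions: 6-min trial at 30 fps; symmetric 10 s bout means put the
# immobile fraction near one half, matching typical mid-trial assay levels.
DEFAULT_CLOCK = TrialClock(fps=30.0, n_frames=10800)
DEFAULT_PROCESS = BoutProcess()
# Two raters with realistic human reaction times (~0.1 s and ~0.3 s), a 1 s
# boundary-perception spread per toggle (mobility onsets/offsets are gradual
# and raters place them a second or so apart), a 30% chance of missing
# sub-second bouts, and rare (2%) whole-bout state-call inversions. These
# levels reproduce the disagreement magnitudes observed between trained
# human raters: tens of seconds of total disagreement per 6-min trial,
# clips typically under 10 s with occasional multi-ten-second outliers.
DEFAULT_SCORER_1 = ScorerModel(lag_frames=3, jitter_sd_frames=30.0,
                               miss_prob=0.3, flip_prob=0.02)
DEFAULT_SCORER_2 = ScorerModel(lag_frames=9, jitter_sd_frames=30.0,
                               miss_prob=0.3, flip_prob=0.02)


def simulate_truth(
    process: BoutProcess, clock: TrialClock, seed: int | np.random.SeedSequence
) -> MobilityTimeline:
    """Draw one ground-truth timeline from the bout process.

    Bouts alternate starting from ``initial_state``; each dwell is drawn
    from the (possibly time-modulated) exponential, discretized to at least
    one frame, and the sequence is truncated at ``n_frames``.
    """
    rng = np.random.default_rng(seed)
    states = np.empty(clock.n_frames, dtype=np.int8)
    state = process.initial_state
    frame = 0
    while frame < clock.n_frames:
        progress = frame / clock.n_frames
        scale = 1.0 + process.immobility_trend * progress
        mean = (process.mean_mobile_bout_sec / scale if state == 1
                else process.mean_immobile_bout_sec * scale)
        dwell = max(1, int(round(rng.exponential(mean) * clock.fps)))
        states[frame: frame + dwell] = state
        frame += dwell
        state ^= 1
    return MobilityTimeline(states, clock)


def simulate_scorer(
    truth: MobilityTimeline,
    model: ScorerModel,
    seed: int | np.random.SeedSequence | None = None,
    scorer: str = "",
    trial_id: str = "",
) -> MobilityStatusTable:
    """Simulate one rater's status table for a ground-truth timeline.

    The truth's transition marks are perturbed by the constant lag plus
    per-mark Gaussian jitter; bouts below the detectability threshold are
    dropped with probability ``miss_prob`` and state calls inverted with
    probability ``flip_prob`` (both implemented by deleting the bout's
    bounding toggle pair). Jittered marks that would cross or leave the
    trial are resolved by dropping the inner toggle pair, preserving a
    valid alternating table.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    clock = truth.clock
    truth_table = timeline_to_table(truth)
    segs = truth_table.segments

    # bout-level errors: a missed or flipped bout loses its bounding toggle
    # pair and is absorbed into its neighbours
    keep = [True] * len(segs)
    min_frames = clock.to_frames(model.min_detectable_sec)
    for i in range(1, len(segs) - 1):  # first/last bouts anchor the trial
        if segs[i].interval_frames < min_frames and rng.random() < model.miss_prob:
            keep[i] = False
        elif rng.random() < model.flip_prob:
            keep[i] = False

    # a mark exists wherever the observed state actually changes after the
    # dropped bouts are merged into the preceding kept segment
    kept = [(seg.mobility_state, seg.mark_frame)
            for i, seg in enumerate(segs) if keep[i]]
    marks = [kept[i][1] for i in range(1, len(kept))
             if kept[i][0] != kept[i - 1][0]]

    # observation timing: constant lag + per-mark jitter
    noisy = []
    for m in marks:
        jitter = rng.normal(0.0, model.jitter_sd_frames) if model.jitter_sd_frames else 0.0
        noisy.append(int(round(m + model.lag_frames + jitter)))
    # enforce a strictly increasing mark stream within [2, n_frames]:
    # crossing pairs lose the inner toggle pair (logged), out-of-range
    # marks are clamped
    cleaned: list[int] = []
    dropped = 0
    for m in noisy:
        m = min(max(m, 2), clock.n_frames)
        if cleaned and m <= cleaned[-1]:
            cleaned.pop()  # the crossing pair cancels: drop both toggles
            dropped += 1
            continue
        cleaned.append(m)
    if dropped:
        logger.debug("simulate_scorer: dropped %d crossing toggle pairs", dropped)

    initial = kept[0][0] if kept else int(truth.states[0])
    return marks_to_table(cleaned, int(initial), clock, scorer=scorer, trial_id=trial_id)


def simulate_cohort(
    n_trials: int,
    process: BoutProcess,
    model1: ScorerModel,
    model2: ScorerModel,
    clock: TrialClock,
    seed: int,
) -> list[tuple[MobilityTimeline, MobilityStatusTable, MobilityStatusTable]]:
    """Simulate ``n_trials`` independent (truth, table1, table2) triples.

    Per-trial streams are spawned from the master seed, so the whole cohort
    is reproducible from a single integer and trials are independent.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    master = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(master.spawn(n_trials)):
        ss_truth, ss_s1, ss_s2 = child.spawn(3)
        trial_id = f"sim_trial_{i:04d}"
        truth = simulate_truth(process, clock, ss_truth)
        t1 = simulate_scorer(truth, model1, ss_s1, scorer="sim_scorer_1",
                             trial_id=trial_id)
        t2 = simulate_scorer(truth, model2, ss_s2, scorer="sim_scorer_2",
                             trial_id=trial_id)
        out.append((truth, t1, t2))
    return out
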