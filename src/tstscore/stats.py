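"""Inter-scorer and inter-method agreement statistics.

Quantifies how well two raters (or two scoring methods) agree on total
immobility time across a cohort of trials: Pearson correlation of the
paired totals, Bland–Altman bias and 1.96·SD limits of agreement, per-trial
total disagreement duration, the distribution of disagreement-clip lengths
in 5 s bins, and the correlation of per-trial coefficient of variation with
mean immobility.

A key distinction throughout: the *difference* in total immobility time
understates the actual disagreement, because opposite-signed disagreement
clips cancel in the totals. ``total_disagreement_sec`` (the summed duration
of all clips) bounds ``|diff_sec|`` from above, never the reverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .rescore import RescoreSettings, align, estimate_lag, find_disagreements
from .timeline import (
    MobilityStatusTable,
    MobilityTimeline,
    TrialClock,
    table_to_timeline,
    total_immobility,
)

__all__ = [
    "BlandAltmanResult",
    "TrialAgreement",
    "CohortReport",
    "pearson",
    "bland_altman",
    "trial_agreement",
    "clip_length_histogram",
    "cohort_report",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman agreement summary for paired measurements.

    ``bias`` is the mean of the paired differences; the limits of agreement
    are ``bias ± 1.96 × sd_diff`` with the sample (n−1) standard deviation.
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    pairs: int

    @classmethod
    def from_differences(cls, diffs: np.ndarray) -> "BlandAltmanResult":
        bias = float(np.mean(diffs))
        sd = float(np.std(diffs, ddof=1))
        return cls(bias=bias, sd_diff=sd,
                   loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
                   pairs=len(diffs))


@dataclass
class TrialAgreement:
    """Per-trial agreement record between two scorers."""

    trial_id: str
    score1_sec: float
    score2_sec: float
    diff_sec: float                 # score1 - score2
    total_disagreement_sec: float   # summed duration of all disagreement clips
    clip_lengths_sec: list[float]


@dataclass
class CohortReport:
    """Cohort-level agreement statistics between two scorers."""

    trials: list[TrialAgreement]
    pearson_r: float
    pearson_p: float
    r_squared: float
    bland_altman: BlandAltmanResult
    disagreement_mean_sec: float
    disagreement_min_sec: float
    disagreement_max_sec: float
    clip_histogram: list[tuple[float, float, float]]  # (bin_left_sec, mean, sd)
    cv_vs_mean_r: float
    cv_vs_mean_p: float
    score1_median_iqr: tuple[float, float, float]  # (median, q1, q3)
    score2_median_iqr: tuple[float, float, float]


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p value from the t distribution
    on n−2 degrees of freedom. Zero variance in either input leaves the
    correlation undefined and is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError(f"need >= 3 pairs for a correlation, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: Pearson correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman analysis of paired measurements; differences are
    ``x − y`` (first scorer/method minus the second) and the plotted
    abscissa is ``(x + y) / 2``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 2:
        raise ValidationError(f"need >= 2 pairs, got {x.size}")
    return BlandAltmanResult.from_differences(x - y)


def trial_agreement(
    table1: MobilityStatusTable,
    table2: MobilityStatusTable,
    settings: RescoreSettings | None = None,
    clock: TrialClock | None = None,
) -> TrialAgreement:
    """Alignment + disagreement detection for a single trial pair.

    Clips are *not* filtered by the minimum disagreement length: agreement
    statistics describe all disagreement, not just what would be presented
    for rescoring.
    """
    settings = settings or RescoreSettings()
    clock = clock or table1.clock
    t1 = table_to_timeline(table1)
    t2 = table_to_timeline(table2)
    lag = estimate_lag(t1, t2, clock.to_frames(settings.max_lag_sec))
    t2a = align(t2, lag)
    clips = find_disagreements(t1, t2a)
    lengths = [c.duration_sec for c in clips]
    s1 = total_immobility(t1)
    s2 = total_immobility(t2)
    return TrialAgreement(
        trial_id=table1.trial_id,
        score1_sec=s1,
        score2_sec=s2,
        diff_sec=s1 - s2,
        total_disagreement_sec=float(sum(lengths)),
        clip_lengths_sec=lengths,
    )


def clip_length_histogram(
    trials: list[TrialAgreement], bin_sec: float = 5.0
) -> list[tuple[float, float, float]]:
    """Distribution of disagreement-clip lengths across trials.

    Clips are binned into [0, bin), [bin, 2·bin), ...; for each bin the
    per-trial clip count is computed and its mean and sd across trials
    returned as ``(bin_left_sec, mean, sd)``. Sample (n−1) sd for two or
    more trials; a single trial has no across-trial spread, sd 0.
    """
    if bin_sec <= 0:
        raise ValidationError("bin_sec must be positive")
    if not trials:
        raise ValidationError("need at least one trial")
    max_len = max((max(t.clip_lengths_sec, default=0.0) for t in trials), default=0.0)
    n_bins = max(1, int(np.floor(max_len / bin_sec)) + 1)
    counts = np.zeros((len(trials), n_bins))
    for i, t in enumerate(trials):
        for length in t.clip_lengths_sec:
            counts[i, min(int(length // bin_sec), n_bins - 1)] += 1
    means = counts.mean(axis=0)
    sds = counts.std(axis=0, ddof=1) if len(trials) > 1 else np.zeros(n_bins)
    return [(b * bin_sec, float(m), float(s))
            for b, (m, s) in enumerate(zip(means, sds))]


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def cohort_report(
    pairs: list[tuple[MobilityStatusTable, MobilityStatusTable]],
    settings: RescoreSettings | None = None,
    clock: TrialClock | None = None,
) -> CohortReport:
    """Assemble the full set of agreement statistics over a cohort.

    Per trial, the coefficient of variation is the sample sd of the two
    scores divided by their mean; trials with mean score 0 are excluded
    from the CV correlation with a warning. ``cv_vs_mean_r`` tests whether
    scorer variability scales with the immobility level itself.
    """
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 trial pairs, got {len(pairs)}")
    settings = settings or RescoreSettings()
    clock = clock or pairs[0][0].clock
    trials = [trial_agreement(t1, t2, settings, clock) for t1, t2 in pairs]

    s1 = np.array([t.score1_sec for t in trials])
    s2 = np.array([t.score2_sec for t in trials])
    r, p = pearson(s1, s2)
    ba = bland_altman(s1, s2)
    totals = np.array([t.total_disagreement_sec for t in trials])

    means = (s1 + s2) / 2.0
    sds = np.std(np.column_stack([s1, s2]), axis=1, ddof=1)
    usable = means > 0
    if not usable.all():
        warnings.warn(
            f"{np.count_nonzero(~usable)} trial(s) with mean score 0 "
            "excluded from the CV-vs-mean correlation", stacklevel=2,
        )
    cv = sds[usable] / means[usable]
    cv_r, cv_p = pearson(means[usable], cv)

    return CohortReport(
        trials=trials,
        pearson_r=r,
        pearson_p=p,
        r_squared=r * r,
        bland_altman=ba,
        disagreement_mean_sec=float(totals.mean()),
        disagreement_min_sec=float(totals.min()),
        disagreement_max_sec=float(totals.max()),
        clip_histogram=clip_length_histogram(trials),
        cv_vs_mean_r=cv_r,
        cv_vs_mean_p=cv_p,
        score1_median_iqr=_median_iqr(s1),
        score2_median_iqr=_median_iqr(s2),
    )
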