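# Methods

## The scored-timeline model

A trial is a fixed-length video at `fps` frames per second with `n_frames`
frames (defaults used throughout tests and examples: 30 fps, 10 800 frames
= 6 min, the assay's standard protocol). The subject's state at each frame
is binary: 0 immobile, 1 mobile. A rater's score is a strictly alternating
run-length table whose rows are maximal constant-state segments; the table
covers frames `[1, n_frames]` exactly, with no gaps or overlaps. The
per-frame timeline and the table are inverse representations, and the
package treats the frame columns as authoritative: seconds columns are
always recomputed as `frames / fps`, and imported files whose seconds
disagree with their frames by more than half a frame period are rejected
rather than repaired (hand-edited files are the main failure mode this
guards against; round-off from other tools within half a frame period is
tolerated and rewritten).

Frame indexing is 1-based and inclusive at every public interface. A mark
(toggle) at frame *m* opens a new segment at *m*; marks must lie in
`[2, n_frames]` — a mark at frame 1 would create an empty first segment, and
is treated as a user error rather than silently reinterpreted as a changed
initial state. The default initial state is mobile (1), since subjects
initially struggle when suspended; it is overridable.

T_f is the immobile-frame count over the whole trial divided by fps. T_p
restricts the count to frames with `frame/fps > exclude_sec` (default
120 s), a strict inequality; boundary segments are split at the frame
level, never pro-rated. Inside the rescore pipeline the exclusion window is
clamped to the trial duration so short (test or truncated) trials yield
T_p = 0 instead of an error; the standalone `partial_immobility` keeps its
strict range check.

## Rescore pipeline numerics

**Lag estimation.** The two per-frame timelines are mean-centered and their
unnormalized cross-correlation is evaluated at every integer lag within
±`max_lag_sec` (default 2.0 s = 60 frames at 30 fps; reaction-time
differences are sub-second, and a tight bound prevents spurious global
alignments of quasi-periodic bout patterns). Positive lag means rater 2's
toggles trail rater 1's. Ties break to the smallest |lag|, then to the
negative lag. A constant timeline has no correlation structure: lag 0 is
returned with a warning. The estimator is cross-checked in the tests
against a brute-force matching-frame-count argmax.

**Alignment.** Rater 2 is always shifted into rater 1's frame of reference,
regardless of which rater is primary (the primary choice affects only whose
timeline seeds the merge). Frames shifted in from outside the trial
replicate the nearest boundary state — a rater's state before their first
toggle is their initial state. Clip boundaries and the merged table are
therefore in rater-1 frame coordinates.

**Disagreement clips.** The per-frame sum of the two binary timelines is 1
exactly where the raters disagree; maximal runs of such frames become
clips, ordered by start frame, disjoint and non-adjacent by construction.
The vectorized detector is validated against a literal per-frame loop.

**Filtering and merge.** Clips are presented for adjudication iff their
duration is *strictly* greater than `min_disagreement_sec` (default 1.0 s:
sub-second disagreements are dominated by residual reaction-time jitter,
and adjudicating them costs rater time without improving totals much).
Skipped clips default to the primary rater — a documented source of bias
that the minimum-length setting trades against adjudicator workload. The
adjudicator is an injected callback invoked once per presented clip in
temporal order, returning one state for the whole clip; a human, a scripted
rule, and a simulation ground-truth oracle are interchangeable.

## Agreement statistics

Differences are oriented first-minus-second (rater 1 − rater 2; when
comparing methods, stopwatch − assisted). The Bland–Altman limits use the
sample (n−1) standard deviation of the paired differences and the
conventional 1.96 multiplier; `loa_upper + loa_lower = 2·bias` is an exact
identity of the construction and is asserted as an invariant. Pearson
correlation and its two-sided p value (t distribution, n−2 df) come from
scipy; zero variance in either margin is an error, not a NaN. Medians and
interquartile ranges use linear interpolation between order statistics.
Disagreement statistics are computed on *unfiltered* clips — they describe
rater agreement, not adjudicator workload. The clip-length histogram bins
clips into [0, 5), [5, 10), … seconds, computes per-trial counts per bin,
and reports the across-trial mean and sample sd (defined as 0 for a single
trial, where the n−1 form is undefined). Per-trial coefficient of variation
is the sample sd of the two scores over their mean; trials with mean 0 are
excluded from the CV-vs-mean correlation with a warning.

A structural invariant worth stating: |T₁ − T₂| ≤ total disagreement
duration for every pair, because a totals difference can only accrue on
frames where the raters disagree. The converse fails badly in practice —
total disagreement is typically an order of magnitude larger than the
totals difference — which is the quantitative argument for adjudicating
timelines rather than averaging totals.

## The simulator: what it emulates and what it does not

**Ground truth** is an alternating-renewal process: exponential dwell times
in each state (defaults: mean 10 s mobile, 10 s immobile, initial state
mobile), discretized to whole frames (minimum 1), truncated at the trial
end. Equal 10-s means put the long-run immobile fraction at 0.5 and median
T_f near 180 s, matching typical mid-range immobility on this assay; the
exponential choice gives closed-form occupancy fractions that serve as test
oracles. An optional `immobility_trend` linearly scales the
leave-mobile hazard up (and leave-immobile hazard down) over the trial,
reproducing the qualitative drift from struggling toward immobility;
it defaults to 0 so that occupancy oracles stay exact.

**Rater noise** has four components applied to the truth's toggle stream:
a constant reaction-time lag per rater (defaults 3 and 9 frames = 100 and
300 ms for the two default raters); zero-mean Gaussian jitter per toggle
(default sd 30 frames = 1.0 s, a boundary-perception spread: mobility
onsets and offsets are gradual, and trained raters place them a second or
so apart); missed bouts — a bout shorter than `min_detectable_sec`
(default 1 s) is absorbed into its neighbors with probability `miss_prob`
(default 0.3); and whole-bout state inversions with probability `flip_prob`
(default 0.02). In a strictly alternating table, inverting one bout's state
is identical to deleting its two bounding toggles, and is implemented that
way. Jittered marks that would cross are resolved by dropping the crossing
toggle pair (logged at debug level), preserving a valid table.

These defaults were calibrated, once, against the agreement levels reported
for trained human raters on this assay: they produce a mean total
disagreement of ~43 s per 6-min trial (reported values run from ~20 to
~170 s), disagreement clips mostly under 10 s with occasional
multi-ten-second outliers from inverted bouts, interscorer limits of
agreement near ±35 s, and R² ≈ 0.7 between raters' totals.

What the simulator does **not** emulate: partial-bout misclassification (a
rater wrong about only part of a long bout — real disagreement includes
this; the model only inverts whole bouts), rater drift or fatigue within a
trial, correlated errors between raters watching the same ambiguous
behavior, and any kinematic structure. Passing simulation-based tests
therefore shows the pipeline is correct and beneficial under independent,
parametrically-describable rater noise; it does not certify performance
under correlated or systematic human biases (in particular, errors shared
by both raters are invisible to disagreement-based adjudication by
construction).

## Fidelity of adjudicated scores: what the tests show

With a ground-truth adjudicator, on 200 simulated trials at the default
noise, the merged timeline mismatches truth on fewer *frames* than either
rater's timeline on essentially every trial, and the cohort-mean absolute
T_f error drops by more than half relative to the better rater (≈3.5 s vs
≈8 s; `scripts/acceptance.py` recomputes these). A per-trial comparison of
*totals* errors, however — merged error ≤ min of the two raters' errors —
holds only ~50–70% of the time, and this is structural, not a defect: a
single rater's totals error is a sum of signed bout/edge errors that
frequently lands near zero by cancellation, while the merged score retains
a small irreducible residual (sub-threshold clips defaulting to the
primary rater, and the minority remainder of clips adjudicated to one
state). As rater noise approaches pure zero-mean timing jitter, that
comparison degenerates to a coin flip between the raters. The honest
summary: adjudication uniformly improves the *timeline* and strongly
improves *expected* score accuracy; it cannot beat a rater who got the
right total by luck.

## Problem sizes and determinism

Simulation-backed tests use 6-min, 30-fps trials with cohorts of 20–200
trials; property tests run 50–1000 randomized cases with frame counts from
10 to 10 800. All randomness flows through explicit integer seeds or
spawned `SeedSequence` streams (per-trial substreams keep cohort trials
independent yet reproducible from one master seed); no global random state
is touched. Hypothesis-based tests run derandomized. The full suite runs in
well under a minute on one core; `scripts/acceptance.py` in a few seconds.

## Known limitations

- Two raters only; the adjudicator resolves pairwise disagreement and
  cannot detect errors shared by both raters.
- Integer-frame lags only; sub-frame reaction-time differences alias into
  single-frame disagreements at bout edges.
- The CSV dialect fixes the five status-table column names exactly; the
  summary-file and manifest header spellings are this package's choice.
- fps and frame counts are supplied by the caller — videos are never
  opened, by design.
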