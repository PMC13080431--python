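"""CSV readers and writers for the scoring artifacts.

Four artifact kinds are handled:

* mobility status tables — the five-column run-length record;
* immobility summaries — cumulative immobility times plus trial provenance;
* score manifests — one video path per row;
* rescore manifests — video path plus the two scorers' table paths.

All files are RFC-4180 CSV, UTF-8, comma-delimited, with a header row.
Integers are written without a decimal point; seconds with four decimal
places, recomputed from the frame columns on read so a file that has been
rounded elsewhere never propagates drift. Writing then re-reading any file
produced here reproduces it byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .timeline import (
    ImmobilitySummary,
    MobilityStatusTable,
    StatusSegment,
    TrialClock,
)

__all__ = [
    "STATUS_TABLE_COLUMNS",
    "ScoreManifest",
    "RescoreManifest",
    "write_status_table",
    "read_status_table",
    "write_summary",
    "read_summary",
    "read_manifest",
    "results_dir_for",
]

STATUS_TABLE_COLUMNS = (
    "Mobility_state",
    "Mark_frames",
    "Interval_frames",
    "Mark_sec",
    "Interval_sec",
)

SUMMARY_COLUMNS = (
    "trial_id",
    "video_path",
    "scorer",
    "scored_on_date",
    "results_path",
    "t_full_sec",
    "t_partial_sec",
)


@dataclass(frozen=True)
class ScoreManifest:
    """List of trial videos queued for scoring."""

    video_paths: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.video_paths)


@dataclass(frozen=True)
class RescoreManifest:
    """List of trials queued for rescoring: each row pairs a video with the
    two scorers' status-table paths."""

    rows: tuple[tuple[str, str, str], ...]  # (video_path, score1_path, score2_path)

    def __len__(self) -> int:
        return len(self.rows)


def write_status_table(table: MobilityStatusTable, path: str | os.PathLike) -> None:
    """Write a validated status table as five-column CSV."""
    table.validate()
    lines = [",".join(STATUS_TABLE_COLUMNS)]
    for seg in table.segments:
        lines.append(
            f"{seg.mobility_state},{seg.mark_frame},{seg.interval_frames},"
            f"{seg.mark_sec:.4f},{seg.interval_sec:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_status_table(
    path: str | os.PathLike,
    clock: TrialClock,
    scorer: str = "",
    trial_id: str = "",
) -> MobilityStatusTable:
    """Parse and validate a status-table CSV.

    Column names are checked case-sensitively. The seconds columns are
    cross-checked against the frame columns (half a frame period of slack
    for files rounded by other tools) and then rewritten from frames, so
    the in-memory table is always frame-exact. Any invariant violation —
    typically the fingerprint of a hand-edited file — raises with the
    offending rows listed.
    """
    df = pd.read_csv(path)
    missing = [c for c in STATUS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing or renamed column(s) {missing}; "
            f"expected exactly {list(STATUS_TABLE_COLUMNS)}"
        )
    segments = []
    for _, row in df.iterrows():
        segments.append(StatusSegment(
            mobility_state=int(row["Mobility_state"]),
            mark_frame=int(row["Mark_frames"]),
            interval_frames=int(row["Interval_frames"]),
            mark_sec=float(row["Mark_sec"]),
            interval_sec=float(row["Interval_sec"]),
        ))
    table = MobilityStatusTable(segments, clock, scorer=scorer, trial_id=trial_id)
    table.validate()  # includes the seconds/frames cross-check
    # rewrite seconds from frames: the frame columns are authoritative
    table.segments = [
        StatusSegment.build(s.mobility_state, s.mark_frame, s.interval_frames, clock)
        for s in table.segments
    ]
    return table


def write_summary(summary: ImmobilitySummary, path: str | os.PathLike) -> None:
    """Write an immobility summary as a one-row CSV.

    The T_p <= T_f invariant is enforced by :class:`ImmobilitySummary`
    itself, so an inconsistent summary is refused before anything touches
    the filesystem.
    """
    if summary.t_partial_sec > summary.t_full_sec:  # unreachable via the dataclass
        raise ValidationError("t_partial_sec exceeds t_full_sec")
    values = [
        summary.trial_id, summary.video_path, summary.scorer,
        summary.scored_on_date, summary.results_path,
        f"{summary.t_full_sec:.4f}", f"{summary.t_partial_sec:.4f}",
    ]
    text = ",".join(SUMMARY_COLUMNS) + "\n" + ",".join(values) + "\n"
    Path(path).write_text(text, encoding="utf-8")


def read_summary(path: str | os.PathLike) -> ImmobilitySummary:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing summary column(s) {missing}")
    if len(df) != 1:
        raise FormatError(f"{path}: expected exactly one summary row, got {len(df)}")
    row = df.iloc[0]
    return ImmobilitySummary(
        t_full_sec=float(row["t_full_sec"]),
        t_partial_sec=float(row["t_partial_sec"]),
        trial_id=str(row["trial_id"]),
        scorer=str(row["scorer"]),
        scored_on_date=str(row["scored_on_date"]),
        video_path=str(row["video_path"]),
        results_path=str(row["results_path"]),
    )


def read_manifest(path: str | os.PathLike, mode: str) -> ScoreManifest | RescoreManifest:
    """Read a score- or rescore-mode manifest.

    Score mode expects one path column (``video_path``); rescore mode
    expects three (``video_path, score1_path, score2_path``).
    """
    if mode not in ("score", "rescore"):
        raise ValueError(f"mode must be 'score' or 'rescore', got {mode!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if mode == "score":
        if len(df.columns) != 1:
            raise FormatError(
                f"{path}: score-mode manifest needs exactly 1 column "
                f"(video_path), found {len(df.columns)}"
            )
        paths = [p.strip() for p in df.iloc[:, 0]]
        if not paths or any(not p for p in paths):
            raise FormatError(f"{path}: manifest rows must be non-empty paths")
        return ScoreManifest(tuple(paths))
    if len(df.columns) != 3:
        raise FormatError(
            f"{path}: rescore-mode manifest needs exactly 3 columns "
            f"(video_path, score1_path, score2_path), found {len(df.columns)}"
        )
    rows = []
    for i, row in df.iterrows():
        triple = tuple(str(x).strip() for x in row)
        if any(not p for p in triple):
            raise FormatError(f"{path}: row {i}: all three paths must be non-empty")
        rows.append(triple)
    if not rows:
        raise FormatError(f"{path}: manifest has no rows")
    return RescoreManifest(tuple(rows))


def results_dir_for(video_path: str | os.PathLike) -> Path:
    """Results folder for a video: a directory named after the video,
    beside the video file. Reused if it already exists, never recreated."""
    video = Path(video_path)
    out = video.parent / video.stem
    out.mkdir(parents=True, exist_ok=True)
    return out


def rescore_filename(stem: str, suffix: str = ".csv") -> str:
    """Filename for rescore-mode outputs: marked with a ``_rescore`` token."""
    return f"{stem}_rescore{suffix}"
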