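"""Gaze and trial-metadata file I/O plus recording-quality filtering.

File formats
------------
Gaze CSV: UTF-8, comma separated, header ``trial_id,participant_id,t,x,y,valid``
with ``valid`` in {0, 1}.  Coordinate units (pixels or normalized) are carried
through unchanged; the pipeline is unit-agnostic.

Trial metadata CSV: header ``trial_id,duration_s,drops``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GazeSample",
    "GazeRecording",
    "TrialMeta",
    "GazeFormatError",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_trial_meta",
    "write_trial_meta",
    "detection_rate",
    "filter_by_detection",
]

GAZE_COLUMNS = ["trial_id", "participant_id", "t", "x", "y", "valid"]
META_COLUMNS = ["trial_id", "duration_s", "drops"]


class GazeFormatError(ValueError):
    """Raised when an input file violates the gaze/metadata CSV contract."""


@dataclass(frozen=True)
class GazeSample:
    """One timestamped gaze point.

    ``x``/``y`` are only meaningful when ``valid`` is true; the eye tracker
    emits placeholder coordinates for undetected samples.
    """

    t: float
    x: float
    y: float
    valid: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError(f"sample time must be finite and non-negative, got {self.t}")
        if self.valid and not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("valid sample must have finite coordinates")


@dataclass
class GazeRecording:
    """All gaze samples of one trial, ordered by time."""

    trial_id: str
    participant_id: str
    samples: list[GazeSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError(f"trial {self.trial_id!r}: a recording needs at least 2 samples")
        ts = [s.t for s in self.samples]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"trial {self.trial_id!r}: samples not ordered by t")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def t(self) -> np.ndarray:
        return np.array([s.t for s in self.samples], dtype=float)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array, invalid samples included as stored."""
        return np.array([[s.x, s.y] for s in self.samples], dtype=float)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.array([s.valid for s in self.samples], dtype=bool)


@dataclass(frozen=True)
class TrialMeta:
    """Objective outcome of one peg-transfer trial."""

    trial_id: str
    duration_s: float
    drops: int

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError(f"duration_s must be non-negative, got {self.duration_s}")
        if self.drops < 0:
            raise ValueError(f"drops must be non-negative, got {self.drops}")


def read_gaze_csv(path) -> list[GazeRecording]:
    """Read a gaze CSV into one :class:`GazeRecording` per distinct trial.

    Rows may be interleaved across trials; within each trial they are sorted
    by ``t``.  Missing header columns or duplicate timestamps within a trial
    raise :class:`GazeFormatError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"gaze CSV {path} missing column(s): {', '.join(missing)}")

    recordings: list[GazeRecording] = []
    for trial_id, group in df.groupby("trial_id", sort=True):
        pids = group["participant_id"].unique()
        if len(pids) != 1:
            raise GazeFormatError(
                f"trial {trial_id!r} is attributed to multiple participants: {sorted(map(str, pids))}"
            )
        group = group.sort_values("t", kind="stable")
        t = group["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise GazeFormatError(f"trial {trial_id!r} has duplicate timestamps")
        samples = [
            GazeSample(t=float(r.t), x=float(r.x), y=float(r.y), valid=bool(int(r.valid)))
            for r in group.itertuples(index=False)
        ]
        recordings.append(GazeRecording(str(trial_id), str(pids[0]), samples))
    return recordings


def write_gaze_csv(path, recordings: list[GazeRecording]) -> None:
    rows = [
        (rec.trial_id, rec.participant_id, s.t, s.x, s.y, int(s.valid))
        for rec in recordings
        for s in rec.samples
    ]
    pd.DataFrame(rows, columns=GAZE_COLUMNS).to_csv(path, index=False)


def read_trial_meta(path) -> list[TrialMeta]:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"metadata CSV {path} missing column(s): {', '.join(missing)}")
    return [
        TrialMeta(str(r.trial_id), float(r.duration_s), int(r.drops))
        for r in df.itertuples(index=False)
    ]


def write_trial_meta(path, metas: list[TrialMeta]) -> None:
    pd.DataFrame(
        [(m.trial_id, m.duration_s, m.drops) for m in metas], columns=META_COLUMNS
    ).to_csv(path, index=False)


def detection_rate(rec: GazeRecording) -> float:
    """Fraction of samples in which the eyes were detected (``valid`` true)."""
    n = len(rec.samples)
    if n == 0:
        raise ValueError("cannot compute detection rate of an empty recording")
    return sum(s.valid for s in rec.samples) / n


def filter_by_detection(
    recordings: list[GazeRecording], threshold: float = 0.8
) -> tuple[list[GazeRecording], list[GazeRecording]]:
    """Split recordings into (kept, removed) by per-participant detection rate.

    The rate is pooled over all of a participant's trials; participants whose
    pooled rate is strictly below ``threshold`` have *all* their trials
    removed.  A rate exactly equal to the threshold is kept.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    valid_count: dict[str, int] = {}
    total_count: dict[str, int] = {}
    for rec in recordings:
        pid = rec.participant_id
        valid_count[pid] = valid_count.get(pid, 0) + int(sum(s.valid for s in rec.samples))
        total_count[pid] = total_count.get(pid, 0) + len(rec.samples)
    keep_pid = {pid for pid in total_count if valid_count[pid] / total_count[pid] >= threshold}
    kept = [r for r in recordings if r.participant_id in keep_pid]
    removed = [r for r in recordings if r.participant_id not in keep_pid]
    return kept, removed
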