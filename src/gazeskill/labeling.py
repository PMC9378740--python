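"""Objective peg-transfer scoring and k-means skill-level labeling.

The trial score is ``cutoff - duration - penalty_per_drop * drops`` (floored
at zero), and the three skill levels are obtained by 1-D k-means over the
scores of all trials, with clusters mapped to levels in ascending order of
their mean score.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .gaze_io import TrialMeta

__all__ = [
    "SkillLabel",
    "ScoreConfig",
    "peg_score",
    "cluster_skill_levels",
    "class_summary",
    "write_labels_csv",
    "read_labels_csv",
]


class SkillLabel(IntEnum):
    """Three ordered skill levels; higher value = higher skill."""

    NOVICE = 0
    INTERMEDIATE = 1
    EXPERT = 2

    def __str__(self) -> str:  # CSV serialization uses lowercase names
        return self.name.lower()

    @classmethod
    def from_string(cls, s: str) -> "SkillLabel":
        return cls[s.strip().upper()]


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring parameters: 300 s cutoff, 17 s penalty per dropped peg."""

    cutoff_s: float = 300.0
    penalty_per_drop_s: float = 17.0

    def __post_init__(self) -> None:
        if self.cutoff_s <= 0 or self.penalty_per_drop_s <= 0:
            raise ValueError("cutoff_s and penalty_per_drop_s must be strictly positive")


def peg_score(meta: TrialMeta, cfg: ScoreConfig = ScoreConfig()) -> float:
    """Score = cutoff − duration − penalty × drops, floored at 0."""
    if meta.duration_s > cfg.cutoff_s:
        raise ValueError(
            f"trial {meta.trial_id!r}: duration {meta.duration_s} exceeds cutoff {cfg.cutoff_s}"
        )
    raw = cfg.cutoff_s - meta.duration_s - cfg.penalty_per_drop_s * meta.drops
    return max(raw, 0.0)


def cluster_skill_levels(
    scores, k: int = 3, seed: int | None = 0, n_init: int = 10
) -> list[SkillLabel]:
    """Assign each score a skill level via 1-D k-means with ``k`` clusters.

    Clusters are relabeled so that the one with the lowest mean score becomes
    NOVICE and the highest EXPERT; the result is therefore invariant to the
    arbitrary cluster numbering of the underlying k-means run.  Deterministic
    given ``seed`` (``n_init`` seeded restarts).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if len(np.unique(scores)) < k:
        raise ValueError(f"need at least {k} distinct scores, got {len(np.unique(scores))}")
    if k != len(SkillLabel):
        raise ValueError(f"k must be {len(SkillLabel)} to map onto skill levels")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignment = km.fit_predict(scores.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())  # ascending mean score
    cluster_to_level = {int(c): SkillLabel(rank) for rank, c in enumerate(order)}
    return [cluster_to_level[int(a)] for a in assignment]


def class_summary(scores, labels) -> pd.DataFrame:
    """Per-class count, mean and sample standard deviation of the scores.

    Classes with no members get ``n=0`` and NaN moments; singleton classes
    get a NaN sd.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must be aligned")
    rows = []
    for level in SkillLabel:
        vals = scores[[lab == level for lab in labels]]
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        sd = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
        rows.append({"skill": str(level), "n": n, "mean": mean, "sd": sd})
    return pd.DataFrame(rows).set_index("skill")


def write_labels_csv(path, trial_ids, scores, labels) -> None:
    pd.DataFrame(
        {"trial_id": list(trial_ids), "score": list(scores), "skill": [str(l) for l in labels]}
    ).to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["skill"] = df["skill"].map(SkillLabel.from_string)
    return df
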