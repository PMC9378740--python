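"""Seeded synthetic peg-transfer datasets with planted class structure.

Every stage of the pipeline is testable without real data: trial durations
and drop counts cluster by skill level (so score clustering is recoverable),
gaze traces carry class-specific subsequence motifs (so shapelet discovery
has a known answer), and task frames render pegs whose positional jitter
shrinks with skill (so the image branch has a learnable signal).

All randomness flows from one master seed through named sub-streams;
regeneration is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .gaze_io import (
    GazeRecording,
    GazeSample,
    TrialMeta,
    write_gaze_csv,
    write_trial_meta,
)
from .labeling import SkillLabel

__all__ = [
    "SynthConfig",
    "motif_template",
    "generate_trial",
    "generate_frames",
    "generate_trials",
    "generate_dataset",
    "planted_motif_set",
]

# sub-stream tags so each purpose draws from an independent generator
_STREAM_GAZE, _STREAM_META, _STREAM_FRAMES = 1, 2, 3


@dataclass(frozen=True)
class SynthConfig:
    """Generator defaults; class-indexed tuples are (novice, intermediate, expert)."""

    n_per_class: int = 10
    series_len: int = 600
    class_duration_means: tuple[float, float, float] = (205.0, 139.0, 90.0)
    class_duration_sds: tuple[float, float, float] = (18.0, 9.0, 8.0)
    class_drop_rates: tuple[float, float, float] = (0.25, 0.1, 0.03)
    motif_len: int = 40
    n_motifs: int = 3
    motif_amplitude: float = 25.0
    noise_sd: float = 2.0
    frame_size: int = 64
    frames_per_trial: int = 12
    class_jitter_sds: tuple[float, float, float] = (12.0, 4.0, 0.8)
    n_participants: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.series_len <= self.motif_len:
            raise ValueError("series_len must exceed motif_len")
        positives = (
            self.n_per_class,
            self.series_len,
            self.motif_len,
            self.n_motifs,
            self.motif_amplitude,
            self.noise_sd,
            self.frame_size,
            self.frames_per_trial,
            *self.class_duration_means,
            *self.class_duration_sds,
            *self.class_jitter_sds,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("all generator parameters must be positive")


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def motif_template(skill: SkillLabel, motif_len: int, amplitude: float = 1.0) -> np.ndarray:
    """Fixed deterministic per-class motif shape of the given length.

    Novice: trapezoidal dwell plateau; intermediate: single smooth bump;
    expert: high-frequency zigzag.  Distinct shapes make extracted shapelets
    attributable to a class.
    """
    u = np.linspace(0.0, 1.0, motif_len)
    if skill == SkillLabel.NOVICE:
        shape = np.clip(3.0 * np.minimum(u, 1.0 - u), 0.0, 1.0)
    elif skill == SkillLabel.INTERMEDIATE:
        shape = np.sin(2.0 * np.pi * u) * np.sin(np.pi * u)
    else:
        shape = np.sin(6.0 * np.pi * u) * np.sin(np.pi * u)
    return amplitude * shape


def _smooth_walk(rng: np.random.Generator, n: int, noise_sd: float, rho: float = 0.95) -> np.ndarray:
    """Mean-reverting Gaussian-increment walk (stays bounded around 0)."""
    steps = rng.normal(0.0, noise_sd, size=n)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = rho * acc + steps[i]
        out[i] = acc
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v <= hi:
            return float(v)
    raise RuntimeError("truncated normal rejection failed; check parameters")


def _motif_offsets(rng: np.random.Generator, n: int, motif_len: int, k: int) -> list[int]:
    # one motif per equal segment => planted windows never overlap
    seg = n // k
    if seg <= motif_len:
        raise ValueError("series too short for the requested number of motifs")
    return [int(i * seg + rng.integers(0, seg - motif_len)) for i in range(k)]


def _generate_meta(skill: SkillLabel, cfg: SynthConfig, trial_index: int) -> TrialMeta:
    c = int(skill)
    rng = _stream(cfg.seed, _STREAM_META, trial_index)
    duration = _truncated_normal(
        rng, cfg.class_duration_means[c], cfg.class_duration_sds[c], 0.0, 300.0
    )
    drops = int(rng.poisson(cfg.class_drop_rates[c]))
    return TrialMeta(f"t{trial_index:04d}", duration, drops)


def _generate_gaze(
    skill: SkillLabel, cfg: SynthConfig, trial_index: int, duration: float,
    participant_id: str | None = None,
) -> GazeRecording:
    rng = _stream(cfg.seed, _STREAM_GAZE, trial_index)
    n = cfg.series_len
    x = _smooth_walk(rng, n, cfg.noise_sd)
    y = _smooth_walk(rng, n, cfg.noise_sd)
    template = motif_template(skill, cfg.motif_len, cfg.motif_amplitude)
    for off in _motif_offsets(rng, n, cfg.motif_len, cfg.n_motifs):
        x[off : off + cfg.motif_len] += template
    t = np.linspace(0.0, duration, n)
    if participant_id is None:
        participant_id = f"p{trial_index % cfg.n_participants}"
    samples = [GazeSample(float(ti), float(xi), float(yi), True) for ti, xi, yi in zip(t, x, y)]
    return GazeRecording(f"t{trial_index:04d}", participant_id, samples)


def generate_trial(
    skill: SkillLabel, cfg: SynthConfig, trial_index: int, participant_id: str | None = None
) -> tuple[GazeRecording, TrialMeta]:
    """One seeded trial: gaze recording with planted motifs + its metadata."""
    meta = _generate_meta(skill, cfg, trial_index)
    rec = _generate_gaze(skill, cfg, trial_index, meta.duration_s, participant_id)
    return rec, meta


def _peg_centers(frame_size: int) -> np.ndarray:
    """Canonical centers of the 6 pegs: two columns of three."""
    xs = np.array([0.3, 0.7]) * frame_size
    ys = np.array([0.25, 0.5, 0.75]) * frame_size
    return np.array([(x, y) for x in xs for y in ys])


def generate_frames(
    skill: SkillLabel, n_frames: int, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n_frames, frame_size, frame_size, 3) uint8 frames of jittered pegs."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    size = cfg.frame_size
    radius = max(2, size // 16)
    centers = _peg_centers(size)
    jitter_sd = cfg.class_jitter_sds[int(skill)]
    yy, xx = np.mgrid[0:size, 0:size]
    frames = np.zeros((n_frames, size, size), dtype=float)
    for f in range(n_frames):
        canvas = np.zeros((size, size))
        jitter = rng.normal(0.0, jitter_sd, size=centers.shape)
        for (cx, cy), (jx, jy) in zip(centers, jitter):
            mask = (xx - (cx + jx)) ** 2 + (yy - (cy + jy)) ** 2 <= radius**2
            canvas[mask] = 200.0
        canvas += rng.normal(0.0, 8.0, size=canvas.shape)
        frames[f] = canvas
    frames = np.clip(frames, 0.0, 255.0).astype(np.uint8)
    return np.repeat(frames[..., None], 3, axis=3)


@dataclass
class SynthDataset:
    """In-memory dataset plus its ground-truth manifest.

    ``true_labels`` are the score-derived k-means labels that condition the
    gaze motifs and frame jitter; ``planted_labels`` are the classes whose
    duration/drop distributions each trial was drawn from.  The two agree for
    all but the occasional score-boundary trial.
    """

    recordings: list[GazeRecording]
    metas: list[TrialMeta]
    frames: dict[str, np.ndarray]
    true_labels: dict[str, SkillLabel]
    planted_labels: dict[str, SkillLabel]
    config: SynthConfig = field(repr=False, default=SynthConfig())


def generate_trials(cfg: SynthConfig) -> SynthDataset:
    """All trials (3 * n_per_class) with frames, entirely in memory.

    Two-phase: durations/drops are drawn from the planted class first, then
    trials are relabeled by 1-D k-means over their scores (mirroring how the
    pipeline labels real data), and gaze motifs and frame jitter are
    generated from that relabeled class.  This keeps the class-conditional
    signals consistent with the labels every downstream stage trains on.
    """
    from .labeling import cluster_skill_levels, peg_score

    planted, metas = [], []
    idx = 0
    for skill in SkillLabel:
        for _ in range(cfg.n_per_class):
            metas.append(_generate_meta(skill, cfg, idx))
            planted.append(skill)
            idx += 1
    scores = [peg_score(m) for m in metas]
    effective = cluster_skill_levels(scores, seed=cfg.seed)

    recordings, frames, truth, planted_by_id = [], {}, {}, {}
    for i, (meta, skill) in enumerate(zip(metas, effective)):
        rec = _generate_gaze(skill, cfg, i, meta.duration_s)
        frame_rng = _stream(cfg.seed, _STREAM_FRAMES, i)
        frames[rec.trial_id] = generate_frames(skill, cfg.frames_per_trial, cfg, frame_rng)
        recordings.append(rec)
        truth[rec.trial_id] = skill
        planted_by_id[rec.trial_id] = planted[i]
    return SynthDataset(recordings, metas, frames, truth, planted_by_id, cfg)


def generate_dataset(cfg: SynthConfig, outdir) -> dict:
    """Write gaze CSV, metadata CSV, frame tree and manifest; return manifest."""
    if cfg.n_per_class < 3:
        raise ValueError("n_per_class must be >= 3")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_trials(cfg)
    write_gaze_csv(outdir / "gaze.csv", ds.recordings)
    write_trial_meta(outdir / "meta.csv", ds.metas)
    frames_dir = outdir / "frames"
    for trial_id, stack in ds.frames.items():
        d = frames_dir / trial_id
        d.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack):
            Image.fromarray(frame).save(d / f"{i:05d}.png")
    manifest = {
        "seed": cfg.seed,
        "n_per_class": cfg.n_per_class,
        "trials": {tid: str(lab) for tid, lab in ds.true_labels.items()},
        "planted": {tid: str(lab) for tid, lab in ds.planted_labels.items()},
        "paths": {"gaze": "gaze.csv", "meta": "meta.csv", "frames": "frames"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def planted_motif_set(
    n_per_class: int = 6,
    length: int = 120,
    motif_len: int = 20,
    amplitude: float = 14.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Two-class series set where class 1 carries one exactly-planted motif.

    Returns ``(values, labels, windows)`` where ``values`` is
    (2*n_per_class, length), ``labels`` is 0/1 and ``windows`` maps each
    class-1 row index to its (start, end) planted window.
    """
    rng = _stream(seed, 0xB10B)
    values = np.empty((2 * n_per_class, length))
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    template = motif_template(SkillLabel.INTERMEDIATE, motif_len, amplitude)
    windows: dict[int, tuple[int, int]] = {}
    for i in range(2 * n_per_class):
        values[i] = _smooth_walk(rng, length, noise_sd)
        if labels[i] == 1:
            off = int(rng.integers(0, length - motif_len))
            values[i, off : off + motif_len] += template
            windows[i] = (off, off + motif_len)
    return values, labels, windows
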