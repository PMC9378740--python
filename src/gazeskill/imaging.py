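"""Class-balanced frame extraction and the image-branch classifier.

The default ``small_cnn`` backbone is a fixed, seed-drawn 3-block
convolutional feature extractor (random filters, ReLU, 2x2 mean pooling)
followed by a trainable 3-layer fully-connected head (two hidden layers plus
the 3-node output).  It runs on CPU at desk scale; an Inception-ResNet-v2
backbone is selectable only when a deep-learning runtime is installed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .ensemble import ClassifierOutcome
from .labeling import SkillLabel

__all__ = [
    "FrameSet",
    "ImageModelConfig",
    "ImageFeatureExtractor",
    "ImageModel",
    "balance_capture_rates",
    "extract_frames",
    "split_trials",
    "train_image_classifier",
    "predict_frame_probs",
    "aggregate_trial_prediction",
    "predict_trials",
]

logger = logging.getLogger(__name__)


@dataclass
class FrameSet:
    """Extracted frames with per-frame trial ids and skill labels."""

    images: np.ndarray  # (n, res, res, 3) uint8
    trial_ids: list[str]
    labels: list[SkillLabel]
    resolution: int = 299

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        n, h, w, c = self.images.shape
        if (h, w, c) != (self.resolution, self.resolution, 3):
            raise ValueError(f"frames must be {self.resolution}x{self.resolution}x3")
        if n != len(self.trial_ids) or n != len(self.labels):
            raise ValueError("trial_ids and labels must align with images")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "FrameSet":
        idx = np.asarray(idx)
        return FrameSet(
            self.images[idx],
            [self.trial_ids[i] for i in idx],
            [self.labels[i] for i in idx],
            self.resolution,
        )


@dataclass(frozen=True)
class ImageModelConfig:
    backbone: str = "small_cnn"
    fc_layers: int = 3
    out_nodes: int = 3
    train_fraction: float = 2 / 3
    epochs: int = 200
    hidden_sizes: tuple[int, int] = (64, 32)
    n_filters: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in ("small_cnn", "inception_resnet_v2"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.fc_layers != len(self.hidden_sizes) + 1:
            raise ValueError("fc_layers must equal number of hidden layers + output layer")
        if self.out_nodes != len(SkillLabel):
            raise ValueError("out_nodes must equal the number of classes")


def balance_capture_rates(class_video_counts) -> np.ndarray:
    """Per-class frame sampling rates proportional to 1/count, max rate 1.

    Equal-duration videos sampled at these rates yield equal expected frame
    counts per class, e.g. trial counts (1, 3, 8) give rates (1, 1/3, 1/8).
    """
    counts = np.asarray(class_video_counts, dtype=float)
    if counts.shape != (len(SkillLabel),):
        raise ValueError(f"expected {len(SkillLabel)} class counts")
    if np.any(counts < 1):
        raise ValueError("every class needs at least one video")
    rates = (1.0 / counts) / np.max(1.0 / counts)
    return rates


def _load_resized(path: Path, resolution: int) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    img = Image.fromarray(arr[:, :, :3]).resize((resolution, resolution), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def extract_frames(
    trial_dirs: dict[str, Path],
    labels: dict[str, SkillLabel],
    rates=None,
    resolution: int = 299,
) -> FrameSet:
    """Read frames from per-trial directories, subsampled at the class rate.

    Subsampling is deterministic: every ``round(1/rate)``-th frame in
    filename order.  Unreadable images are skipped with a warning; a trial
    with no frame files is an error.
    """
    if rates is None:
        rates = np.ones(len(SkillLabel))
    rates = np.asarray(rates, dtype=float)
    images, frame_trials, frame_labels = [], [], []
    for trial_id in sorted(trial_dirs):
        d = Path(trial_dirs[trial_id])
        files = sorted(p for p in d.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not files:
            raise ValueError(f"trial {trial_id!r}: no frame files in {d}")
        label = labels[trial_id]
        stride = max(1, int(round(1.0 / rates[int(label)])))
        for p in files[::stride]:
            try:
                images.append(_load_resized(p, resolution))
            except (OSError, ValueError) as e:
                warnings.warn(f"skipping unreadable frame {p}: {e}", stacklevel=2)
                logger.warning("skipping unreadable frame %s: %s", p, e)
                continue
            frame_trials.append(trial_id)
            frame_labels.append(label)
    return FrameSet(np.stack(images), frame_trials, frame_labels, resolution)


def split_trials(
    frameset: FrameSet, train_fraction: float = 2 / 3, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified trial-level split: all frames of a trial land on one side."""
    trial_ids = sorted(set(frameset.trial_ids))
    trial_label = {t: l for t, l in zip(frameset.trial_ids, frameset.labels)}
    y = [int(trial_label[t]) for t in trial_ids]
    tr, te = train_test_split(trial_ids, train_size=train_fraction, stratify=y, random_state=seed)
    return sorted(tr), sorted(te)


def _to_gray(images: np.ndarray) -> np.ndarray:
    return images.astype(np.float64).mean(axis=3) / 255.0


def _conv_block(x: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Valid conv + ReLU + 2x2 mean pool.  x: (n,H,W,Cin), filters: (Cout,Cin,3,3)."""
    windows = sliding_window_view(x, (3, 3), axis=(1, 2))  # (n,H-2,W-2,Cin,3,3)
    out = np.einsum("nhwcij,ocij->nhwo", windows, filters)
    np.maximum(out, 0.0, out=out)
    n, h, w, c = out.shape
    out = out[:, : h - h % 2, : w - w % 2]
    return out.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


class ImageFeatureExtractor:
    """Fixed seed-drawn 3-block conv backbone (filters are never trained).

    Because the filters stay frozen, features for a frame set can be computed
    once and reused across repeated train/test splits.
    """

    def __init__(self, n_filters: int = 16, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF117E55]))
        shapes = [(n_filters, 1, 3, 3)] + [(n_filters, n_filters, 3, 3)] * 2
        self.filters = [rng.standard_normal(s) / np.sqrt(s[1] * 9) for s in shapes]
        self.seed = seed

    def transform(self, images: np.ndarray, batch: int = 32) -> np.ndarray:
        feats = []
        for lo in range(0, len(images), batch):
            x = _to_gray(images[lo : lo + batch])[..., None]
            # multi-scale summary: per-block global mean/std per filter map,
            # plus the flattened final map
            pooled = []
            for f in self.filters:
                x = _conv_block(x, f)
                pooled.append(x.mean(axis=(1, 2)))
                pooled.append(x.std(axis=(1, 2)))
            pooled.append(x.reshape(x.shape[0], -1))
            feats.append(np.hstack(pooled))
        return np.vstack(feats)


@dataclass
class ImageModel:
    """Fixed conv backbone + fitted FC head; records per-epoch training loss."""

    config: ImageModelConfig
    extractor: ImageFeatureExtractor
    scaler: StandardScaler
    head: MLPClassifier
    loss_curve: list[float] = field(default_factory=list)


def train_image_classifier(
    frameset: FrameSet,
    config: ImageModelConfig = ImageModelConfig(),
    extractor: ImageFeatureExtractor | None = None,
    features: np.ndarray | None = None,
) -> ImageModel:
    """Fit the image branch on the given (training) frames.

    Splitting into train/test at the trial level is the caller's job (see
    :func:`split_trials`); this function refuses degenerate inputs: fewer
    than 2 classes, or any present class with fewer than 2 trials.
    ``features`` may carry precomputed extractor output for these frames.
    """
    if config.backbone == "inception_resnet_v2":
        raise NotImplementedError(
            "inception_resnet_v2 requires a deep-learning runtime; use backbone='small_cnn'"
        )
    y = np.array([int(l) for l in frameset.labels])
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes of frames to train")
    for level in np.unique(y):
        n_trials = len({t for t, l in zip(frameset.trial_ids, frameset.labels) if int(l) == level})
        if n_trials < 2:
            raise ValueError(f"class {SkillLabel(level)} has fewer than 2 trials")
    if extractor is None:
        extractor = ImageFeatureExtractor(config.n_filters, config.seed)
    X = extractor.transform(frameset.images) if features is None else np.asarray(features)
    scaler = StandardScaler().fit(X)
    head = MLPClassifier(
        hidden_layer_sizes=config.hidden_sizes,
        max_iter=config.epochs,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        head.fit(scaler.transform(X), y)
    return ImageModel(config, extractor, scaler, head, list(head.loss_curve_))


def predict_frame_probs(
    model: ImageModel, images: np.ndarray, features: np.ndarray | None = None
) -> np.ndarray:
    """(n_frames, 3) class probabilities, aligned to SkillLabel order."""
    X = model.extractor.transform(images) if features is None else np.asarray(features)
    raw = model.head.predict_proba(model.scaler.transform(X))
    out = np.zeros((len(images), len(SkillLabel)))
    for j, c in enumerate(model.head.classes_):
        out[:, int(c)] = raw[:, j]
    return out


def aggregate_trial_prediction(frame_probs, trial_id: str = "") -> ClassifierOutcome:
    """Trial probability = arithmetic mean of its frame probabilities."""
    frame_probs = np.atleast_2d(np.asarray(frame_probs, dtype=float))
    if frame_probs.size == 0:
        raise ValueError("cannot aggregate an empty set of frame probabilities")
    mean = frame_probs.mean(axis=0)
    return ClassifierOutcome(trial_id, mean / mean.sum())


def predict_trials(
    model: ImageModel, frameset: FrameSet, features: np.ndarray | None = None
) -> list[ClassifierOutcome]:
    """Per-trial outcomes: frame probabilities averaged within each trial."""
    probs = predict_frame_probs(model, frameset.images, features)
    outcomes = []
    for trial_id in sorted(set(frameset.trial_ids)):
        mask = [t == trial_id for t in frameset.trial_ids]
        outcomes.append(aggregate_trial_prediction(probs[mask], trial_id))
    return outcomes
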