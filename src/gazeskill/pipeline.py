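"""End-to-end orchestration: label -> resample -> shapelets -> ensemble,
frames -> image classifier, then ELM fusion, repeated over seeded runs.

All stages of one run share a single trial-level stratified split, so the
fused evaluation never mixes a trial's data across train and test.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import ensemble, fusion, imaging, labeling, timeseries
from .gaze_io import read_gaze_csv, read_trial_meta
from .labeling import ScoreConfig, SkillLabel

__all__ = ["PipelineConfig", "LoadedDataset", "load_dataset", "run_once", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    resample_len: int = 300
    shapelet_k: int = 8
    shapelet_lmin: int | None = None
    shapelet_lmax: int | None = None
    shapelet_measure: str = "info_gain"
    max_candidates: int | None = 150
    k_folds: int = 3
    ensemble_mode: str = "stacking"
    image_epochs: int = 150
    elm_hidden: int = 20
    train_fraction: float = 2 / 3
    n_runs: int = 1
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LoadedDataset:
    trial_ids: list[str]
    scores: np.ndarray
    labels: list[SkillLabel]
    seriesset: timeseries.SeriesSet
    frameset: imaging.FrameSet
    extractor: imaging.ImageFeatureExtractor
    frame_features: np.ndarray  # backbone output, cached across runs


def load_dataset(
    dataset_dir, cfg: PipelineConfig, score_cfg: ScoreConfig = ScoreConfig()
) -> LoadedDataset:
    """Read a dataset directory and derive scores, k-means labels and series."""
    dataset_dir = Path(dataset_dir)
    recordings = read_gaze_csv(dataset_dir / "gaze.csv")
    metas = read_trial_meta(dataset_dir / "meta.csv")
    meta_by_id = {m.trial_id: m for m in metas}
    recordings = [r for r in recordings if r.trial_id in meta_by_id]
    trial_ids = [r.trial_id for r in recordings]

    scores = np.array([labeling.peg_score(meta_by_id[t], score_cfg) for t in trial_ids])
    labels = labeling.cluster_skill_levels(scores, seed=cfg.seed)
    seriesset = timeseries.build_series_set(recordings, cfg.resample_len)

    frames_dir = dataset_dir / "frames"
    trial_dirs = {t: frames_dir / t for t in trial_ids if (frames_dir / t).is_dir()}
    label_by_id = dict(zip(trial_ids, labels))
    class_counts = np.bincount([int(label_by_id[t]) for t in trial_dirs], minlength=3)
    rates = imaging.balance_capture_rates(np.maximum(class_counts, 1))
    frameset = imaging.extract_frames(
        trial_dirs, label_by_id, rates, resolution=_probe_resolution(trial_dirs)
    )
    # the conv backbone is untrained; fix it at the master seed and cache its
    # features so repeated splits only refit the FC head
    extractor = imaging.ImageFeatureExtractor(seed=cfg.seed)
    frame_features = extractor.transform(frameset.images)
    return LoadedDataset(
        trial_ids, scores, labels, seriesset, frameset, extractor, frame_features
    )


def _probe_resolution(trial_dirs: dict[str, Path]) -> int:
    """Native square size of the stored frames (avoids pointless upscaling)."""
    from PIL import Image

    first_dir = trial_dirs[sorted(trial_dirs)[0]]
    first = sorted(first_dir.iterdir())[0]
    with Image.open(first) as im:
        return min(im.size)


def _subset_series(ss: timeseries.SeriesSet, keep: list[str]) -> timeseries.SeriesSet:
    idx = [ss.trial_ids.index(t) for t in keep]
    return timeseries.SeriesSet(ss.values[idx], [ss.trial_ids[i] for i in idx], ss.channels)


def run_once(data: LoadedDataset, cfg: PipelineConfig, run_seed: int) -> dict:
    """One seeded trial-level split, both branches, ELM fusion; returns metrics."""
    y = np.array([int(l) for l in data.labels])
    ids = np.array(data.trial_ids)
    tr_ids, te_ids = train_test_split(
        ids, train_size=cfg.train_fraction, stratify=y, random_state=run_seed % (2**31 - 1)
    )
    tr_ids, te_ids = sorted(tr_ids), sorted(te_ids)
    label_by_id = dict(zip(data.trial_ids, data.labels))
    y_tr = [int(label_by_id[t]) for t in tr_ids]
    y_te = [int(label_by_id[t]) for t in te_ids]

    # --- time-series branch: shapelets discovered on training trials only
    train_ss = _subset_series(data.seriesset, tr_ids)
    shapelets = timeseries.extract_shapelets(
        train_ss,
        y_tr,
        k=cfg.shapelet_k,
        lmin=cfg.shapelet_lmin,
        lmax=cfg.shapelet_lmax,
        measure=cfg.shapelet_measure,
        max_candidates=cfg.max_candidates,
        seed=run_seed,
    )
    features = timeseries.shapelet_transform(data.seriesset, shapelets)
    feat_by_id = dict(zip(features.trial_ids, features.values))
    X_tr = np.array([feat_by_id[t] for t in tr_ids])
    X_te = np.array([feat_by_id[t] for t in te_ids])

    base_cfg = ensemble.BaseModelConfig(seed=run_seed % (2**31 - 1))
    stacked = ensemble.train_stacked(X_tr, y_tr, base_cfg, cfg.k_folds, cfg.ensemble_mode)
    ts_train_out = ensemble.predict_stacked(stacked, X_tr, tr_ids)
    ts_test_out = ensemble.predict_stacked(stacked, X_te, te_ids)

    # --- image branch, same split (cached backbone features, per-run head)
    fs = data.frameset
    tr_idx = np.flatnonzero([t in set(tr_ids) for t in fs.trial_ids])
    te_idx = np.flatnonzero([t in set(te_ids) for t in fs.trial_ids])
    img_cfg = imaging.ImageModelConfig(epochs=cfg.image_epochs, seed=run_seed % (2**31 - 1))
    img_model = imaging.train_image_classifier(
        fs.subset(tr_idx), img_cfg, data.extractor, data.frame_features[tr_idx]
    )
    img_train_out = imaging.predict_trials(
        img_model, fs.subset(tr_idx), data.frame_features[tr_idx]
    )
    img_test_out = imaging.predict_trials(
        img_model, fs.subset(te_idx), data.frame_features[te_idx]
    )

    # --- ELM fusion of branch probabilities
    def fused_matrix(ts_outs, img_outs, order):
        ts_by_id = {o.trial_id: o for o in ts_outs}
        img_by_id = {o.trial_id: o for o in img_outs}
        return np.array(
            [fusion.build_fusion_features(ts_by_id[t], img_by_id[t]) for t in order]
        )

    elm = fusion.elm_train(
        fused_matrix(ts_train_out, img_train_out, tr_ids),
        y_tr,
        n_hidden=cfg.elm_hidden,
        seed=run_seed,
    )
    fused_out = fusion.elm_predict(elm, fused_matrix(ts_test_out, img_test_out, te_ids), te_ids)

    ts_pred = [int(o.label) for o in ts_test_out]
    img_pred = [int(o.label) for o in img_test_out]
    fused_pred = [int(o.label) for o in fused_out]
    confusion = np.zeros((3, 3), dtype=int)
    for actual, pred in zip(y_te, fused_pred):
        confusion[actual, pred] += 1
    return {
        "run_seed": int(run_seed),
        "ts_accuracy": float(np.mean(np.array(ts_pred) == y_te)),
        "img_accuracy": float(np.mean(np.array(img_pred) == y_te)),
        "fused_accuracy": float(np.mean(np.array(fused_pred) == y_te)),
        "confusion": confusion,
        "test_trials": list(te_ids),
        "fused_outcomes": fused_out,
    }


def run_pipeline(dataset_dir, cfg: PipelineConfig) -> dict:
    """Repeated seeded runs; returns the JSON-serializable report."""
    data = load_dataset(dataset_dir, cfg)
    run_seeds = [int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(cfg.n_runs)]
    runs = []
    pooled = np.zeros((3, 3), dtype=int)
    for r, rs in enumerate(run_seeds):
        logger.info("run %d/%d (seed %d)", r + 1, cfg.n_runs, rs)
        res = run_once(data, cfg, rs)
        pooled += res["confusion"]
        runs.append(res)

    def stats(key):
        vals = [r[key] for r in runs]
        return {
            "per_run": vals,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
        }

    report = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "n_trials": len(data.trial_ids),
        "class_sizes": np.bincount([int(l) for l in data.labels], minlength=3).tolist(),
        "ts_accuracy": stats("ts_accuracy"),
        "img_accuracy": stats("img_accuracy"),
        "fused_accuracy": stats("fused_accuracy"),
        "confusion_matrix": pooled.tolist(),
        "fused_accuracy_pct": fusion.accuracy_from_confusion(pooled),
    }
    return report
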