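"""Seven-learner heterogeneous ensemble over shapelet features.

Base learners: RBF-SVM, random forest, extremely randomized trees, MLP,
AdaBoost, gradient-boosted trees, and a histogram gradient-boosted variant
standing in for XGBoost (trees=100, max depth 3).  Fusion of the base
outputs is either stacked generalization (logistic regression trained on
out-of-fold class probabilities) or majority voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .labeling import SkillLabel

__all__ = [
    "BASE_MODEL_KINDS",
    "BaseModelConfig",
    "StackedModel",
    "ClassifierOutcome",
    "make_base_model",
    "train_stacked",
    "predict_stacked",
    "evaluate_repeated",
]

BASE_MODEL_KINDS = (
    "svm_rbf",
    "random_forest",
    "extra_trees",
    "mlp",
    "adaboost",
    "gbdt",
    "xgboost",
)


@dataclass(frozen=True)
class BaseModelConfig:
    """Stated hyperparameters of the seven base learners."""

    n_trees: int = 100
    adaboost_learning_rate: float = 0.1
    xgb_max_depth: int = 3
    mlp_iters: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.xgb_max_depth, self.mlp_iters) <= 0:
            raise ValueError("tree count, depth and iterations must be positive")
        if self.adaboost_learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def make_base_model(kind: str, cfg: BaseModelConfig):
    """Instantiate one configured base learner (scale-sensitive ones piped
    through a standardizer)."""
    seed = cfg.seed
    if kind == "svm_rbf":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", probability=True, random_state=seed)
        )
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed)
    if kind == "extra_trees":
        return ExtraTreesClassifier(n_estimators=cfg.n_trees, random_state=seed)
    if kind == "mlp":
        return make_pipeline(
            StandardScaler(), MLPClassifier(max_iter=cfg.mlp_iters, random_state=seed)
        )
    if kind == "adaboost":
        return AdaBoostClassifier(
            n_estimators=cfg.n_trees,
            learning_rate=cfg.adaboost_learning_rate,
            random_state=seed,
        )
    if kind == "gbdt":
        return GradientBoostingClassifier(n_estimators=cfg.n_trees, random_state=seed)
    if kind == "xgboost":
        return HistGradientBoostingClassifier(
            max_iter=cfg.n_trees, max_depth=cfg.xgb_max_depth, random_state=seed
        )
    raise ValueError(f"unknown base model kind {kind!r}; choose from {BASE_MODEL_KINDS}")


@dataclass(frozen=True)
class ClassifierOutcome:
    """Per-trial 3-class probability vector plus its argmax label."""

    trial_id: str
    probs: np.ndarray
    label: SkillLabel = field(init=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (len(SkillLabel),):
            raise ValueError(f"probs must be a {len(SkillLabel)}-vector")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be non-negative and sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "label", SkillLabel(int(np.argmax(probs))))


@dataclass
class StackedModel:
    """Fitted base models plus a logistic-regression meta-learner.

    The meta-learner is trained only on out-of-fold base-model class
    probabilities, never on in-fold predictions.
    """

    base_models: dict
    meta_learner: LogisticRegression
    classes_: np.ndarray
    n_features: int
    k_folds: int = 3
    mode: str = "stacking"


def _class_probs(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """predict_proba aligned to the global class order (folds may miss classes)."""
    raw = model.predict_proba(X)
    out = np.zeros((X.shape[0], len(classes)))
    for j, c in enumerate(model.classes_):
        out[:, np.searchsorted(classes, c)] = raw[:, j]
    return out


def train_stacked(
    features,
    labels,
    config: BaseModelConfig = BaseModelConfig(),
    k_folds: int = 3,
    mode: str = "stacking",
) -> StackedModel:
    """Fit the seven base learners and the stacking meta-learner.

    Meta-features are the out-of-fold class probabilities of every base model
    (7 x 3 = 21 columns), produced by stratified K-fold cross-fitting, so no
    meta-feature for a sample comes from a model that saw that sample.
    """
    X = np.asarray(getattr(features, "values", features), dtype=float)
    y = np.asarray([int(l) for l in labels])
    if mode not in ("stacking", "majority_vote"):
        raise ValueError(f"unknown mode {mode!r}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    counts = np.bincount(y, minlength=len(SkillLabel))
    present = counts[counts > 0]
    if np.any(present < k_folds):
        raise ValueError(f"every class needs >= {k_folds} samples for {k_folds}-fold stacking")

    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=config.seed)
    meta_blocks = []
    base_models = {}
    for kind in BASE_MODEL_KINDS:
        model = make_base_model(kind, config)
        oof = cross_val_predict(model, X, y, cv=cv, method="predict_proba")
        meta_blocks.append(oof)
        base_models[kind] = make_base_model(kind, config).fit(X, y)
    meta_X = np.hstack(meta_blocks)
    meta = LogisticRegression(max_iter=1000, random_state=config.seed).fit(meta_X, y)
    return StackedModel(base_models, meta, classes, X.shape[1], k_folds, mode)


def predict_stacked(model: StackedModel, features, trial_ids=None) -> list[ClassifierOutcome]:
    """Fused predictions: meta-learner probabilities (stacking) or base-model
    majority vote with probability-sum tie-breaking."""
    X = np.asarray(getattr(features, "values", features), dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} feature columns, got {X.shape[1]}")
    if trial_ids is None:
        trial_ids = getattr(features, "trial_ids", None) or [str(i) for i in range(X.shape[0])]

    base_probs = np.stack(
        [_class_probs(model.base_models[k], X, model.classes_) for k in BASE_MODEL_KINDS]
    )  # (7, n, n_classes_present)

    n_levels = len(SkillLabel)
    probs = np.zeros((X.shape[0], n_levels))
    if model.mode == "stacking":
        meta_X = np.hstack(list(base_probs))
        raw = model.meta_learner.predict_proba(meta_X)
        for j, c in enumerate(model.meta_learner.classes_):
            probs[:, int(c)] = raw[:, j]
    else:
        votes = base_probs.argmax(axis=2)  # (7, n) indices into model.classes_
        summed = base_probs.sum(axis=0)  # (n, n_classes_present)
        for i in range(X.shape[0]):
            counts = np.bincount(votes[:, i], minlength=len(model.classes_))
            winners = np.flatnonzero(counts == counts.max())
            if len(winners) > 1:  # tie: highest summed base probability
                winners = winners[np.argsort(-summed[i, winners], kind="stable")[:1]]
            win_class = int(model.classes_[winners[0]])
            # report normalized summed probabilities but force the vote winner
            p = np.zeros(n_levels)
            for j, c in enumerate(model.classes_):
                p[int(c)] = summed[i, j]
            p /= p.sum()
            if int(np.argmax(p)) != win_class:
                p[win_class] = p.max() + 1e-6
                p /= p.sum()
            probs[i] = p
    probs = probs / probs.sum(axis=1, keepdims=True)
    return [ClassifierOutcome(tid, p) for tid, p in zip(trial_ids, probs)]


def evaluate_repeated(
    fit_predict,
    features,
    labels,
    n_runs: int = 30,
    train_fraction: float = 2 / 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated stratified split evaluation.

    ``fit_predict(X_train, y_train, X_test, run_seed)`` must return predicted
    integer labels for the test rows.  Returns a per-run accuracy frame with
    ``mean``/``sd`` in ``.attrs`` (sd is NaN for a single run).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = np.asarray(getattr(features, "values", features), dtype=float)
    y = np.asarray([int(l) for l in labels])
    counts = np.bincount(y)
    if np.any(counts[counts > 0] < 3):
        raise ValueError("every class needs >= 3 samples for stratified splitting")
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    accs = []
    for r in range(n_runs):
        rs = int(run_seeds[r] % (2**31 - 1))
        idx_tr, idx_te = train_test_split(
            np.arange(len(y)), train_size=train_fraction, stratify=y, random_state=rs
        )
        y_pred = fit_predict(X[idx_tr], y[idx_tr], X[idx_te], rs)
        accs.append(float(np.mean(np.asarray(y_pred) == y[idx_te])))
    df = pd.DataFrame({"run": np.arange(n_runs), "accuracy": accs})
    df.attrs["mean"] = float(np.mean(accs))
    df.attrs["sd"] = float(np.std(accs, ddof=1)) if n_runs > 1 else float("nan")
    return df


def stacked_fit_predict(
    config_seed_base: int = 0, mode: str = "stacking", k_folds: int = 3, **config_overrides
):
    """Adapter producing a ``fit_predict`` callable for :func:`evaluate_repeated`."""

    def fit_predict(X_tr, y_tr, X_te, run_seed):
        cfg = BaseModelConfig(
            seed=int((config_seed_base + run_seed) % (2**31 - 1)), **config_overrides
        )
        model = train_stacked(X_tr, y_tr, cfg, k_folds=k_folds, mode=mode)
        return [int(o.label) for o in predict_stacked(model, X_te)]

    return fit_predict
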