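"""Extreme-learning-machine late fusion of the two classifier branches.

An ELM is a single-hidden-layer network whose input weights and biases are
randomly drawn and frozen; only the hidden-to-output weights are solved, as
the minimum-norm least-squares fit of the hidden activations to one-hot
targets (Moore-Penrose pseudo-inverse).  Defaults: tanh activation, 20
hidden nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .ensemble import ClassifierOutcome
from .labeling import SkillLabel

__all__ = [
    "ELMModel",
    "build_fusion_features",
    "elm_train",
    "elm_predict",
    "accuracy_from_confusion",
    "save_elm",
    "load_elm",
]


@dataclass
class ELMModel:
    W: np.ndarray  # (d_in, n_hidden), drawn uniform(-1, 1)
    b: np.ndarray  # (n_hidden,)
    beta: np.ndarray  # (n_hidden, n_classes)
    n_hidden: int
    seed: int

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W + self.b)


def build_fusion_features(ts_out: ClassifierOutcome, img_out: ClassifierOutcome) -> np.ndarray:
    """Concatenate [time-series probs (3), image probs (3)] for one trial."""
    if ts_out.trial_id != img_out.trial_id:
        raise ValueError(
            f"branch outcomes refer to different trials: {ts_out.trial_id!r} vs {img_out.trial_id!r}"
        )
    return np.concatenate([ts_out.probs, img_out.probs])


def elm_train(X, y, n_hidden: int = 20, seed: int = 0) -> ELMModel:
    """Solve the ELM output weights for one-hot targets.

    H = tanh(XW + b) with W, b seed-drawn from uniform(-1, 1) and frozen;
    beta = pinv(H) @ onehot(y) is the minimum-norm least-squares solution.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    y = np.asarray([int(l) for l in y])
    if len(y) != X.shape[0] or len(y) < 1:
        raise ValueError("y must align with X rows and be non-empty")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(X.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    targets = np.zeros((len(y), len(SkillLabel)))
    targets[np.arange(len(y)), y] = 1.0
    H = np.tanh(X @ W + b)
    beta = np.linalg.pinv(H) @ targets
    return ELMModel(W, b, beta, n_hidden, seed)


def elm_predict(model: ELMModel, X, trial_ids=None) -> list[ClassifierOutcome]:
    """Scores = tanh(XW + b) @ beta; probabilities via softmax; label = argmax."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.W.shape[0]:
        raise ValueError(f"X must be 2-D with {model.W.shape[0]} columns")
    if trial_ids is None:
        trial_ids = [str(i) for i in range(X.shape[0])]
    scores = model.hidden(X) @ model.beta
    probs = softmax(scores, axis=1)
    return [ClassifierOutcome(tid, p) for tid, p in zip(trial_ids, probs)]


def accuracy_from_confusion(matrix) -> float:
    """100 x trace / total of a confusion-count matrix, rounded to 1 decimal."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
        raise ValueError("confusion matrix must hold non-negative integer counts")
    total = int(m.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return round(100.0 * float(np.trace(m)) / total, 1)


def save_elm(path, model: ELMModel) -> None:
    payload = {
        "W": model.W.tolist(),
        "b": model.b.tolist(),
        "beta": model.beta.tolist(),
        "n_hidden": model.n_hidden,
        "seed": model.seed,
        "activation": "tanh",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_elm(path) -> ELMModel:
    with open(path) as fh:
        d = json.load(fh)
    return ELMModel(
        np.array(d["W"]), np.array(d["b"]), np.array(d["beta"]), int(d["n_hidden"]), int(d["seed"])
    )
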