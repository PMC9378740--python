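"""Fixed-length resampling and the shapelet transform.

A shapelet is a time-series subsequence that discriminates between classes;
its feature value for a series is the minimum Euclidean distance between the
shapelet and any same-length contiguous subsequence of that series.  The
shapelet transform maps every series to its vector of distances to a selected
shapelet set, turning series classification into tabular classification.

The two gaze coordinates are treated as independent channels: candidates are
generated per channel and compete on quality; the selected shapelets' feature
columns are concatenated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .gaze_io import GazeRecording

__all__ = [
    "SeriesSet",
    "Shapelet",
    "FeatureMatrix",
    "resample_series",
    "build_series_set",
    "subsequence_distance",
    "generate_candidates",
    "assess_candidate",
    "info_gain",
    "f_stat",
    "mood_median",
    "remove_self_similar",
    "extract_shapelets",
    "shapelet_transform",
    "write_shapelets_csv",
    "read_shapelets_csv",
]

CHANNELS = ("x", "y")


@dataclass
class SeriesSet:
    """Equal-length multichannel series for a set of trials.

    ``values`` has shape (n_trials, length, n_channels); ``channels`` names
    the last axis.
    """

    values: np.ndarray
    trial_ids: list[str]
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n, length, channels)")
        if self.values.shape[0] != len(self.trial_ids):
            raise ValueError("trial_ids must align with values rows")
        if self.values.shape[2] != len(self.channels):
            raise ValueError("channel axis must match channel names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """(n, length) view of one named channel."""
        return self.values[:, :, self.channels.index(name)]


@dataclass
class Shapelet:
    """A scored subsequence taken from one trial's series on one channel."""

    values: np.ndarray
    source_trial: str
    start: int
    channel: str
    quality: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("shapelet values must be a 1-D vector of length >= 2")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureMatrix:
    """n_trials x k matrix of series-to-shapelet distances."""

    values: np.ndarray
    trial_ids: list[str]
    shapelets: list[Shapelet]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.trial_ids), len(self.shapelets)):
            raise ValueError("feature matrix shape must be (n_trials, n_shapelets)")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"shp{j}" for j in range(len(self.shapelets))]
        return pd.DataFrame(self.values, index=self.trial_ids, columns=cols)


def resample_series(series, target_len: int) -> np.ndarray:
    """Linearly resample to ``target_len`` evenly spaced points.

    Endpoints are fixed: output[0] == series[0] and output[-1] == series[-1];
    interior points are linear interpolations at evenly spaced fractional
    positions over [0, len-1].
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    if target_len < 2:
        raise ValueError(f"target_len must be >= 2, got {target_len}")
    positions = np.linspace(0.0, len(series) - 1.0, target_len)
    return np.interp(positions, np.arange(len(series)), series)


def _interpolate_invalid(t: np.ndarray, v: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid samples by linear interpolation over valid neighbours."""
    if valid.all():
        return v
    if not valid.any():
        raise ValueError("recording has no valid samples to interpolate from")
    out = v.copy()
    out[~valid] = np.interp(t[~valid], t[valid], v[valid])
    return out


def build_series_set(recordings: list[GazeRecording], target_len: int) -> SeriesSet:
    """Turn raw recordings into an equal-length (n, target_len, 2) series set.

    Invalid samples are filled by linear interpolation over the valid ones
    before resampling, so dropout gaps do not inject placeholder coordinates.
    """
    values = np.empty((len(recordings), target_len, len(CHANNELS)), dtype=float)
    trial_ids = []
    for i, rec in enumerate(recordings):
        t = rec.t
        xy = rec.xy
        valid = rec.valid_mask
        for c in range(len(CHANNELS)):
            filled = _interpolate_invalid(t, xy[:, c], valid)
            values[i, :, c] = resample_series(filled, target_len)
        trial_ids.append(rec.trial_id)
    return SeriesSet(values, trial_ids)


def subsequence_distance(S, T) -> float:
    """Minimum Euclidean distance from S to any |S|-length subsequence of T."""
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    if len(S) > len(T):
        raise ValueError(f"shapelet length {len(S)} exceeds series length {len(T)}")
    windows = sliding_window_view(T, len(S))
    return float(np.sqrt(np.min(np.sum((windows - S) ** 2, axis=1))))


def _min_distances(shapelet_values: np.ndarray, channel_matrix: np.ndarray) -> np.ndarray:
    """Vectorized min subsequence distance of one shapelet to every series row."""
    l = len(shapelet_values)
    windows = sliding_window_view(channel_matrix, l, axis=1)  # (n, m-l+1, l)
    sq = np.einsum("nwl,nwl->nw", windows, windows)
    cross = windows @ shapelet_values
    d2 = sq - 2.0 * cross + float(shapelet_values @ shapelet_values)
    return np.sqrt(np.maximum(d2.min(axis=1), 0.0))


def generate_candidates(seriesset: SeriesSet, lmin: int, lmax: int) -> list[Shapelet]:
    """All contiguous subsequences of each length in [lmin, lmax], per channel."""
    m = seriesset.length
    if not (2 <= lmin <= lmax <= m):
        raise ValueError(f"need 2 <= lmin <= lmax <= series length, got ({lmin}, {lmax}, {m})")
    out = []
    for i, ch, l in itertools.product(range(seriesset.n), seriesset.channels, range(lmin, lmax + 1)):
        row = seriesset.channel(ch)[i]
        for start in range(m - l + 1):
            out.append(Shapelet(row[start : start + l], seriesset.trial_ids[i], start, ch))
    return out


def candidate_count(seriesset: SeriesSet, lmin: int, lmax: int) -> int:
    """Pool size: n x channels x sum over lengths of (length - l + 1)."""
    m = seriesset.length
    if not (2 <= lmin <= lmax <= m):
        raise ValueError(f"need 2 <= lmin <= lmax <= series length, got ({lmin}, {lmax}, {m})")
    per_series = sum(m - l + 1 for l in range(lmin, lmax + 1))
    return seriesset.n * len(seriesset.channels) * per_series


def _decode_candidate(seriesset: SeriesSet, lmin: int, lmax: int, flat: int) -> Shapelet:
    """Map a flat pool index to its subsequence, mirroring generate_candidates order."""
    m = seriesset.length
    per_length = [m - l + 1 for l in range(lmin, lmax + 1)]
    per_series_channel = sum(per_length)
    i, rem = divmod(flat, len(seriesset.channels) * per_series_channel)
    ch_idx, rem = divmod(rem, per_series_channel)
    for l, n_starts in zip(range(lmin, lmax + 1), per_length):
        if rem < n_starts:
            start = rem
            break
        rem -= n_starts
    ch = seriesset.channels[ch_idx]
    row = seriesset.channel(ch)[i]
    return Shapelet(row[start : start + l], seriesset.trial_ids[i], start, ch)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def info_gain(distances, labels) -> float:
    """Best-split information gain of a threshold on the distance list.

    Scans every midpoint between consecutive distinct sorted distances and
    returns the maximum reduction from parent entropy (log base 2) to the
    size-weighted child entropies.  Zero when the labels are single-class.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    parent = _entropy(labels)
    if parent == 0.0:
        return 0.0
    order = np.argsort(distances, kind="stable")
    d_sorted = distances[order]
    classes, y_int = np.unique(labels[order], return_inverse=True)
    n = len(labels)
    # cumulative per-class counts for every prefix split, all splits at once
    onehot = np.zeros((n, len(classes)))
    onehot[np.arange(n), y_int] = 1.0
    left_counts = np.cumsum(onehot, axis=0)[:-1]  # split after position i
    right_counts = left_counts[-1] + onehot[-1] - left_counts
    valid = d_sorted[:-1] != d_sorted[1:]  # only midpoints between distinct values
    if not valid.any():
        return 0.0

    def _h(counts: np.ndarray) -> np.ndarray:
        tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / tot
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return -terms.sum(axis=1)

    n_left = np.arange(1, n)
    child = (n_left * _h(left_counts) + (n - n_left) * _h(right_counts)) / n
    return float(max(0.0, np.max(parent - child[valid])))


def f_stat(distances, labels) -> float:
    """One-way F statistic of the distances grouped by class label."""
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    groups = [distances[labels == c] for c in np.unique(labels)]
    if len(groups) < 2:
        return 0.0
    stat, _ = stats.f_oneway(*groups)
    return float(stat) if np.isfinite(stat) else 0.0


def mood_median(distances, labels) -> float:
    """Chi-square statistic of the above/below-pooled-median contingency table."""
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        return 0.0
    med = np.median(distances)
    above = distances > med
    table = np.array(
        [[np.sum(above & (labels == c)), np.sum(~above & (labels == c))] for c in classes]
    )
    # degenerate: every distance on one side of the median
    if (table.sum(axis=0) == 0).any():
        return 0.0
    stat, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat)


_MEASURES = {"info_gain": info_gain, "f_stat": f_stat, "mood_median": mood_median}


def assess_candidate(cand: Shapelet, seriesset: SeriesSet, labels, measure: str = "info_gain") -> float:
    """Quality of a candidate: distance to every series, scored by ``measure``."""
    if measure not in _MEASURES:
        raise ValueError(f"unknown quality measure {measure!r}; choose from {sorted(_MEASURES)}")
    labels = np.asarray(labels)
    if len(labels) != seriesset.n:
        raise ValueError("labels must align with series")
    distances = _min_distances(cand.values, seriesset.channel(cand.channel))
    return _MEASURES[measure](distances, labels)


def remove_self_similar(shapelets: list[Shapelet]) -> list[Shapelet]:
    """Greedy overlap pruning of a quality-descending shapelet list.

    A shapelet is kept only if its half-open index range [start, start+l) on
    the same source trial and channel does not overlap any already-kept one.
    """
    qualities = [s.quality for s in shapelets]
    if any(b > a for a, b in zip(qualities, qualities[1:])):
        raise ValueError("input must be sorted by quality descending")
    kept: list[Shapelet] = []
    for cand in shapelets:
        overlaps = any(
            k.source_trial == cand.source_trial
            and k.channel == cand.channel
            and cand.start < k.start + len(k)
            and k.start < cand.start + len(cand)
            for k in kept
        )
        if not overlaps:
            kept.append(cand)
    return kept


def _sort_key(s: Shapelet, separation: float = 0.0):
    # quality desc; quality ties broken by class separation of the distance
    # list (info gain saturates easily at small n), then shorter length,
    # earlier start, lower trial id
    return (-s.quality, -separation, len(s), s.start, s.source_trial, s.channel)


def extract_shapelets(
    seriesset: SeriesSet,
    labels,
    k: int = 10,
    lmin: int | None = None,
    lmax: int | None = None,
    measure: str = "info_gain",
    max_candidates: int | None = None,
    seed: int | None = 0,
) -> list[Shapelet]:
    """Select up to ``k`` top-quality, non-self-similar shapelets.

    ``lmin``/``lmax`` default to 3%% and 10%% of the series length (minimum 2).
    When ``max_candidates`` is given, a seed-controlled uniform subsample of
    the candidate pool is assessed instead of the full enumeration, which is
    infeasible for long series.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = seriesset.length
    if lmin is None:
        lmin = max(2, int(round(0.03 * m)))
    if lmax is None:
        lmax = max(lmin, int(round(0.10 * m)))
    n_total = candidate_count(seriesset, lmin, lmax)
    if n_total == 0:
        raise ValueError("no candidates generated")
    if max_candidates is not None and max_candidates < n_total:
        # sample candidate indices lazily; the full pool is never materialized
        rng = np.random.default_rng(seed)
        flat = np.sort(rng.choice(n_total, size=max_candidates, replace=False))
        candidates = [_decode_candidate(seriesset, lmin, lmax, int(f)) for f in flat]
    else:
        candidates = generate_candidates(seriesset, lmin, lmax)
    labels_arr = np.asarray(labels)
    if len(labels_arr) != seriesset.n:
        raise ValueError("labels must align with series")
    quality_fn = _MEASURES[measure] if measure in _MEASURES else None
    if quality_fn is None:
        raise ValueError(f"unknown quality measure {measure!r}; choose from {sorted(_MEASURES)}")
    scored = []
    for c in candidates:
        dists = _min_distances(c.values, seriesset.channel(c.channel))
        sep = f_stat(dists, labels_arr)  # tie-break on class separation
        scored.append((replace(c, quality=quality_fn(dists, labels_arr)), sep))
    scored.sort(key=lambda pair: _sort_key(*pair))
    return remove_self_similar([c for c, _ in scored])[:k]


def shapelet_transform(seriesset: SeriesSet, shapelets: list[Shapelet]) -> FeatureMatrix:
    """Map every series to its vector of min distances to each shapelet."""
    if not shapelets:
        raise ValueError("shapelet list is empty")
    for s in shapelets:
        if s.channel not in seriesset.channels:
            raise ValueError(f"shapelet channel {s.channel!r} not present in series set")
        if len(s) > seriesset.length:
            raise ValueError("shapelet longer than series")
    cols = [_min_distances(s.values, seriesset.channel(s.channel)) for s in shapelets]
    return FeatureMatrix(np.column_stack(cols), list(seriesset.trial_ids), list(shapelets))


def write_shapelets_csv(path, shapelets: list[Shapelet]) -> None:
    rows = []
    for s in shapelets:
        rows.append(
            {
                "channel": s.channel,
                "source_trial": s.source_trial,
                "start": s.start,
                "length": len(s),
                "quality": s.quality,
                "values": ";".join(repr(float(v)) for v in s.values),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_shapelets_csv(path) -> list[Shapelet]:
    df = pd.read_csv(path)
    return [
        Shapelet(
            np.array([float(v) for v in r.values.split(";")]),
            str(r.source_trial),
            int(r.start),
            str(r.channel),
            float(r.quality),
        )
        for r in df.itertuples(index=False)
    ]
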