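import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeskill.labeling import SkillLabel
from gazeskill.synthgen import planted_motif_set
from gazeskill.timeseries import (
    FeatureMatrix,
    SeriesSet,
    Shapelet,
    assess_candidate,
    candidate_count,
    f_stat,
    generate_candidates,
    info_gain,
    mood_median,
    read_shapelets_csv,
    remove_self_similar,
    resample_series,
    extract_shapelets,
    shapelet_transform,
    subsequence_distance,
    write_shapelets_csv,
)

# ---------------------------------------------------------------- oracles


def brute_subsequence_distance(S, T):
    S, T = np.asarray(S, float), np.asarray(T, float)
    return min(
        math.sqrt(float(np.sum((T[i : i + len(S)] - S) ** 2)))
        for i in range(len(T) - len(S) + 1)
    )


def brute_info_gain(distances, labels):
    """Exhaustive threshold scan over midpoints of consecutive sorted distances."""
    distances = np.asarray(distances, float)
    labels = np.asarray(labels)

    def entropy(ys):
        if len(ys) == 0:
            return 0.0
        _, counts = np.unique(ys, return_counts=True)
        p = counts / counts.sum()
        return float(-np.sum(p * np.log2(p)))

    parent = entropy(labels)
    d_sorted = np.sort(np.unique(distances))
    best = 0.0
    for a, b in zip(d_sorted, d_sorted[1:]):
        thr = (a + b) / 2
        left, right = labels[distances <= thr], labels[distances > thr]
        child = (len(left) * entropy(left) + len(right) * entropy(right)) / len(labels)
        best = max(best, parent - child)
    return best


def _series_set(arr, channels=("x",)):
    arr = np.asarray(arr, float)
    values = arr[:, :, None] if arr.ndim == 2 else arr
    return SeriesSet(values, [f"s{i}" for i in range(len(arr))], channels=channels)


# ---------------------------------------------------------------- resample


class TestResample:
    def test_integer_landing(self):
        np.testing.assert_allclose(resample_series([0, 1, 2, 3, 4], 3), [0, 2, 4])

    def test_closed_form_interpolation(self):
        # positions 0, 1/3, 2/3, 1 over [1, 3]
        np.testing.assert_allclose(resample_series([1, 3], 4), [1, 5 / 3, 7 / 3, 3])

    def test_identity_when_length_unchanged(self):
        s = np.random.default_rng(0).normal(size=17)
        np.testing.assert_allclose(resample_series(s, 17), s)

    @pytest.mark.parametrize("bad_target", [0, 1, -3])
    def test_target_too_short(self, bad_target):
        with pytest.raises(ValueError):
            resample_series([1, 2, 3], bad_target)

    def test_input_too_short(self):
        with pytest.raises(ValueError):
            resample_series([1.0], 5)

    @given(
        data=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30),
        target=st.integers(2, 50),
    )
    def test_endpoints_always_preserved(self, data, target):
        out = resample_series(data, target)
        assert len(out) == target
        assert out[0] == data[0]
        assert out[-1] == data[-1]


# ------------------------------------------------------ subsequence distance


class TestSubsequenceDistance:
    def test_exact_occurrence(self):
        assert subsequence_distance([1, 2], [0, 1, 2, 3]) == 0.0

    def test_all_subsequences_equidistant(self):
        assert subsequence_distance([0, 0], [1, 1, 1]) == pytest.approx(math.sqrt(2))

    def test_shapelet_longer_than_series_is_error(self):
        with pytest.raises(ValueError):
            subsequence_distance([1, 2, 3], [1, 2])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            l = int(rng.integers(2, 6))
            m = int(rng.integers(l, 15))
            S, T = rng.normal(size=l), rng.normal(size=m)
            assert subsequence_distance(S, T) == pytest.approx(
                brute_subsequence_distance(S, T)
            )


# ---------------------------------------------------------------- candidates


class TestGenerateCandidates:
    def test_counting_formula(self):
        ss = _series_set(np.arange(5.0)[None, :])
        cands = generate_candidates(ss, 2, 3)
        assert len(cands) == 4 + 3
        assert candidate_count(ss, 2, 3) == 7

    def test_full_length_candidates(self):
        ss = _series_set(np.arange(10.0).reshape(2, 5))
        assert len(generate_candidates(ss, 5, 5)) == 2

    def test_length_bounds_validated(self):
        ss = _series_set(np.arange(5.0)[None, :])
        with pytest.raises(ValueError):
            generate_candidates(ss, 6, 6)
        with pytest.raises(ValueError):
            generate_candidates(ss, 1, 3)

    def test_two_channel_pool_doubles(self):
        values = np.random.default_rng(0).normal(size=(3, 8, 2))
        ss = SeriesSet(values, ["a", "b", "c"])
        assert candidate_count(ss, 2, 2) == 2 * 3 * 7


# ------------------------------------------------------------- quality scores


class TestQualityMeasures:
    def test_info_gain_pure_split(self):
        assert info_gain([1, 2, 5, 6], ["A", "A", "B", "B"]) == 1.0

    def test_info_gain_single_class_is_zero(self):
        assert info_gain([1, 2, 3], ["A", "A", "A"]) == 0.0

    def test_info_gain_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = rng.normal(size=12)
            y = rng.choice(["A", "B", "C"], size=12)
            assert info_gain(d, y) == pytest.approx(brute_info_gain(d, y))

    def test_info_gain_bounded_by_parent_entropy(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            d = rng.normal(size=15)
            y = rng.choice([0, 1, 2], size=15)
            _, counts = np.unique(y, return_counts=True)
            p = counts / counts.sum()
            h = -np.sum(p * np.log2(p))
            assert 0.0 <= info_gain(d, y) <= h + 1e-12

    def test_info_gain_null_under_permutation(self):
        # mean gain over shuffles stays within 3 sd of the 0-separation null
        rng = np.random.default_rng(17)
        d = rng.normal(size=30)
        y = np.repeat([0, 1, 2], 10)
        gains = [info_gain(d, rng.permutation(y)) for _ in range(100)]
        null_gains = [
            info_gain(rng.normal(size=30), np.repeat([0, 1, 2], 10)) for _ in range(100)
        ]
        mu, sd = np.mean(null_gains), np.std(null_gains, ddof=1)
        assert abs(np.mean(gains) - mu) <= 3 * sd

    def test_f_stat_matches_scipy_oneway(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(5)
        d = rng.normal(size=15)
        y = np.repeat([0, 1, 2], 5)
        expected = f_oneway(d[y == 0], d[y == 1], d[y == 2]).statistic
        assert f_stat(d, y) == pytest.approx(float(expected))

    def test_mood_median_matches_scipy_median_test(self):
        from scipy.stats import median_test

        rng = np.random.default_rng(6)
        d = np.round(rng.normal(size=20), 3)
        y = np.repeat([0, 1], 10)
        stat, _, _, _ = median_test(d[y == 0], d[y == 1], correction=False)
        assert mood_median(d, y) == pytest.approx(float(stat))

    def test_assess_candidate_uses_distances(self):
        # class B contains the candidate exactly -> distances separate classes
        rows = np.array(
            [[5.0, 5.0, 5.0, 5.0], [6.0, 6.0, 6.0, 6.0], [0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 2.9]]
        )
        ss = _series_set(rows)
        cand = Shapelet(np.array([0.0, 1.0, 2.0]), "s2", 0, "x")
        gain = assess_candidate(cand, ss, ["A", "A", "B", "B"])
        assert gain == 1.0

    def test_unknown_measure_rejected(self):
        ss = _series_set(np.arange(8.0)[None, :])
        cand = Shapelet(np.array([0.0, 1.0]), "s0", 0, "x")
        with pytest.raises(ValueError):
            assess_candidate(cand, ss, ["A"], measure="gini")


# -------------------------------------------------------------- self-similar


def _shp(trial, start, length, quality, channel="x"):
    return Shapelet(np.zeros(length), trial, start, channel, quality)


class TestRemoveSelfSimilar:
    def test_overlapping_same_trial_keeps_best(self):
        kept = remove_self_similar([_shp("a", 0, 4, 0.9), _shp("a", 2, 4, 0.8)])
        assert len(kept) == 1 and kept[0].quality == 0.9

    def test_same_range_different_trials_both_kept(self):
        kept = remove_self_similar([_shp("a", 0, 4, 0.9), _shp("b", 0, 4, 0.8)])
        assert len(kept) == 2

    def test_adjacent_half_open_ranges_both_kept(self):
        kept = remove_self_similar([_shp("a", 0, 4, 0.9), _shp("a", 4, 4, 0.8)])
        assert len(kept) == 2

    def test_different_channels_do_not_conflict(self):
        kept = remove_self_similar(
            [_shp("a", 0, 4, 0.9, "x"), _shp("a", 0, 4, 0.8, "y")]
        )
        assert len(kept) == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            remove_self_similar([_shp("a", 0, 4, 0.5), _shp("a", 6, 4, 0.9)])


# ------------------------------------------------------------- extraction


class TestExtractShapelets:
    def test_planted_motif_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            vals, labs, wins = planted_motif_set(n_per_class=8, seed=seed)
            ss = _series_set(vals)
            shp = extract_shapelets(
                ss, labs, k=3, lmin=12, lmax=24, max_candidates=600, seed=seed
            )
            top = shp[0]
            i = ss.trial_ids.index(top.source_trial)
            win = wins.get(i)
            hits += win is not None and top.start < win[1] and win[0] < top.start + len(top)
        assert hits >= 9

    def test_k_larger_than_survivors_returns_all(self):
        vals = np.random.default_rng(0).normal(size=(4, 12))
        ss = _series_set(vals)
        shp = extract_shapelets(ss, [0, 0, 1, 1], k=10_000, lmin=3, lmax=4)
        assert 1 <= len(shp) <= 10_000

    def test_subsample_equals_full_when_budget_covers_pool(self):
        vals = np.random.default_rng(1).normal(size=(8, 10))
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        ss = _series_set(vals)
        full = extract_shapelets(ss, labels, k=5, lmin=3, lmax=5, max_candidates=None)
        capped = extract_shapelets(
            ss, labels, k=5, lmin=3, lmax=5, max_candidates=10**9, seed=0
        )
        assert len(full) == len(capped)
        for a, b in zip(full, capped):
            assert (a.source_trial, a.start, len(a), a.channel) == (
                b.source_trial,
                b.start,
                len(b),
                b.channel,
            )

    def test_lazy_subsample_decodes_valid_candidates(self):
        vals = np.random.default_rng(2).normal(size=(5, 20, 2))
        ss = SeriesSet(vals, [f"s{i}" for i in range(5)])
        shp = extract_shapelets(ss, [0, 0, 1, 1, 1], k=4, lmin=3, lmax=6, max_candidates=50, seed=7)
        for s in shp:
            i = ss.trial_ids.index(s.source_trial)
            row = ss.channel(s.channel)[i]
            np.testing.assert_allclose(s.values, row[s.start : s.start + len(s)])

    def test_deterministic(self):
        vals, labs, _ = planted_motif_set(n_per_class=4, seed=5)
        ss = _series_set(vals)
        a = extract_shapelets(ss, labs, k=3, lmin=10, lmax=15, max_candidates=100, seed=3)
        b = extract_shapelets(ss, labs, k=3, lmin=10, lmax=15, max_candidates=100, seed=3)
        assert [(s.source_trial, s.start, len(s)) for s in a] == [
            (s.source_trial, s.start, len(s)) for s in b
        ]


# ------------------------------------------------------------- transform


class TestShapeletTransform:
    def test_exact_occurrence_gives_zero_feature(self):
        vals = np.arange(20.0).reshape(2, 10)
        ss = _series_set(vals)
        shp = [Shapelet(vals[0, 2:5], "s0", 2, "x", 1.0)]
        fm = shapelet_transform(ss, shp)
        assert fm.values[0, 0] == 0.0

    def test_shape_contract(self):
        vals = np.random.default_rng(0).normal(size=(3, 12))
        ss = _series_set(vals)
        shp = [
            Shapelet(vals[0, :4], "s0", 0, "x", 1.0),
            Shapelet(vals[1, 3:8], "s1", 3, "x", 0.5),
        ]
        assert shapelet_transform(ss, shp).values.shape == (3, 2)

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(6, 15))
        ss = _series_set(vals)
        shp = [
            Shapelet(rng.normal(size=int(rng.integers(2, 8))), f"s{i % 6}", 0, "x", 0.0)
            for i in range(5)
        ]
        fm = shapelet_transform(ss, shp)
        for i, j in itertools.product(range(6), range(5)):
            assert fm.values[i, j] == pytest.approx(
                brute_subsequence_distance(shp[j].values, vals[i])
            )

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=(5, 12))
        shp = [Shapelet(rng.normal(size=4), "s0", 0, "x", 0.0)]
        fm = shapelet_transform(_series_set(vals), shp)
        perm = rng.permutation(5)
        fm_p = shapelet_transform(_series_set(vals[perm]), shp)
        np.testing.assert_allclose(fm_p.values, fm.values[perm])

    def test_channel_mismatch_is_error(self):
        ss = _series_set(np.random.default_rng(0).normal(size=(2, 10)))
        with pytest.raises(ValueError):
            shapelet_transform(ss, [Shapelet(np.zeros(3), "s0", 0, "y", 0.0)])

    def test_nonnegative_entries_enforced(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.array([[-1.0]]), ["a"], [Shapelet(np.zeros(2), "a", 0, "x", 0.0)])


def test_shapelet_csv_roundtrip(tmp_path):
    shp = [
        Shapelet(np.array([1.5, -2.25, 3.0]), "t0001", 7, "x", 0.83),
        Shapelet(np.array([0.0, 1.0]), "t0002", 0, "y", 0.5),
    ]
    p = tmp_path / "shapelets.csv"
    write_shapelets_csv(p, shp)
    back = read_shapelets_csv(p)
    assert len(back) == 2
    for a, b in zip(shp, back):
        np.testing.assert_allclose(a.values, b.values)
        assert (a.source_trial, a.start, a.channel) == (b.source_trial, b.start, b.channel)
        assert a.quality == pytest.approx(b.quality)
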