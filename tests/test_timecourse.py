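"""z-normalization, shape-based distance, clustering, and the
native-reference dendrogram cut."""

import numpy as np
import pandas as pd
import pytest

from silcspp.features import group_by_coelution
from silcspp.sil_trace import find_multiplets
from silcspp.timecourse import (
    ClusterResult,
    ConstantProfileError,
    hcluster,
    native_reference_cut,
    peak_time,
    ratio_profiles,
    sbd,
    znorm,
)


class TestZnorm:
    def test_basic(self):
        np.testing.assert_allclose(znorm([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_allclose(znorm(znorm(x)), znorm(x), atol=1e-12)

    def test_affine_invariance(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_allclose(znorm(2.5 * x + 7), znorm(x), atol=1e-12)

    def test_constant_flagged(self):
        with pytest.raises(ConstantProfileError):
            znorm([2, 2, 2])


def sbd_oracle(x, y):
    """Exhaustive evaluation over every integer lag with explicit padding."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    best = -np.inf
    for w in range(-(n - 1), n):
        cc = sum(
            x[i + w] * y[i] for i in range(n) if 0 <= i + w < n
        )
        best = max(best, cc)
    return 1 - best / np.sqrt(np.dot(x, x) * np.dot(y, y))


class TestSbd:
    def test_identity_and_scale_invariance(self):
        x = znorm([0, 1, 5, 2, 1, 0.5])
        assert sbd(x, x) == pytest.approx(0, abs=1e-12)
        assert sbd(x, 3.7 * x) == pytest.approx(0, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = znorm(rng.normal(size=12)), znorm(rng.normal(size=12))
            assert sbd(x, y) == pytest.approx(sbd(y, x), abs=1e-12)
            assert 0 <= sbd(x, y) <= 2

    def test_matches_exhaustive_lag_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            x, y = znorm(rng.normal(size=12)), znorm(rng.normal(size=12))
            assert sbd(x, y) == pytest.approx(sbd_oracle(x, y), abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sbd([1, 2, 3], [1, 2])


class TestHcluster:
    def test_identical_pair_merges_first(self):
        profiles = {
            "a": [0, 1, 2, 1, 0.5],
            "b": [0, 2, 4, 2, 1.0],  # same shape as a (scaled)
            "c": [2, 1, 0, 1, 2.0],  # inverted
        }
        result = hcluster(profiles)
        first = result.linkage[0]
        merged = {result.ids[int(first[0])], result.ids[int(first[1])]}
        assert merged == {"a", "b"}

    def test_permutation_invariant_partitions(self):
        rng = np.random.default_rng(10)
        data = {f"p{i}": rng.normal(size=10) for i in range(12)}
        res1 = hcluster(data)
        order = list(data)[::-1]
        res2 = hcluster({k: data[k] for k in order})
        for k in (2, 3, 4):
            l1, l2 = res1.labels(k=k), res2.labels(k=k)
            for a in data:
                for b in data:
                    assert (l1[a] == l1[b]) == (l2[a] == l2[b])

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            hcluster({"only": [1, 2, 3]})

    def test_newick_contains_all_leaves(self):
        profiles = {f"p{i}": np.sin(np.arange(8) + i) for i in range(5)}
        newick = hcluster(profiles).to_newick()
        assert newick.endswith(";")
        for name in profiles:
            assert name in newick


def manual_result(ids, linkage_rows):
    return ClusterResult(tuple(ids), np.array(linkage_rows, float))


class TestNativeReferenceCut:
    def test_cut_below_first_mixing_merge(self):
        # leaves: n0 (native), l0, l1 (labeled); l0+l1 merge at 0.2,
        # native joins them at 0.8 -> cut at the 0.2 merge height
        result = manual_result(
            ["n0", "l0", "l1"], [[1, 2, 0.2, 2], [0, 3, 0.8, 3]]
        )
        height, labels = native_reference_cut(result, ["n0"], ["l0", "l1"])
        assert height == pytest.approx(0.2)
        assert labels["n0"] != labels["l0"] == labels["l1"]

    def test_early_mixing_gives_zero_height(self):
        result = manual_result(
            ["n0", "l0", "l1"], [[0, 1, 0.1, 2], [2, 3, 0.9, 3]]
        )
        height, labels = native_reference_cut(result, ["n0"], ["l0", "l1"])
        assert height == 0.0
        assert len(set(labels.values())) == 3

    def test_no_labeled_profiles_returns_root_height(self):
        result = manual_result(
            ["n0", "n1", "x"], [[0, 1, 0.3, 2], [2, 3, 0.7, 3]]
        )
        height, _ = native_reference_cut(result, ["n0", "n1"], [])
        assert height == pytest.approx(0.7)

    def test_missing_native_rejected(self):
        result = manual_result(["a", "b"], [[0, 1, 0.5, 2]])
        with pytest.raises(ValueError):
            native_reference_cut(result, ["ghost"], ["b"])

    def test_never_cocluster_at_returned_height(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            data = {f"f{i}": rng.normal(size=8) for i in range(10)}
            result = hcluster(data)
            natives = ["f0", "f1"]
            labeled = [f"f{i}" for i in range(2, 10)]
            _, labels = native_reference_cut(result, natives, labeled)
            for n in natives:
                for l in labeled:
                    assert labels[n] != labels[l]


class TestRatioProfiles:
    def _setup(self, clean_flax):
        features, design, truth = clean_flax
        return features, design, list(truth.multiplets)

    def test_heavy_equals_light_gives_unity(self, clean_flax):
        features, design, multiplets = self._setup(clean_flax)
        m = multiplets[0]
        doctored = features.copy()
        samples = [c for c in features.columns if c not in ("id", "mz", "rt")]
        light_row = doctored["id"] == m.light_id
        heavy_row = doctored["id"] == m.members[0][1]
        doctored.loc[heavy_row, samples] = doctored.loc[light_row, samples].to_numpy()
        doctored.loc[light_row, samples] = np.maximum(
            doctored.loc[light_row, samples].to_numpy(), 1.0
        )
        doctored.loc[heavy_row, samples] = doctored.loc[light_row, samples].to_numpy()
        profiles = ratio_profiles([m], doctored, design, floor=0.5)
        series = np.asarray(profiles[0].ratios)
        np.testing.assert_allclose(series[~np.isnan(series)], 1.0)

    def test_heavy_all_zero_gives_zero(self, clean_flax):
        features, design, multiplets = self._setup(clean_flax)
        m = multiplets[0]
        doctored = features.copy()
        samples = [c for c in features.columns if c not in ("id", "mz", "rt")]
        doctored.loc[doctored["id"] == m.members[0][1], samples] = 0.0
        doctored.loc[doctored["id"] == m.light_id, samples] = 100.0
        profiles = ratio_profiles([m], doctored, design, floor=0.5)
        np.testing.assert_allclose(np.asarray(profiles[0].ratios), 0.0)

    def test_precursor_ratio_peaks_at_first_post_feeding_point(self, clean_flax):
        features, design, multiplets = self._setup(clean_flax)
        precursor = [m for m in multiplets if m.light_id.startswith("coumaric_acid|")][0]
        profiles = ratio_profiles([precursor], features, design)
        rp = profiles[0]
        assert peak_time(rp.times, rp.ratios) == 0.5
        post = np.asarray(rp.ratios)[1:]
        assert (np.diff(post[~np.isnan(post)]) <= 0).all()


class TestPeakTime:
    def test_simple_max(self):
        assert peak_time([0, 1, 2], [0, 1, 0]) == 1

    def test_monotone_series_peaks_at_end(self):
        assert peak_time([0, 1, 2, 3], [1, 2, 3, 4]) == 3

    def test_tie_resolves_earliest(self):
        assert peak_time([0, 1, 2], [5, 5, 1]) == 0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            peak_time([0, 1], [np.nan, np.nan])
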