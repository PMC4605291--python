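import logging
import math

import numpy as np
import pytest

from idrbind.annotations import AnnotatedProtein
from idrbind.features import (
    DEFAULT_WS,
    FeatureVectorSet,
    WindowSpec,
    build_features,
    contrast_feature,
    contrast_vector,
    derive_window_size,
    select_features,
    window_mean_vector,
)
from idrbind.profiles import ProfileMatrix, build_profile_matrix

from conftest import random_protein


def nearest_rank_oracle(lengths, q=0.2):
    s = sorted(lengths)
    return s[max(1, math.ceil(q * len(s))) - 1]


class TestDeriveWindowSize:
    def test_constant_distribution(self):
        assert derive_window_size([21] * 8) == 21

    def test_worked_example(self):
        lengths = [5, 10, 15, 20, 25, 30, 35, 40, 45, 50]
        assert nearest_rank_oracle(lengths) == 10  # element 2 of the sort
        assert derive_window_size(lengths) == 9  # even -> decrement

    def test_defaults(self):
        assert DEFAULT_WS == {"rna": 55, "dna": 21, "protein": 33}

    def test_empty_error(self):
        with pytest.raises(ValueError):
            derive_window_size([])

    def test_oracle_and_properties(self, rng):
        for _ in range(100):
            lengths = rng.integers(4, 120, size=int(rng.integers(1, 40))).tolist()
            ws = derive_window_size(lengths)
            expected = nearest_rank_oracle(lengths)
            if expected % 2 == 0:
                expected -= 1
            assert ws == max(expected, 5)
            assert ws >= 5 and ws % 2 == 1

    def test_monotone_in_single_increase(self, rng):
        lengths = rng.integers(6, 60, size=15).tolist()
        base = derive_window_size(lengths)
        for i in range(len(lengths)):
            bumped = list(lengths)
            bumped[i] += 5
            assert derive_window_size(bumped) >= base


def contrast_oracle(v, pos, spec):
    """Explicit index-set enumeration."""
    n = len(v)
    h, m, r = spec.half, spec.near_count, spec.remote_count_per_side
    lo = pos - m // 2 if m % 2 == 1 else pos - (m // 2 - 1)
    near_idx = [i for i in range(lo, lo + m) if 0 <= i < n]
    remote_idx = [i for i in range(pos - h, pos - h + r) if 0 <= i < n]
    remote_idx += [i for i in range(pos + h - r + 1, pos + h + 1) if 0 <= i < n]
    if not remote_idx:
        return 0.0
    return np.mean([v[i] for i in near_idx]) - np.mean([v[i] for i in remote_idx])


class TestContrastFeature:
    def test_constant_vector(self):
        spec = WindowSpec("dna", 21)
        v = np.full(60, 3.7)
        for pos in range(60):
            assert contrast_feature(v, pos, spec) == pytest.approx(0.0)

    def test_forced_unit_contrast(self):
        spec = WindowSpec("dna", 21)
        v = np.zeros(100)
        pos = 50
        m = spec.near_count
        lo = pos - m // 2 if m % 2 == 1 else pos - (m // 2 - 1)
        v[lo : lo + m] = 1.0  # near all 1, remote stays 0
        assert contrast_feature(v, pos, spec) == pytest.approx(1.0)

    def test_linear_ramp_oracle(self):
        spec = WindowSpec("dna", 21)
        v = np.arange(100, dtype=float)
        assert contrast_feature(v, 50, spec) == pytest.approx(
            contrast_oracle(v, 50, spec)
        )

    def test_translation_equivariance(self, rng):
        spec = WindowSpec("dna", 9)
        v = rng.random(60)
        shifted = np.concatenate([rng.random(5), v])
        for pos in range(10, 50):
            assert contrast_feature(v, pos, spec) == pytest.approx(
                contrast_feature(shifted, pos + 5, spec)
            )

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            contrast_feature(np.zeros(5), 9, WindowSpec("dna", 5))

    @pytest.mark.parametrize("ws", [5, 9, 21, 33, 55])
    def test_vectorized_matches_scalar(self, rng, ws):
        spec = WindowSpec("rna", ws)
        v = rng.random(80)
        vec = contrast_vector(v, spec)
        for pos in range(80):
            assert vec[pos] == pytest.approx(contrast_feature(v, pos, spec), abs=1e-12)

    def test_scalar_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            ws = int(rng.choice([5, 9, 21, 55]))
            spec = WindowSpec("rna", ws)
            n = int(rng.integers(3, 70))
            v = rng.random(n)
            pos = int(rng.integers(n))
            assert contrast_feature(v, pos, spec) == pytest.approx(
                contrast_oracle(v, pos, spec), abs=1e-12
            )


class TestWindowSpec:
    def test_geometry(self):
        spec = WindowSpec("rna", 55)
        assert spec.near_count == 27
        assert spec.remote_count_per_side == 13  # floor((55-1)/4)

    def test_invalid_ws(self):
        with pytest.raises(ValueError):
            WindowSpec("rna", 6)
        with pytest.raises(ValueError):
            WindowSpec("rna", 3)


class TestBuildFeatures:
    def test_constant_channel_zero_contrast(self):
        pm = ProfileMatrix("p", 30)
        pm.add("c1", np.full(30, 0.4))
        fvs = build_features(pm, WindowSpec("dna", 5), ["c1"], ("contrast",))
        np.testing.assert_allclose(fvs.matrix, 0.0, atol=1e-12)

    def test_window_mean_is_frequency(self, rng):
        pm = ProfileMatrix("p", 40)
        indicator = (rng.random(40) < 0.5).astype(float)
        pm.add("ind", indicator)
        spec = WindowSpec("dna", 7)
        fvs = build_features(pm, spec, ["ind"], ("window_mean",))
        h = 3
        for i in range(40):
            lo, hi = max(0, i - h), min(39, i + h)
            assert fvs.matrix[i, 0] == pytest.approx(indicator[lo : hi + 1].mean())

    def test_row_count(self, rng):
        p = random_protein(rng, 37)
        pm = build_profile_matrix(p)
        fvs = build_features(pm, WindowSpec("protein", 33))
        assert fvs.matrix.shape[0] == 37
        assert fvs.matrix.shape[1] == 2 * len(pm.channels)

    def test_unknown_channel(self):
        pm = ProfileMatrix("p", 10)
        with pytest.raises(KeyError):
            build_features(pm, WindowSpec("dna", 5), ["ghost"])

    def test_window_mean_oracle(self, rng):
        spec = WindowSpec("dna", 9)
        v = rng.random(50)
        out = window_mean_vector(v, spec)
        for i in range(50):
            lo, hi = max(0, i - 4), min(49, i + 4)
            assert out[i] == pytest.approx(v[lo : hi + 1].mean())


def auc_pair_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def make_fvs(matrix, labels, ids=None):
    n, k = matrix.shape
    return FeatureVectorSet(
        [f"f{j}" for j in range(k)], matrix, np.asarray(labels, dtype=bool),
        np.repeat("p0", n) if ids is None else ids, np.arange(1, n + 1),
    )


class TestSelectFeatures:
    def test_duplicate_column_dropped(self, rng):
        y = rng.random(200) < 0.5
        base = y + rng.normal(0, 0.5, 200)
        m = np.column_stack([base, base.copy()])
        kept = select_features(make_fvs(m, y), 0.55, 0.7)
        assert len(kept) == 1

    def test_label_copy_beats_noise(self, rng):
        y = rng.random(300) < 0.4
        m = np.column_stack([y.astype(float), rng.random(300)])
        kept = select_features(make_fvs(m, y), 0.6, 0.7)
        assert kept == ["f0"]

    def test_none_pass(self, rng, caplog):
        y = rng.random(5000) < 0.5
        m = rng.random((5000, 3))
        with caplog.at_level(logging.WARNING):
            kept = select_features(make_fvs(m, y), 0.99, 0.7)
        assert kept == []
        assert any("relevance" in msg for msg in caplog.messages)

    def test_single_class_error(self, rng):
        m = rng.random((10, 2))
        with pytest.raises(ValueError):
            select_features(make_fvs(m, np.ones(10)))

    def test_column_order_invariance(self, rng):
        y = rng.random(300) < 0.4
        m = rng.normal(size=(300, 6)) + y[:, None] * rng.random(6)
        fvs = make_fvs(m, y)
        perm = [4, 2, 0, 5, 1, 3]
        fvs_p = FeatureVectorSet(
            [fvs.feature_ids[j] for j in perm], m[:, perm], fvs.labels,
            fvs.protein_ids, fvs.positions,
        )
        # ordering is by (relevance, id), so the result is identical, not
        # merely equal as a set
        assert select_features(fvs) == select_features(fvs_p)
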