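"""Colocalization: background subtraction, masks, Mander's, PCC, TOS."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroagg import (
    ColocParams,
    ImagePair,
    ImagePairSpec,
    colocalize,
    gen_image_pair,
    manders,
    pearson,
    signal_masks,
    subtract_background,
    threshold_overlap_score,
)


class TestSubtractBackground:
    def test_uniform_image_becomes_zero(self):
        out = subtract_background(np.full((64, 64), 37.0))
        assert np.allclose(out, 0.0)

    def test_narrow_peak_is_preserved(self):
        img = np.full((64, 64), 10.0)
        img[30, 30] = 110.0
        out = subtract_background(img, ball_diameter=25)
        assert out[30, 30] >= 0.95 * 100.0

    def test_broad_blob_is_flattened(self):
        yy, xx = np.mgrid[:128, :128]
        blob = 50.0 * np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 40.0**2))
        out = subtract_background(blob, ball_diameter=25)
        assert out.max() < 0.10 * 50.0

    def test_output_non_negative(self):
        rng = np.random.default_rng(0)
        out = subtract_background(rng.uniform(0, 100, (32, 32)))
        assert np.all(out >= 0)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros(10))


class TestSignalMasks:
    def test_fixed_threshold_is_strict(self):
        a = np.array([[0.0, 50.0], [10.0, 50.0]])
        pair = ImagePair(a, a)
        params = ColocParams(mask_method="fixed", fixed_threshold_a=10.0, fixed_threshold_b=10.0)
        ma, mb = signal_masks(pair, params)
        assert np.array_equal(ma, a > 10.0)
        assert not ma[1, 0]  # exactly at threshold is background

    def test_otsu_recovers_bimodal_labels(self):
        spec = ImagePairSpec(shape=(100, 100), n_signal_a=2000, n_signal_b=2000,
                             overlap_fraction=0.5, fg_intensity=200.0, bg_intensity=10.0,
                             noise_sigma=5.0, seed=4)
        pair, truth = gen_image_pair(spec)
        ma, mb = signal_masks(pair, ColocParams(mask_method="otsu"))
        agreement = np.mean(ma == truth.true_mask_a)
        assert agreement >= 0.999

    def test_threshold_above_max_gives_empty_mask(self):
        a = np.full((8, 8), 5.0)
        b = np.arange(64.0).reshape(8, 8)
        params = ColocParams(mask_method="fixed", fixed_threshold_a=100.0, fixed_threshold_b=100.0)
        ma, mb = signal_masks(ImagePair(a, b), params)
        assert not ma.any() and not mb.any()

    def test_otsu_on_constant_channel_is_error(self):
        pair = ImagePair(np.full((8, 8), 5.0), np.arange(64.0).reshape(8, 8))
        with pytest.raises(ValueError):
            signal_masks(pair, ColocParams(mask_method="otsu"))

    def test_fixed_without_thresholds_is_error(self):
        pair = ImagePair(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            signal_masks(pair, ColocParams(mask_method="fixed"))


class TestManders:
    def test_identical_masks(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:5, 2:5] = True
        assert manders(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[:2] = True
        b[5:] = True
        assert manders(a, b) == (0.0, 0.0)

    def test_definition_arithmetic(self):
        a = np.zeros(400, dtype=bool)
        b = np.zeros(400, dtype=bool)
        a[:100] = True
        b[75:275] = True  # overlap 25, |b| = 200
        m1, m2 = manders(a.reshape(20, 20), b.reshape(20, 20))
        assert m1 == pytest.approx(0.25)
        assert m2 == pytest.approx(0.125)

    def test_empty_mask_is_undefined_not_zero(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.ones((5, 5), dtype=bool)
        m1, m2 = manders(a, b)
        assert np.isnan(m1) and m2 == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.random((20, 20)) > 0.6
        b = rng.random((20, 20)) > 0.4
        m1, m2 = manders(a, b)
        m2r, m1r = manders(b, a)
        assert m1 == m1r and m2 == m2r


class TestPearson:
    def test_identical_channels(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, (32, 32))
        assert pearson(ImagePair(a, a)) == pytest.approx(1.0)

    def test_inverted_channels(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 100, (32, 32))
        assert pearson(ImagePair(a, 100.0 - a)) == pytest.approx(-1.0)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 100, (100, 100))
        b = rng.uniform(0, 100, (100, 100))
        assert abs(pearson(ImagePair(a, b))) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 100, (32, 32))
        b = rng.uniform(0, 100, (32, 32))
        p0 = pearson(ImagePair(a, b))
        p1 = pearson(ImagePair(2.5 * a + 7.0, b))
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_constant_channel_undefined(self):
        a = np.full((8, 8), 3.0)
        b = np.arange(64.0).reshape(8, 8)
        assert np.isnan(pearson(ImagePair(a, b)))


def _tos_from_counts(n_ab, n_a, n_b, n_total):
    e = n_a * n_b / n_total
    if n_ab >= e:
        denom = min(n_a, n_b) - e
    else:
        denom = e - max(0, n_a + n_b - n_total)
    return (n_ab - e) / denom if denom else 0.0


class TestThresholdOverlapScore:
    def test_identical_channels_score_one(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 100, (50, 50))
        assert threshold_overlap_score(ImagePair(a, a)) == pytest.approx(1.0)

    def test_maximal_exclusion_scores_minus_one(self):
        # top-10% pixels of the two channels are disjoint by construction
        n = 400
        a = np.zeros(n)
        b = np.zeros(n)
        a[:40] = 100.0
        b[40:80] = 100.0
        pair = ImagePair(a.reshape(20, 20), b.reshape(20, 20))
        assert threshold_overlap_score(pair) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 100, (100, 100))
        b = rng.uniform(0, 100, (100, 100))
        assert abs(threshold_overlap_score(ImagePair(a, b))) < 0.1

    def test_monotone_in_cooccurrence(self):
        # brute force over all feasible co-occurrence counts on a small grid
        n_total, n_a, n_b = 100, 20, 30
        lo = max(0, n_a + n_b - n_total)
        scores = [_tos_from_counts(k, n_a, n_b, n_total) for k in range(lo, min(n_a, n_b) + 1)]
        assert all(s2 >= s1 for s1, s2 in zip(scores, scores[1:]))
        assert scores[0] >= -1.0 - 1e-12 and scores[-1] <= 1.0 + 1e-12

    def test_tiny_fraction_selecting_zero_pixels_is_error(self):
        pair = ImagePair(np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            threshold_overlap_score(pair, ColocParams(top_fraction=0.01))


class TestGeneratorRoundTrip:
    @pytest.mark.parametrize("overlap", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_noiseless_pair_reproduces_truth_exactly(self, overlap):
        spec = ImagePairSpec(shape=(64, 64), n_signal_a=120, n_signal_b=200,
                             overlap_fraction=overlap, noise_sigma=0.0, seed=int(overlap * 10))
        pair, truth = gen_image_pair(spec)
        params = ColocParams(mask_method="fixed", fixed_threshold_a=50.0,
                             fixed_threshold_b=50.0, background_subtract=False)
        ma, mb = signal_masks(pair, params)
        m1, m2 = manders(ma, mb)
        assert m1 == truth.true_M1
        assert m2 == truth.true_M2

    def test_equal_counts_full_overlap_identical_masks(self):
        spec = ImagePairSpec(n_signal_a=150, n_signal_b=150, overlap_fraction=1.0, seed=1)
        pair, truth = gen_image_pair(spec)
        assert truth.true_M1 == truth.true_M2 == 1.0
        assert np.array_equal(truth.true_mask_a, truth.true_mask_b)
        assert np.array_equal(pair.channel_a, pair.channel_b)

    def test_overlap_exceeding_smaller_channel_is_error(self):
        with pytest.raises(ValueError):
            gen_image_pair(ImagePairSpec(n_signal_a=100, n_signal_b=10, overlap_fraction=0.5))

    def test_colocalize_full_chain_on_clean_pair(self):
        spec = ImagePairSpec(shape=(64, 64), n_signal_a=200, n_signal_b=400,
                             overlap_fraction=0.5, noise_sigma=0.0, seed=9)
        pair, truth = gen_image_pair(spec)
        res = colocalize(pair, ColocParams(mask_method="otsu", background_subtract=False))
        assert res.M1 == pytest.approx(truth.true_M1)
        assert res.M2 == pytest.approx(truth.true_M2)
        assert -1.0 <= res.TOS <= 1.0
        assert -1.0 <= res.PCC <= 1.0
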