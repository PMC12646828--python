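"""Multilevel Otsu thresholding and echogenicity partition.

The threshold search is validated against an exhaustive-enumeration
oracle and against scikit-image's independent implementation (on the
achieved between-class variance, since tie-break conventions may differ).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonomyo import (DegenerateHistogramError, EmptyRoiError, GreyHistogram,
                     RoiMask, ThresholdSet, UltrasoundFrame,
                     between_class_variance, generate_transverse_frame,
                     multi_otsu, partition_roi, roi_histogram)


def brute_force_otsu3(counts):
    """Exhaustive search over all (t1, t2) pairs, lexicographic tie-break.

    Maximises the same objective sum_k S_k^2/W_k (equivalent to the
    between-class variance up to a constant).
    """
    c = np.asarray(counts, float)
    lv = np.arange(256.0)
    W = np.concatenate(([0.0], np.cumsum(c)))
    S = np.concatenate(([0.0], np.cumsum(c * lv)))

    def seg(a, b):
        w = W[b] - W[a]
        s = S[b] - S[a]
        return np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)

    t1 = np.arange(1, 255)
    t2 = np.arange(2, 256)
    first = seg(np.zeros_like(t1), t1)
    mid = seg(t1[:, None], t2[None, :])
    last = seg(t2, np.full_like(t2, 256))
    inner = mid + last[None, :]
    inner[t2[None, :] <= t1[:, None]] = -np.inf
    inner_best = inner.max(axis=1)
    total = first + inner_best
    i = int(np.argmax(total))
    j = int(np.argmax(inner[i]))
    return int(t1[i]), int(t2[j])


def random_histogram(rng, n_levels=64):
    counts = np.zeros(256, dtype=np.int64)
    k = rng.integers(3, n_levels + 1)
    levels = rng.choice(n_levels, size=k, replace=False)
    counts[levels] = rng.integers(1, 1000, size=k)
    return counts


class TestRoiHistogram:
    def _frame(self, pixels):
        return UltrasoundFrame(pixels.astype(np.uint8), 0.01, 0.01, "transverse")

    def test_uniform_roi_concentrates_all_mass(self):
        px = np.zeros((64, 64), np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[10:30, 10:35] = True
        px[mask] = 60
        h = roi_histogram(self._frame(px), RoiMask(mask))
        assert h.counts[60] == mask.sum()
        assert h.total == mask.sum()
        assert (np.delete(h.counts, 60) == 0).all()

    def test_single_pixel_roi(self):
        px = np.zeros((64, 64), np.uint8)
        px[5, 5] = 255
        mask = np.zeros((64, 64), bool)
        mask[5, 5] = True
        h = roi_histogram(self._frame(px), RoiMask(mask))
        assert h.counts[255] == 1 and h.total == 1

    def test_noise_free_simulated_histogram_mass_matches_fractions(
            self, small_transverse):
        frame, truth = generate_transverse_frame(
            small_transverse(fractions=(0.5, 0.3, 0.2), speckle=0.0))
        h = roi_histogram(frame, truth.roi)
        n = truth.roi.n_pixels
        for mean, frac in zip((60, 130, 220), (0.5, 0.3, 0.2)):
            assert h.counts[mean] / n == pytest.approx(frac, abs=0.01)

    def test_shape_mismatch_and_empty_mask_raise(self):
        px = np.zeros((64, 64), np.uint8)
        frame = self._frame(px)
        with pytest.raises(Exception):
            roi_histogram(frame, RoiMask(np.ones((64, 65), bool)))


class TestMultiOtsu:
    def test_two_point_histogram_tie_breaks_to_smallest_threshold(self):
        counts = np.zeros(256, np.int64)
        counts[0] = counts[255] = 100
        ts = multi_otsu(GreyHistogram(counts), n_classes=2)
        assert ts.thresholds == (1,)

    def test_three_point_histogram_isolates_each_level(self):
        counts = np.zeros(256, np.int64)
        counts[[10, 120, 240]] = 100
        ts = multi_otsu(GreyHistogram(counts), n_classes=3)
        t1, t2 = ts.thresholds
        assert 10 < t1 <= 120 < t2 <= 240
        assert ts.thresholds == brute_force_otsu3(counts)

    def test_matches_exhaustive_oracle_on_random_histograms(self, rng):
        for _ in range(200):
            counts = random_histogram(rng)
            ts = multi_otsu(GreyHistogram(counts), n_classes=3)
            assert ts.thresholds == brute_force_otsu3(counts)

    def test_matches_scikit_image_between_class_variance(self, rng):
        from skimage.filters import threshold_multiotsu
        for _ in range(50):
            counts = random_histogram(rng, n_levels=256)
            hist = GreyHistogram(counts)
            ours = between_class_variance(hist, multi_otsu(hist, 3))
            sk_t = threshold_multiotsu(hist=(counts, np.arange(256)), classes=3)
            theirs = between_class_variance(
                hist, ThresholdSet(tuple(int(t) + 1 for t in sk_t)))
            assert ours >= theirs - 1e-9 * max(ours, 1.0)
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-9)

    def test_degenerate_histogram_raises(self):
        counts = np.zeros(256, np.int64)
        counts[[3, 200]] = 5
        with pytest.raises(DegenerateHistogramError):
            multi_otsu(GreyHistogram(counts), n_classes=3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(5, 200), st.integers(1, 500)),
                    min_size=4, max_size=12, unique_by=lambda t: t[0]),
           st.integers(1, 50))
    def test_constant_shift_moves_thresholds_exactly(self, level_counts, shift):
        counts = np.zeros(256, np.int64)
        for level, n in level_counts:
            counts[level] = n
        shifted = np.zeros(256, np.int64)
        shifted[shift:] = counts[:256 - shift]
        base = multi_otsu(GreyHistogram(counts), 3).thresholds
        moved = multi_otsu(GreyHistogram(shifted), 3).thresholds
        assert moved == tuple(t + shift for t in base)


class TestPartition:
    def _uniform(self, value, n=400):
        px = np.zeros((64, 64), np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[:20, :20] = True
        px[mask] = value
        return (UltrasoundFrame(px, 0.01, 0.01, "transverse"), RoiMask(mask))

    def test_uniform_roi_below_t1_is_all_low(self):
        frame, roi = self._uniform(10)
        part = partition_roi(frame, roi, ThresholdSet((50, 150)))
        assert (part.mit_pct, part.fatit_pct, part.nmnfit_pct) == (100.0, 0, 0)

    def test_threshold_value_belongs_to_upper_class(self):
        frame, roi = self._uniform(50)
        part = partition_roi(frame, roi, ThresholdSet((50, 150)))
        assert part.fatit_pct == 100.0

    def test_planted_fraction_recovery_with_default_speckle(
            self, small_transverse):
        frame, truth = generate_transverse_frame(
            small_transverse(seed=2, fractions=(0.5, 0.3, 0.2)))
        part = partition_roi(frame, truth.roi,
                             multi_otsu(roi_histogram(frame, truth.roi)))
        assert part.mit_pct == pytest.approx(50, abs=2)
        assert part.fatit_pct == pytest.approx(30, abs=2)
        assert part.nmnfit_pct == pytest.approx(20, abs=2)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_closure_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[8:40, 4:50] = True
        frame = UltrasoundFrame(px, 0.01, 0.01, "transverse")
        ts = multi_otsu(roi_histogram(frame, RoiMask(mask)))
        part = partition_roi(frame, RoiMask(mask), ts)
        assert part.mit_pct + part.fatit_pct + part.nmnfit_pct == \
            pytest.approx(100.0, abs=1e-9)
        # permuting ROI intensities leaves the partition unchanged
        px2 = px.copy()
        vals = px2[mask]
        px2[mask] = rng.permutation(vals)
        frame2 = UltrasoundFrame(px2, 0.01, 0.01, "transverse")
        part2 = partition_roi(frame2, RoiMask(mask), ts)
        assert (part2.mit_pct, part2.fatit_pct, part2.nmnfit_pct) == \
            (part.mit_pct, part.fatit_pct, part.nmnfit_pct)

    def test_whole_roi_shift_preserves_class_fractions(self):
        rng = np.random.default_rng(7)
        px = rng.integers(40, 180, size=(64, 64)).astype(np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[10:50, 10:50] = True
        frame = UltrasoundFrame(px, 0.01, 0.01, "transverse")
        ts = multi_otsu(roi_histogram(frame, RoiMask(mask)))
        part = partition_roi(frame, RoiMask(mask), ts)
        shifted = UltrasoundFrame((px.astype(int) + 40).clip(0, 255
                                                             ).astype(np.uint8),
                                  0.01, 0.01, "transverse")
        ts2 = multi_otsu(roi_histogram(shifted, RoiMask(mask)))
        assert ts2.thresholds == tuple(t + 40 for t in ts.thresholds)
        part2 = partition_roi(shifted, RoiMask(mask), ts2)
        assert part2.mit_pct == part.mit_pct
        assert part2.fatit_pct == part.fatit_pct
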