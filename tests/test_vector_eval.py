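"""Segmentation accuracy and strand-morphology statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vascusr.vector_eval import (
    ConfusionCounts,
    Strand,
    cdf_pearson_r2,
    confusion,
    ecdf,
    ecdf_at,
    ks_two_sample,
    peak_accuracy_sweep,
    strand_metrics,
    strand_table,
    threshold_segment,
    weighted_accuracy,
)


class TestThresholdAndConfusion:
    def test_threshold_extremes(self, rng):
        img = rng.integers(0, 256, (3, 8, 8))
        assert threshold_segment(img, 0).all()
        assert not threshold_segment(img, 256).any()

    def test_two_level_image_separates_exactly(self):
        img = np.where(np.arange(16).reshape(4, 4) % 2 == 0, 0, 200)
        assert np.array_equal(threshold_segment(img, 100), img == 200)

    def test_perfect_and_inverted_predictions(self, rng):
        truth = rng.random((4, 4)) > 0.5
        c = confusion(truth, truth)
        assert c.fp == 0 and c.fn == 0
        c = confusion(~truth, truth)
        assert c.tp == 0 and c.tn == 0

    def test_hand_counted_toy(self):
        pred = np.array([1, 1, 0, 0], bool)
        truth = np.array([1, 0, 1, 0], bool)
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        assert c.total == 4


class TestWeightedAccuracy:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,expected",
        [
            (10, 0, 90, 0, 1.0),  # perfect
            (0, 10, 90, 0, 0.9),  # sensitivity 0, specificity 1
            (5, 5, 90, 0, 0.95),  # sensitivity 0.5
        ],
    )
    def test_weighting(self, tp, fn, tn, fp, expected):
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        assert weighted_accuracy(c) == pytest.approx(expected)

    def test_balanced_weights_give_balanced_accuracy(self):
        c = ConfusionCounts(tp=8, fn=2, tn=70, fp=20)
        bal = 0.5 * (8 / 10) + 0.5 * (70 / 90)
        assert weighted_accuracy(c, 0.5, 0.5) == pytest.approx(bal)

    def test_empty_class_rejected(self):
        c = ConfusionCounts(tp=0, fn=0, tn=5, fp=0)
        with pytest.raises(ValueError):
            weighted_accuracy(c)


class TestAccuracySweep:
    def test_noiseless_two_level_image_peaks_at_one(self):
        truth = np.zeros((4, 4), bool)
        truth[:2] = True
        img = np.where(truth, 200, 10)
        t, acc, curve = peak_accuracy_sweep(img, truth, thresholds=np.arange(256))
        assert acc == 1.0
        assert t == 11  # lowest separating threshold

    def test_truth_as_image_grid_01(self):
        truth = np.array([[1, 0], [0, 1]], bool)
        t, acc, _ = peak_accuracy_sweep(
            truth.astype(float), truth, thresholds=np.array([0.0, 1.0])
        )
        assert (t, acc) == (1.0, 1.0)

    def test_curve_deterministic(self, rng):
        img = rng.random((4, 8, 8))
        truth = rng.random((4, 8, 8)) > 0.9
        r1 = peak_accuracy_sweep(img, truth)
        r2 = peak_accuracy_sweep(img, truth)
        assert r1[0] == r2[0] and r1[1] == r2[1]
        assert np.array_equal(
            r1[2]["weighted_accuracy"], r2[2]["weighted_accuracy"]
        )


class TestStrandMetrics:
    def test_straight_axial_strand(self):
        s = Strand([[0, 0, 0], [10, 0, 0], [20, 0, 0]], [2.0, 2.0, 2.0])
        m = strand_metrics(s)
        assert m["length_um"] == pytest.approx(20.0)
        assert m["z_direction"] == pytest.approx(1.0)
        assert m["inverse_tortuosity"] == pytest.approx(1.0)
        assert m["mean_radius_um"] == pytest.approx(2.0)

    def test_in_plane_strand_has_zero_z_direction(self):
        s = Strand([[0, 0, 0], [0, 3, 4]], [1.0, 1.0])
        m = strand_metrics(s)
        assert m["z_direction"] == 0.0
        assert m["length_um"] == pytest.approx(5.0)

    def test_semicircle_inverse_tortuosity(self):
        theta = np.linspace(0, np.pi, 2001)
        r = 10.0
        pts = np.stack([np.zeros_like(theta), r * np.sin(theta), r * np.cos(theta)], 1)
        s = Strand(pts, np.full(theta.size, 1.0))
        m = strand_metrics(s)
        assert m["inverse_tortuosity"] == pytest.approx(2 / np.pi, abs=1e-5)

    def test_length_weighted_mean_radius(self):
        # two segments of lengths 1 and 3 with segment-mean radii 1.5, 2.5
        s = Strand([[0, 0, 0], [0, 0, 1], [0, 0, 4]], [1.0, 2.0, 3.0])
        m = strand_metrics(s)
        assert m["mean_radius_um"] == pytest.approx((1.5 * 1 + 2.5 * 3) / 4)

    def test_degenerate_strands_rejected(self):
        with pytest.raises(ValueError):
            Strand([[0, 0, 0]], [1.0])
        with pytest.raises(ValueError):
            Strand([[0, 0, 0], [0, 0, 0]], [1.0, 1.0])
        with pytest.raises(ValueError):
            Strand([[0, 0, 0], [0, 0, 1]], [1.0, -1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_inverse_tortuosity_at_most_one(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 12))
        pts = np.cumsum(r.normal(0, 1, (n, 3)) + 0.1, axis=0)
        strand = Strand(pts, r.uniform(0.5, 3.0, n))
        m = strand_metrics(strand)
        assert m["inverse_tortuosity"] <= 1.0 + 1e-12

    def test_table_columns(self):
        s = Strand([[0, 0, 0], [5, 0, 0]], [1.0, 1.0])
        df = strand_table([s, s])
        assert list(df.columns) == [
            "strand_id",
            "length_um",
            "mean_radius_um",
            "z_direction",
            "inverse_tortuosity",
        ]
        assert len(df) == 2


class TestEcdf:
    def test_single_value_step(self):
        support, frac = ecdf([3.0])
        assert support.tolist() == [3.0]
        assert frac.tolist() == [1.0]

    def test_fraction_at_interior_point(self):
        assert ecdf_at([1, 2, 3], [2.0])[0] == pytest.approx(2 / 3)

    def test_duplicates(self):
        assert ecdf_at([1, 1, 2], [1.0])[0] == pytest.approx(2 / 3)
        support, frac = ecdf([1, 1, 2])
        assert support.tolist() == [1.0, 2.0]
        assert frac.tolist() == [2 / 3, 1.0]

    def test_final_value_one(self, rng):
        _, frac = ecdf(rng.random(17))
        assert frac[-1] == 1.0


class TestCdfPearson:
    def test_identical_samples_give_one(self, rng):
        a = rng.random(30)
        assert cdf_pearson_r2(a, a) == pytest.approx(1.0)

    def test_two_linear_cdfs_correlate_despite_shift(self, rng):
        # uniform samples on overlapping ranges: r^2 stays high even though
        # the distributions differ -- the documented blind spot of this
        # statistic (K-S is used alongside it)
        a = rng.uniform(0, 1, 2000)
        b = rng.uniform(0.3, 1.3, 2000)
        assert cdf_pearson_r2(a, b) > 0.9

    def test_hand_computed_grid(self):
        a = np.array([1.0, 2.0])
        b = np.array([2.0, 4.0])
        grid = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fa = np.array([0.0, 0.5, 1.0, 1.0, 1.0])
        fb = np.array([0.0, 0.0, 0.5, 0.5, 1.0])
        expected = np.corrcoef(fa, fb)[0, 1] ** 2
        assert cdf_pearson_r2(a, b, grid=grid) == pytest.approx(expected, abs=1e-12)

    def test_constant_cdf_rejected(self):
        with pytest.raises(ValueError):
            cdf_pearson_r2(np.array([1.0]), np.array([1.0]), grid=np.array([5.0]))


class TestKsTwoSample:
    def test_identical_samples_zero_statistic(self, rng):
        a = rng.random(20)
        d, _ = ks_two_sample(a, a)
        assert d == 0.0

    def test_disjoint_samples_statistic_one(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0])
        assert d == 1.0
        # exact small-sample p: 2 extreme assignments out of C(5,2)=10
        assert p == pytest.approx(0.2)

    def test_hand_computed_overlap(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [3, 4, 5, 6])
        assert d == pytest.approx(0.5)

    def test_brute_force_oracle_on_small_samples(self, rng):
        for _ in range(10):
            a = rng.random(6)
            b = rng.random(8)
            d, _ = ks_two_sample(a, b)
            grid = np.union1d(a, b)
            brute = np.max(np.abs(ecdf_at(a, grid) - ecdf_at(b, grid)))
            assert d == pytest.approx(brute, abs=1e-12)

    def test_invariance_under_monotone_transform(self, rng):
        a, b = rng.random(15), rng.random(12)
        d1, _ = ks_two_sample(a, b)
        d2, _ = ks_two_sample(np.exp(3 * a), np.exp(3 * b))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])
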