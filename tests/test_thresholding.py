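import math

import numpy as np
import pytest

from mulchres import (
    DegenerateHistogramError,
    DegeneratePlaneError,
    GrayHistogram,
    InputError,
    SaturationPlane,
    class_statistics,
    local_entropy_threshold,
    manual_threshold,
    otsu_threshold,
    ridler_calvard_threshold,
    shannon_entropy,
)

from conftest import random_histogram


def spike_histogram(spec: dict[int, int]) -> GrayHistogram:
    counts = np.zeros(256, dtype=np.int64)
    for b, c in spec.items():
        counts[b] = c
    return GrayHistogram(counts)


def brute_force_class_stats(counts, t_bin):
    """Independent per-bin summation oracle for the two-class statistics."""
    total = counts.sum()
    lo = [(k, c) for k, c in enumerate(counts) if k <= t_bin and c > 0]
    hi = [(k, c) for k, c in enumerate(counts) if k > t_bin and c > 0]
    w0 = sum(c for _, c in lo) / total
    w1 = sum(c for _, c in hi) / total
    m1 = sum(k * c for k, c in lo) / sum(c for _, c in lo) if lo else math.nan
    m2 = sum(k * c for k, c in hi) / sum(c for _, c in hi) if hi else math.nan
    sb2 = w0 * w1 * (m1 - m2) ** 2 if lo and hi else 0.0
    return w0, w1, m1, m2, sb2


class TestClassStatistics:
    def test_single_class_split(self):
        cs = class_statistics(spike_histogram({100: 10}), 50)
        assert cs.omega0 == 0.0
        assert cs.sigma_b2 == 0.0
        assert cs.empty_class

    def test_balanced_two_spike_split(self):
        cs = class_statistics(spike_histogram({64: 5, 192: 5}), 128)
        assert cs.omega0 == cs.omega1 == 0.5
        assert cs.m1 == 64 and cs.m2 == 192

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            hist = random_histogram(rng)
            t_bin = int(rng.integers(0, 256))
            cs = class_statistics(hist, t_bin)
            w0, w1, m1, m2, sb2 = brute_force_class_stats(hist.counts, t_bin)
            assert cs.omega0 == pytest.approx(w0, abs=1e-12)
            assert cs.omega1 == pytest.approx(w1, abs=1e-12)
            if not cs.empty_class:
                assert cs.m1 == pytest.approx(m1, rel=1e-12)
                assert cs.m2 == pytest.approx(m2, rel=1e-12)
            assert cs.sigma_b2 == pytest.approx(sb2, rel=1e-9, abs=1e-9)

    def test_variance_decomposition_at_every_split(self, rng):
        hist = random_histogram(rng)
        p = hist.probabilities
        k = np.arange(256)
        mu = (p * k).sum()
        total_var = (p * (k - mu) ** 2).sum()
        for t_bin in range(256):
            cs = class_statistics(hist, t_bin)
            assert cs.sigma_b2 + cs.sigma_w2 == pytest.approx(total_var, abs=1e-9)

    def test_empty_histogram_rejected(self):
        with pytest.raises(InputError):
            class_statistics(GrayHistogram(np.zeros(256, dtype=np.int64)), 100)


class TestOtsu:
    def test_plateau_tie_broken_to_floored_mean(self):
        res = otsu_threshold(spike_histogram({64: 50, 192: 50}))
        assert res.t_bin == 127  # plateau 64..191, floor of its mean
        assert res.t == 127 / 255
        assert res.objective == pytest.approx(0.25 * 128**2)

    def test_matches_exhaustive_search_oracle(self, rng):
        for _ in range(100):
            hist = random_histogram(rng)
            res = otsu_threshold(hist)
            sb2 = [class_statistics(hist, t).sigma_b2 for t in range(256)]
            best = max(sb2)
            plateau = [t for t, v in enumerate(sb2) if v == pytest.approx(best, rel=1e-12)]
            assert res.t_bin in range(plateau[0], plateau[-1] + 1)
            assert res.objective == pytest.approx(best, rel=1e-9)

    def test_unbalanced_two_spike(self):
        hist = spike_histogram({10: 900, 200: 100})
        res = otsu_threshold(hist)
        sb2 = [class_statistics(hist, t).sigma_b2 for t in range(256)]
        assert res.objective == pytest.approx(max(sb2), rel=1e-12)
        assert res.objective == pytest.approx(0.9 * 0.1 * (200 - 10) ** 2)

    def test_mean_property_at_selected_threshold(self, rng):
        # the optimal split sits at the average of the two class means;
        # stated for dense histograms (as on field images), where the
        # maximizer is unique — sparse spike histograms have wide
        # maximizing plateaus on which any split is optimal
        for _ in range(25):
            counts = rng.integers(1, 50, 256)
            counts[rng.integers(30, 100)] += 2000
            counts[rng.integers(150, 230)] += 2000
            hist = GrayHistogram(counts.astype(np.int64))
            res = otsu_threshold(hist)
            cs = class_statistics(hist, res.t_bin)
            assert abs(res.t_bin - 0.5 * (cs.m1 + cs.m2)) <= 1.0

    def test_single_bin_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(spike_histogram({42: 1000}))


class TestRidlerCalvard:
    def test_two_spike_fixed_point(self):
        res = ridler_calvard_threshold(spike_histogram({64: 50, 192: 50}))
        assert res.t == pytest.approx(128 / 255, abs=1e-12)
        assert res.iterations >= 1

    def test_symmetric_bimodal_centers(self):
        counts = np.zeros(256, dtype=np.int64)
        for offset, c in [(0, 100), (1, 60), (2, 20), (-1, 60), (-2, 20)]:
            counts[60 + offset] += c
            counts[180 + offset] += c
        res = ridler_calvard_threshold(GrayHistogram(counts))
        assert res.t * 255 == pytest.approx(120.0, abs=0.5)

    def test_fixed_point_self_consistency(self, rng):
        for _ in range(30):
            hist = random_histogram(rng)
            res = ridler_calvard_threshold(hist)
            t_bins = res.t * 255
            p = hist.probabilities
            k = np.arange(256)
            lo = k <= t_bins
            m1 = (p[lo] * k[lo]).sum() / p[lo].sum()
            m2 = (p[~lo] * k[~lo]).sum() / p[~lo].sum()
            assert abs(t_bins - 0.5 * (m1 + m2)) < 0.5  # half a bin

    def test_close_to_otsu_for_equal_variance_classes(self, rng):
        # two equally spread modes: the isodata and the variance-optimal
        # splits should agree to within one bin
        counts = np.zeros(256, dtype=np.int64)
        for center in (70, 190):
            for off in range(-6, 7):
                counts[center + off] += 100 - 10 * abs(off)
        hist = GrayHistogram(counts)
        rc = ridler_calvard_threshold(hist)
        ot = otsu_threshold(hist)
        assert abs(rc.t * 255 - ot.t_bin) <= 1.0

    def test_single_bin_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            ridler_calvard_threshold(spike_histogram({0: 7}))


def oracle_quadrant_entropy(pairs, t_bin):
    """Independent scan oracle: renormalized BB + FF quadrant entropies."""
    from collections import Counter

    counts = Counter(pairs)
    total = sum(counts.values())
    H = 0.0
    for pred in (
        lambda i, j: i <= t_bin and j <= t_bin,
        lambda i, j: i > t_bin and j > t_bin,
    ):
        cells = [c for (i, j), c in counts.items() if pred(i, j)]
        mass = sum(cells) / total
        if mass > 0:
            H += -sum(
                (c / total / mass) * math.log2(c / total / mass) for c in cells
            )
    return H


class TestLocalEntropy:
    def test_constant_plane_rejected(self):
        with pytest.raises(DegeneratePlaneError):
            local_entropy_threshold(SaturationPlane(np.full((8, 8), 0.5)))

    def _pairs(self, q):
        pairs = []
        m, n = q.shape
        for i in range(m):
            for j in range(n):
                if j + 1 < n:
                    pairs.append((q[i, j], q[i, j + 1]))
                if i + 1 < m:
                    pairs.append((q[i, j], q[i + 1, j]))
        return pairs

    def test_matches_exhaustive_scan_oracle(self, rng):
        values = rng.choice([50 / 255, 90 / 255, 200 / 255, 230 / 255], size=(12, 16))
        plane = SaturationPlane(values)
        res = local_entropy_threshold(plane)
        q = plane.quantized()
        curve = [oracle_quadrant_entropy(self._pairs(q), t) for t in range(256)]
        best = max(curve)
        assert curve[res.t_bin] == pytest.approx(best, abs=1e-9)
        assert res.objective == pytest.approx(best, abs=1e-9)

    def test_two_region_plane_matches_oracle(self):
        values = np.where(np.arange(16)[None, :] < 8, 50 / 255, 200 / 255)
        plane = SaturationPlane(np.broadcast_to(values, (10, 16)).copy())
        res = local_entropy_threshold(plane)
        q = plane.quantized()
        curve = [oracle_quadrant_entropy(self._pairs(q), t) for t in range(256)]
        assert curve[res.t_bin] == pytest.approx(max(curve), abs=1e-12)

    def test_invariant_to_swapping_sides(self):
        left_low = np.where(np.arange(16)[None, :] < 8, 50 / 255, 200 / 255)
        left_high = np.where(np.arange(16)[None, :] < 8, 200 / 255, 50 / 255)
        res_a = local_entropy_threshold(
            SaturationPlane(np.broadcast_to(left_low, (10, 16)).copy())
        )
        res_b = local_entropy_threshold(
            SaturationPlane(np.broadcast_to(left_high, (10, 16)).copy())
        )
        assert res_a.t_bin == res_b.t_bin

    def test_first_order_variant_runs(self, rng):
        values = rng.choice([0.2, 0.6], size=(16, 16))
        res = local_entropy_threshold(SaturationPlane(values), variant="first_order")
        assert 0 <= res.t_bin <= 255


class TestManualAndEntropy:
    def test_manual_wraps_value(self):
        res = manual_threshold(0.2499)
        assert res.method == "MT" and res.t == 0.2499

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_manual_out_of_range(self, bad):
        with pytest.raises(InputError):
            manual_threshold(bad)

    @pytest.mark.parametrize(
        "spec,expected",
        [
            ({k: 1 for k in range(256)}, 8.0),  # uniform
            ({10: 99}, 0.0),  # single bin
            ({0: 5, 255: 5}, 1.0),  # two equal bins
        ],
    )
    def test_known_entropies(self, spec, expected):
        assert shannon_entropy(spike_histogram(spec)).H == pytest.approx(expected)

    def test_entropy_bounds(self, rng):
        for _ in range(50):
            H = shannon_entropy(random_histogram(rng)).H
            assert 0.0 <= H <= 8.0
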