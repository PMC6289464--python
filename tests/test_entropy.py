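"""Histogram, Gaussian prior, relative-entropy curves and thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entropymap.entropy import (
    GreyHistogram,
    auto_min_run,
    binarize,
    entropy_analysis,
    find_g0,
    find_g1,
    grey_histogram,
)
from entropymap.errors import DegenerateHistogramError, WorkflowError
from entropymap.grey import GreyImage


# ---------------------------------------------------------------- oracles


def loop_entropy_analysis(counts):
    """Independent scalar-loop evaluation of the histogram statistics.

    Pure-python re-derivation: mean, variance (P-1 denominator),
    Gaussian prior with total count P, R = ln(H/G) on occupied bins,
    q = (1/P) sum R*H.
    """
    p = sum(counts)
    g_mean = sum(g * counts[g] for g in range(256)) / p
    sigma2 = sum((g - g_mean) ** 2 * counts[g] for g in range(256)) / (p - 1)
    gauss = [
        p / math.sqrt(2 * math.pi * sigma2) * math.exp(-((g - g_mean) ** 2) / (2 * sigma2))
        for g in range(256)
    ]
    rel = [
        math.log(counts[g] / gauss[g]) if counts[g] > 0 else 0.0 for g in range(256)
    ]
    q = sum(rel[g] * counts[g] for g in range(256)) / p
    return g_mean, sigma2, gauss, rel, q


def scan_g0(counts, rel, g_mean, min_run):
    """Exhaustive scan oracle for g0 over all 256 levels.

    First run of >= min_run consecutive occupied positive bins above
    the mean, skipping the positive run contiguous with the mean.
    """
    good = [counts[g] > 0 and rel[g] > 0 for g in range(256)]
    g = math.floor(g_mean) + 1
    while g < 256 and good[g]:
        g += 1
    while g <= 256 - min_run:
        if all(good[g + i] for i in range(min_run)):
            return g - 1
        g += 1
    return None


def make_hist(counts):
    return GreyHistogram(np.asarray(counts, dtype=np.int64))


def gaussian_counts(n, mean, sd):
    """Deterministic discretized-Gaussian histogram with ~n pixels."""
    from scipy.stats import norm

    g = np.arange(256)
    return np.round(n * (norm.cdf(g + 0.5, mean, sd) - norm.cdf(g - 0.5, mean, sd))).astype(int)


# ------------------------------------------------------------- histogram


class TestHistogram:
    def test_counting(self):
        img = GreyImage(np.array([[0, 0], [255, 255]], dtype=np.uint8))
        hist = grey_histogram(img)
        assert hist.counts[0] == 2 and hist.counts[255] == 2
        assert hist.counts.sum() == 4 == hist.total

    def test_matches_counting_loop(self, rng):
        levels = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        hist = grey_histogram(GreyImage(levels))
        expect = [0] * 256
        for v in levels.ravel():
            expect[int(v)] += 1
        assert hist.counts.tolist() == expect
        assert hist.total == 32 * 32


# -------------------------------------------------------------- analysis


class TestEntropyAnalysis:
    def test_two_level_histogram_worked_example(self):
        # pixels at levels {0, 0, 1, 1}
        counts = [0] * 256
        counts[0] = counts[1] = 2
        an = entropy_analysis(make_hist(counts))
        g_mean, sigma2, gauss, rel, q = loop_entropy_analysis(counts)
        assert an.g_mean == pytest.approx(0.5) == pytest.approx(g_mean)
        assert an.sigma2 == pytest.approx(1.0 / 3.0) == pytest.approx(sigma2)
        assert an.gaussian[0] == pytest.approx(gauss[0], rel=1e-12)
        assert an.gaussian[0] == pytest.approx(1.900, abs=5e-4)
        assert an.rel_entropy[0] == pytest.approx(math.log(2 / gauss[0]), rel=1e-12)
        assert an.q == pytest.approx(q, rel=1e-12)
        assert an.q == pytest.approx(0.051, abs=5e-4)

    def test_matches_scalar_loop_on_random_images(self, rng):
        for _ in range(10):
            levels = rng.integers(0, 256, (32, 32), dtype=np.uint8)
            an = entropy_analysis(grey_histogram(GreyImage(levels)))
            g_mean, sigma2, gauss, rel, q = loop_entropy_analysis(an.hist.counts.tolist())
            assert an.g_mean == pytest.approx(g_mean, rel=1e-10)
            assert an.sigma2 == pytest.approx(sigma2, rel=1e-10)
            np.testing.assert_allclose(an.gaussian, gauss, rtol=1e-10)
            np.testing.assert_allclose(an.rel_entropy, rel, rtol=1e-10, atol=1e-10)
            assert an.q == pytest.approx(q, rel=1e-10, abs=1e-12)

    def test_gaussian_prior_symmetric_about_mean(self):
        counts = [0] * 256
        for g, n in ((96, 10), (112, 40), (128, 80), (144, 40), (160, 10)):
            counts[g] = n
        an = entropy_analysis(make_hist(counts))
        assert an.g_mean == pytest.approx(128.0)
        for k in (1, 5, 20, 50):
            assert an.gaussian[128 - k] == pytest.approx(an.gaussian[128 + k], rel=1e-12)

    def test_histogram_equal_to_prior_gives_near_zero_entropy(self):
        # self-consistency: H = G rounded to counts -> R ~ 0, q ~ 0
        counts = gaussian_counts(100000, 128, 20)
        an = entropy_analysis(make_hist(counts))
        occupied = an.hist.counts > 20  # rounding noise dominates sparse bins
        assert np.abs(an.rel_entropy[occupied]).max() < 0.05
        assert abs(an.q) < 0.01

    def test_sign_law(self, rng):
        for _ in range(5):
            levels = rng.integers(0, 256, (32, 32), dtype=np.uint8)
            an = entropy_analysis(grey_histogram(GreyImage(levels)))
            h = an.hist.counts
            occ = h > 0
            assert np.all(np.sign(an.rel_entropy[occ]) == np.sign(h[occ] - an.gaussian[occ]))

    def test_prior_mass_conserved(self):
        # sum G(g) ~ P within 1% for sigma2 >= 4 with the mean inside the range
        for sd in (2.0, 5.0, 20.0):
            counts = gaussian_counts(50000, 120, sd)
            an = entropy_analysis(make_hist(counts))
            assert an.gaussian.sum() == pytest.approx(an.hist.total, rel=0.01)

    def test_degenerate_histograms_raise(self):
        single = [0] * 256
        single[7] = 100
        with pytest.raises(DegenerateHistogramError):
            entropy_analysis(make_hist(single))
        one_pixel = [0] * 256
        one_pixel[7] = 1
        with pytest.raises(DegenerateHistogramError):
            entropy_analysis(make_hist(one_pixel))


# ------------------------------------------------------------ thresholds


def example_histogram():
    """Bulk Gaussian (1000 px at mean 50, sd 10) + 30 px over 200-210."""
    counts = gaussian_counts(1000, 50, 10)
    for g in range(200, 211):
        counts[g] += 3 if g % 2 else 2
    return counts


class TestFindG0:
    def test_noise_prior_histogram_has_no_threshold(self):
        counts = gaussian_counts(100000, 128, 20)
        an = entropy_analysis(make_hist(counts))
        assert find_g0(an) is None

    def test_bright_group_detected_just_below_its_onset(self):
        counts = example_histogram()
        an = entropy_analysis(make_hist(counts))
        g_mean, _, _, rel, _ = loop_entropy_analysis(list(counts))
        for min_run in (1, 2, 5):
            expect = scan_g0(list(counts), rel, g_mean, min_run)
            assert find_g0(an, min_run=min_run) == expect
        assert find_g0(an, min_run=1) == 199

    def test_isolated_spurious_bin_skipped_with_min_run(self):
        counts = example_histogram()
        counts[120] += 30  # isolated bright bin
        an = entropy_analysis(make_hist(counts))
        g_mean, _, _, rel, _ = loop_entropy_analysis(list(counts))
        assert rel[120] > 0
        assert find_g0(an, min_run=1) == scan_g0(list(counts), rel, g_mean, 1) == 119
        assert find_g0(an, min_run=2) == scan_g0(list(counts), rel, g_mean, 2) == 199

    def test_auto_min_run_scales_with_occupancy(self):
        counts = example_histogram()
        an = entropy_analysis(make_hist(counts))
        k = auto_min_run(an)
        n_occ = int(((np.arange(256) > an.g_mean) & (an.hist.counts > 0)).sum())
        assert k == math.ceil(math.log2(n_occ / 0.05))


class TestFindG1:
    def _analysis_with_rh(self, counts):
        return entropy_analysis(make_hist(counts))

    def test_single_peak_ends_at_last_positive_level(self):
        # half-Gaussian bulk at 0 + structure class + far inclusions
        counts = gaussian_counts(40000, 0, 12) + gaussian_counts(6000, 80, 8)
        counts[220:226] += 40
        an = self._analysis_with_rh(counts)
        g0 = find_g0(an)
        assert g0 is not None and g0 < 80
        g1 = find_g1(an, g0)
        rh = an.weighted
        # oracle: last positive level of the first positive run above g0
        a = next(g for g in range(g0 + 1, 256) if rh[g] > 0)
        b = a
        while b < 255 and rh[b + 1] > 0:
            b += 1
        assert g1 == b
        assert 80 < g1 < 220  # inclusions alone satisfy g > g1

    def test_merged_peaks_cut_at_the_dip(self):
        # two positive populations joined by a shallow dip never reaching 0
        counts = gaussian_counts(40000, 0, 10)
        counts += gaussian_counts(8000, 120, 11) + gaussian_counts(6000, 155, 11)
        an = self._analysis_with_rh(counts)
        g0 = find_g0(an)
        rh = an.weighted
        assert (rh[120:156] > 0).all()  # the dip stays positive
        g1 = find_g1(an, g0)
        assert 128 <= g1 <= 148  # the dip's local minimum, not the run end

    def test_error_when_nothing_positive_above_g0(self):
        counts = gaussian_counts(100000, 100, 15)
        an = self._analysis_with_rh(counts)
        with pytest.raises(WorkflowError):
            find_g1(an, 254)

    def test_g1_exceeds_g0(self):
        counts = gaussian_counts(40000, 0, 12) + gaussian_counts(6000, 80, 8)
        an = self._analysis_with_rh(counts)
        g0 = find_g0(an)
        assert find_g1(an, g0) > g0


class TestBinarize:
    def test_max_threshold_gives_all_black(self):
        img = GreyImage(np.arange(256, dtype=np.uint8).reshape(16, 16))
        assert not binarize(img, 255).white.any()

    def test_white_rule_is_strict_inequality(self):
        img = GreyImage(np.array([[0, 64], [128, 255]], dtype=np.uint8))
        assert binarize(img, 100).white.tolist() == [[False, False], [True, True]]
        assert binarize(img, 128).white.tolist() == [[False, False], [False, True]]

    @settings(deadline=None, max_examples=50)
    @given(t=st.integers(0, 255), seed=st.integers(0, 10**6))
    def test_white_count_matches_histogram_tail(self, t, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        img = GreyImage(levels)
        hist = grey_histogram(img)
        assert binarize(img, t).white.sum() == hist.counts[t + 1 :].sum()

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10**6))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        img = GreyImage(rng.integers(0, 256, (16, 16), dtype=np.uint8))
        counts = [binarize(img, t).white.sum() for t in range(0, 256, 17)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
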