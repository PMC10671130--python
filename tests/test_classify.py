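"""Pixel masking, histogramming, deconvolution and shade assignment."""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from dyescan.classify import (
    ACHROMATIC, CHROMATIC, WHITE_DOMAIN, EXCLUDED, SHADE1, SHADE2,
    EmptyHistogramError, Histogram1D, LayerScan, ScanFormatError,
    blue_histogram, classify_pixels, fit_two_gaussians, histogram2d,
    mask_pixels, read_scan, write_scan,
)
from dyescan.synthetic import (
    LBL_SHADE1, LBL_SHADE2, ScanRecipe, generate_scan,
)


def solid_scan(rgb, shape=(4, 4)):
    px = np.tile(np.array(rgb, dtype=np.uint8), (*shape, 1))
    return LayerScan(pixels=px, layer_index=1, n_layers=1)


class TestReadScan:
    def test_bmp_round_trip_preserves_bytes(self, tmp_path):
        px = np.array([[[1, 2, 3], [4, 5, 6]],
                       [[7, 8, 9], [250, 251, 252]]], dtype=np.uint8)
        scan = LayerScan(pixels=px, layer_index=1, n_layers=1)
        path = tmp_path / "tiny.bmp"
        write_scan(scan, path)
        back = read_scan(path, 1, 1)
        assert np.array_equal(back.pixels, px)

    def test_generator_output_round_trips_through_png(self, tmp_path,
                                                      two_shade_scan):
        _, scan, _ = two_shade_scan
        path = tmp_path / "layer.png"
        write_scan(scan, path)
        back = read_scan(path, 1, 1)
        assert np.array_equal(back.pixels, scan.pixels)
        # PNG stores density as pixels/metre, so dpi round-trips approximately
        assert back.dpi == pytest.approx(1200, rel=1e-4)

    def test_grayscale_file_rejected_with_mode_named(self, tmp_path):
        from PIL import Image
        path = tmp_path / "gray.png"
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8), mode="L").save(path)
        with pytest.raises(ScanFormatError, match="'L'"):
            read_scan(path, 1, 1)

    def test_layer_index_bounds_enforced(self):
        with pytest.raises(ValueError):
            LayerScan(pixels=np.zeros((2, 2, 3), dtype=np.uint8),
                      layer_index=3, n_layers=2)


class TestHistogram2D:
    def test_uniform_gray_is_single_diagonal_cell(self):
        h = histogram2d(solid_scan((77, 77, 77)), "R", "B")
        assert h[77, 77] == 16
        assert h.sum() == 16

    def test_two_populations_equal_counts(self):
        px = np.zeros((2, 2, 3), dtype=np.uint8)
        px[:, 0] = (0, 0, 200)
        px[:, 1] = (0, 0, 240)
        scan = LayerScan(pixels=px, layer_index=1, n_layers=1)
        h = histogram2d(scan, "G", "B")
        assert h[0, 200] == 2 and h[0, 240] == 2 and h.sum() == 4

    def test_marginals_match_channel_histograms(self, two_shade_scan):
        _, scan, _ = two_shade_scan
        h = histogram2d(scan, "R", "B")
        red = np.bincount(scan.pixels[..., 0].ravel(), minlength=256)
        blue = np.bincount(scan.pixels[..., 2].ravel(), minlength=256)
        assert np.array_equal(h.sum(axis=1), red)
        assert np.array_equal(h.sum(axis=0), blue)

    def test_identical_channels_rejected(self, two_shade_scan):
        with pytest.raises(ValueError, match="distinct"):
            histogram2d(two_shade_scan[1], "B", "B")


class TestMaskPixels:
    @pytest.mark.parametrize("rgb, expected", [
        ((128, 128, 128), ACHROMATIC),       # mid gray
        ((250, 250, 252), ACHROMATIC),       # near-white, gray rule first
        ((81, 91, 121), CHROMATIC),          # bound-shade color, spread 40
        ((0, 145, 248), CHROMATIC),          # free-shade color
        ((255, 246, 250), WHITE_DOMAIN),     # bright but chromatic enough
    ])
    def test_label_rules(self, rgb, expected):
        mask = mask_pixels(solid_scan(rgb), gray_tol=8, white_floor=245)
        assert (mask.labels == expected).all()

    def test_default_gray_tol_keeps_bound_shade(self):
        mask = mask_pixels(solid_scan((81, 91, 121)), gray_tol=20)
        assert (mask.labels == CHROMATIC).all()

    def test_idempotent_and_order_invariant(self, two_shade_scan):
        _, scan, _ = two_shade_scan
        labels = mask_pixels(scan).labels
        assert np.array_equal(mask_pixels(scan).labels, labels)
        perm = np.random.default_rng(1).permutation(scan.shape[0])
        shuffled = LayerScan(pixels=scan.pixels[perm], layer_index=1,
                             n_layers=1)
        assert np.array_equal(mask_pixels(shuffled).labels, labels[perm])


class TestBlueHistogram:
    def test_no_blue_pixels_raises(self):
        with pytest.raises(EmptyHistogramError):
            scan = solid_scan((200, 0, 0))
            blue_histogram(scan, mask_pixels(scan))

    def test_single_color_fills_one_bin(self):
        scan = solid_scan((0, 145, 248), shape=(10, 10))
        hist = blue_histogram(scan, mask_pixels(scan))
        assert hist.counts[248] == 100
        assert hist.total == 100

    def test_total_matches_generator_bookkeeping(self, two_shade_scan):
        _, scan, labels = two_shade_scan
        hist = blue_histogram(scan, mask_pixels(scan))
        n_shade = ((labels == LBL_SHADE1) | (labels == LBL_SHADE2)).sum()
        assert hist.total == n_shade


def mixture_histogram(mu1, s1, mu2, s2, w1, n, seed):
    rng = np.random.default_rng(seed)
    n1 = rng.binomial(n, w1)
    draws = np.concatenate([rng.normal(mu1, s1, n1),
                            rng.normal(mu2, s2, n - n1)])
    counts = np.bincount(np.clip(np.rint(draws), 0, 255).astype(int),
                         minlength=256)
    return Histogram1D(counts=counts)


class TestFitTwoGaussians:
    def test_recovers_planted_mixture(self):
        hist = mixture_histogram(195, 8, 240, 6, 0.6, 100_000, seed=4)
        fit = fit_two_gaussians(hist)
        assert fit.converged and not fit.degenerate
        assert abs(fit.mu1 - 195) <= 2
        assert abs(fit.mu2 - 240) <= 2
        assert abs(fit.w1 - 0.6) <= 0.03

    def test_two_delta_peaks(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[190] = counts[240] = 200
        fit = fit_two_gaussians(Histogram1D(counts=counts))
        assert fit.mu1 == pytest.approx(190, abs=1e-3)
        assert fit.mu2 == pytest.approx(240, abs=1e-3)
        assert fit.w1 == pytest.approx(0.5, abs=1e-3)

    def test_unimodal_data_flagged_degenerate(self):
        rng = np.random.default_rng(9)
        counts = np.bincount(np.clip(np.rint(rng.normal(200, 8, 50_000)),
                                     0, 255).astype(int), minlength=256)
        with pytest.warns(RuntimeWarning, match="unimodal"):
            fit = fit_two_gaussians(Histogram1D(counts=counts))
        assert fit.degenerate

    def test_refuses_sparse_histograms(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[200] = 99
        with pytest.raises(ValueError, match="100"):
            fit_two_gaussians(Histogram1D(counts=counts))

    def test_deterministic(self):
        hist = mixture_histogram(190, 10, 242, 5, 0.45, 50_000, seed=2)
        f1 = fit_two_gaussians(hist)
        f2 = fit_two_gaussians(hist)
        assert f1 == f2

    def test_parameter_recovery_across_settings(self):
        """Means within +-2 levels across a spread of generator settings."""
        ok = 0
        cases = [(mu1, mu2, s, w)
                 for mu1 in (182, 195, 208)
                 for mu2 in (238, 248)
                 for s in (4, 8, 12)
                 for w in (0.25, 0.5, 0.75)]
        for i, (mu1, mu2, s, w) in enumerate(cases):
            fit = fit_two_gaussians(
                mixture_histogram(mu1, s, mu2, s, w, 100_000, seed=50 + i))
            ok += (abs(fit.mu1 - mu1) <= 2 and abs(fit.mu2 - mu2) <= 2)
        assert ok / len(cases) >= 0.95


class TestClassifyPixels:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted(two_shade_scan):
        _, scan, labels = two_shade_scan
        mask = mask_pixels(scan)
        fit = fit_two_gaussians(blue_histogram(scan, mask))
        return scan, labels, mask, fit

    def test_label_conservation(self, fitted):
        scan, _, mask, fit = fitted
        cm = classify_pixels(scan, mask, fit)
        counts = cm.counts
        assert counts["excluded"] + counts["shade1"] + counts["shade2"] == cm.total

    def test_pixel_at_component_mean_gets_that_shade(self, fitted):
        scan, _, mask, fit = fitted
        b1 = int(round(fit.mu1))
        px = np.tile(np.array([int(0.33 * b1), int(0.37 * b1), b1],
                              dtype=np.uint8), (2, 2, 1))
        s = LayerScan(pixels=px, layer_index=1, n_layers=1)
        cm = classify_pixels(s, mask_pixels(s), fit)
        assert (cm.labels == SHADE1).all()

    def test_posterior_tie_breaks_toward_shade1(self):
        from dyescan.classify import MixtureFit
        fit = MixtureFit(mu1=190.0, mu2=210.0, sigma1=5.0, sigma2=5.0,
                         w1=0.5, w2=0.5, converged=True, n_pixels=1000)
        # blue = 200 is exactly equidistant: posterior tie
        px = np.tile(np.array([66, 74, 200], dtype=np.uint8), (1, 1, 1))
        s = LayerScan(pixels=px, layer_index=1, n_layers=1)
        cm = classify_pixels(s, mask_pixels(s), fit)
        assert cm.labels[0, 0] == SHADE1

    def test_matches_brute_force_posterior(self, fitted):
        scan, _, mask, fit = fitted
        cm = classify_pixels(scan, mask, fit)
        blue = scan.pixels[..., 2].astype(float)
        lp1 = math.log(fit.w1) + norm.logpdf(blue, fit.mu1, fit.sigma1)
        lp2 = math.log(fit.w2) + norm.logpdf(blue, fit.mu2, fit.sigma2)
        oracle = np.where(lp1 >= lp2, SHADE1, SHADE2)
        included = cm.labels != EXCLUDED
        assert included.any()
        assert np.array_equal(cm.labels[included], oracle[included])

    def test_confusion_below_bayes_error_plus_margin(self, fitted):
        scan, labels, mask, fit = fitted
        cm = classify_pixels(scan, mask, fit)
        s1, s2 = labels == LBL_SHADE1, labels == LBL_SHADE2
        confusions = (((cm.labels == SHADE2) & s1).sum()
                      + ((cm.labels == SHADE1) & s2).sum())
        rate = confusions / (s1.sum() + s2.sum())
        # analytic Bayes error of the generating mixture (w1 = .3/.5)
        w1 = 0.6
        diff = lambda b: (w1 * norm.pdf(b, 195, 8)
                          - (1 - w1) * norm.pdf(b, 240, 6))
        bstar = brentq(diff, 200, 239)
        bayes = (w1 * norm.sf(bstar, 195, 8)
                 + (1 - w1) * norm.cdf(bstar, 240, 6))
        assert rate <= bayes + 0.01
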