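"""Cortical intensity profile extraction, alignment, Gaussian-peak
fitting and polarity ratios."""

import math

import numpy as np
import pytest

from neuropol.profilepol import (
    AngularProfile,
    GaussianPeakModel,
    align_and_wrap,
    angular_grid,
    average_profiles,
    extract_profile,
    fit_gaussian_peak,
    normalize_max1,
    polarity_ratio,
    wrapped_difference,
)
from neuropol.synthgen import ProfileConfig, simulate_profile


def ring_image(shape=(101, 101), radius=30.0, width=12.0, intensity=100.0,
               hotspot_deg=None, hotspot_amp=0.0, hotspot_sigma=20.0):
    """Synthetic ring with an optional Gaussian angular hotspot (y-up angles)."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dx = cols - cx
    dy = -(rows - cy)  # y-up
    r = np.hypot(dx, dy)
    img = np.where(np.abs(r - radius) <= width / 2, intensity, 0.0)
    if hotspot_deg is not None:
        ang = np.degrees(np.arctan2(dy, dx))
        delta = wrapped_difference(ang, hotspot_deg)
        img = img * (1.0 + hotspot_amp * np.exp(-delta**2 / (2 * hotspot_sigma**2)))
    return img


def ring_contour(radius=30.0, center=(50.0, 50.0), n=180):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    # contour in image coords: y is the row axis (y-down)
    return np.c_[center[0] + radius * np.cos(t), center[1] - radius * np.sin(t)]


class TestExtract:
    def test_uniform_ring_flat_profile(self):
        img = ring_image()
        prof = extract_profile(img, ring_contour(), thickness=4)
        assert np.max(np.abs(prof.intensity - 100.0)) <= 1.0

    def test_hotspot_angle_recovered(self):
        img = ring_image(hotspot_deg=37.0, hotspot_amp=2.0)
        prof = extract_profile(img, ring_contour(), thickness=4)
        peak = prof.angles[int(np.argmax(prof.intensity))]
        assert abs(wrapped_difference(peak, 37.0)) <= prof.step + 1e-9

    def test_thickness_independent_on_flat_ring(self):
        img = ring_image()
        p1 = extract_profile(img, ring_contour(), thickness=1)
        p4 = extract_profile(img, ring_contour(), thickness=4)
        assert np.allclose(p1.intensity, p4.intensity, atol=1e-9)

    def test_border_contour_rejected(self):
        img = ring_image()
        with pytest.raises(ValueError):
            extract_profile(img, ring_contour(radius=49.5), thickness=4)


class TestAlignWrap:
    def test_max_moved_to_zero(self):
        prof = simulate_profile(ProfileConfig(peak_center=37.0, n_samples=360))
        aligned = align_and_wrap(prof)
        assert aligned.angles[int(np.argmax(aligned.intensity))] == pytest.approx(0.0)
        assert aligned.aligned

    def test_idempotent_and_conserving(self):
        prof = simulate_profile(ProfileConfig(peak_center=-120.0, noise_sd=0.2, seed=4))
        a1 = align_and_wrap(prof)
        a2 = align_and_wrap(a1)
        assert np.array_equal(a1.intensity, a2.intensity)
        assert np.sum(a1.intensity) == pytest.approx(np.sum(prof.intensity))
        assert sorted(a1.intensity) == pytest.approx(sorted(prof.intensity))

    def test_grid_support(self):
        prof = simulate_profile(ProfileConfig(n_samples=360))
        a = align_and_wrap(prof)
        assert a.angles[0] == -179.0 and a.angles[-1] == 180.0

    def test_tied_maxima_flagged(self):
        grid = angular_grid(36)
        inten = np.zeros(36)
        inten[3] = inten[20] = 5.0
        a = align_and_wrap(AngularProfile(grid, inten))
        assert a.warnings


class TestAverageNormalize:
    def test_identical_profiles_sem_zero(self):
        p = simulate_profile(ProfileConfig())
        avg = average_profiles([p, p])
        assert np.allclose(avg.intensity, p.intensity)
        assert np.allclose(avg.sem, 0.0)

    def test_constant_profiles_mean_and_sem(self):
        grid = angular_grid(36)
        p0 = AngularProfile(grid, np.zeros(36))
        p2 = AngularProfile(grid, np.full(36, 2.0))
        avg = average_profiles([p0, p2])
        assert np.allclose(avg.intensity, 1.0)
        assert np.allclose(avg.sem, 1.0)  # sd = sqrt(2), sem = sd/sqrt(2)

    def test_mismatched_grids_rejected(self):
        p1 = simulate_profile(ProfileConfig(n_samples=36))
        p2 = simulate_profile(ProfileConfig(n_samples=72))
        with pytest.raises(ValueError):
            average_profiles([p1, p2])

    def test_normalize_shape_preserved_and_idempotent(self):
        p = simulate_profile(ProfileConfig(amplitude=49.0, baseline=1.0))
        n1 = normalize_max1(p)
        assert np.max(n1.intensity) == pytest.approx(1.0)
        ratio_before = p.intensity[10] / p.intensity[200]
        assert n1.intensity[10] / n1.intensity[200] == pytest.approx(ratio_before)
        n2 = normalize_max1(n1)
        assert np.allclose(n1.intensity, n2.intensity)


class TestGaussianPeakFit:
    def test_noiseless_recovery(self):
        p = simulate_profile(ProfileConfig(amplitude=3.0, peak_center=0.0,
                                           sigma=25.0, baseline=1.0, noise_sd=0.0))
        fit = fit_gaussian_peak(p, n_mc=0)
        assert fit.amplitude == pytest.approx(3.0, rel=1e-6)
        assert fit.sigma == pytest.approx(25.0, rel=1e-6)
        assert fit.baseline == pytest.approx(1.0, rel=1e-6)
        assert abs(fit.center) < 1e-4

    def test_flat_profile_degenerate(self):
        grid = angular_grid(36)
        fit = fit_gaussian_peak(AngularProfile(grid, np.full(36, 2.0)), n_mc=0)
        assert fit.degenerate and fit.amplitude == 0.0

    def test_deterministic_given_seed(self):
        p = simulate_profile(ProfileConfig(noise_sd=0.1, seed=9))
        f1 = fit_gaussian_peak(p, n_mc=20, seed=5)
        f2 = fit_gaussian_peak(p, n_mc=20, seed=5)
        assert f1.param_errors == f2.param_errors

    def test_mc_error_reflects_noise_scale(self):
        p = simulate_profile(ProfileConfig(amplitude=3.0, noise_sd=0.15,
                                           seed=2, n_samples=90))
        fit = fit_gaussian_peak(p, n_mc=50, seed=3)
        assert 0.0 < fit.param_errors["amplitude"] < 1.0

    def test_summary_lists_parameters(self):
        p = simulate_profile(ProfileConfig(noise_sd=0.05, seed=1))
        s = GaussianPeakModel(p).fit(n_mc=5, seed=1).summary()
        for name in ("amplitude", "center", "sigma", "baseline"):
            assert name in s


class TestPolarityRatio:
    def test_flat_profile_ratios_exactly_one(self):
        grid = angular_grid(360)
        p = AngularProfile(grid, np.full(360, 7.0), sem=np.zeros(360), aligned=True)
        r = polarity_ratio(p)
        assert r.ratio_0_over_180 == 1.0
        assert r.ratio_0_over_90 == 1.0
        assert r.err_0_over_180 == 0.0

    def test_two_to_one_ratio(self):
        grid = angular_grid(360)
        inten = np.ones(360)
        for anchor in (0.0,):
            idx = np.argsort(np.abs(wrapped_difference(grid, anchor)))[:3]
            inten[idx] = 2.0
        p = AngularProfile(grid, inten, sem=np.zeros(360), aligned=True)
        r = polarity_ratio(p)
        assert r.ratio_0_over_180 == pytest.approx(2.0)
        assert r.ratio_0_over_90 == pytest.approx(2.0)

    def test_error_propagation_formula(self):
        # a = 4 +- 0.4, b = 2 +- 0.2 -> r = 2 +- 2 sqrt(0.01 + 0.01)
        grid = angular_grid(360)
        inten = np.ones(360)
        sem = np.zeros(360)
        for anchor, val, s in ((0.0, 4.0, 0.4), (90.0, 2.0, 0.2), (180.0, 2.0, 0.2)):
            idx = np.argsort(np.abs(wrapped_difference(grid, anchor)))[:3]
            inten[idx] = val
            sem[idx] = s * math.sqrt(3)  # 3-point mean SE = sqrt(sum sem^2)/3
        p = AngularProfile(grid, inten, sem=sem, aligned=True)
        r = polarity_ratio(p)
        assert r.ratio_0_over_90 == pytest.approx(2.0)
        assert r.err_0_over_90 == pytest.approx(2.0 * math.sqrt(0.02), rel=1e-6)

    def test_unaligned_profile_rejected(self):
        p = simulate_profile(ProfileConfig())
        with pytest.raises(ValueError):
            polarity_ratio(p)


class TestRenderedChain:
    def test_extract_align_fit_recovers_hotspot(self):
        # full chain on a rendered ring: multiplicative hotspot of amplitude
        # ratio 2 at 37 deg on a 100-intensity ring
        img = ring_image(hotspot_deg=37.0, hotspot_amp=2.0, hotspot_sigma=30.0)
        prof = extract_profile(img, ring_contour(), thickness=4)
        fit = fit_gaussian_peak(align_and_wrap(prof), n_mc=0)
        assert fit.amplitude == pytest.approx(200.0, rel=0.05)
        assert fit.baseline == pytest.approx(100.0, rel=0.05)
        assert fit.sigma == pytest.approx(30.0, rel=0.05)
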