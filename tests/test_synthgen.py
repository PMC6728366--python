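"""Synthetic-neuromast generator: determinism, distributional structure,
and self-consistency with the downstream analyses."""

import numpy as np
import pytest

from neuropol.circstats import bin_axial, wrap_axial
from neuropol.concentric import concentricity_test, tangent_deviations
from neuropol.ellipse import EllipseModel
from neuropol.orient import division_angle, pair_opposition
from neuropol.synthgen import (
    FieldConfig,
    ProfileConfig,
    simulate_divisions,
    simulate_field,
    simulate_label_image,
    simulate_pairs,
    simulate_profile,
)


class TestFieldGenerator:
    def test_determinism(self):
        cfg = FieldConfig(n_cells=25, orientation_model="concentric", seed=42)
        a = simulate_field(cfg)
        b = simulate_field(cfg)
        assert [(c.x, c.y, c.axial_angle) for c in a] == [
            (c.x, c.y, c.axial_angle) for c in b]

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            FieldConfig(orientation_model="swirl")

    def test_angles_in_axial_range(self):
        for model in ("uniform", "axial_bimodal", "concentric"):
            cells = simulate_field(FieldConfig(n_cells=200, orientation_model=model, seed=1))
            for c in cells:
                assert -90.0 < c.axial_angle <= 90.0
                if c.dir_angle is not None:
                    assert -180.0 < c.dir_angle <= 180.0

    def test_centers_inside_jittered_annulus(self):
        e = EllipseModel(0.0, 0.0, 40.0, 30.0, 20.0)
        cells = simulate_field(FieldConfig(n_cells=300, ellipse=e,
                                           radial_jitter=0.2, seed=3))
        import math
        th = math.radians(e.theta)
        for c in cells:
            u = c.x * math.cos(th) + c.y * math.sin(th)
            v = -c.x * math.sin(th) + c.y * math.cos(th)
            s = math.hypot(u / e.a, v / e.b)
            assert 0.8 - 1e-9 <= s <= 1.0 + 1e-9

    def test_concentric_noiseless_limit_zero_deviation(self):
        e = EllipseModel(0.0, 0.0, 30.0, 30.0, 0.0)  # circle geometry
        cells = simulate_field(FieldConfig(n_cells=40, ellipse=e, radial_jitter=0.1,
                                           orientation_model="concentric",
                                           kappa=1e9, seed=6))
        dev = tangent_deviations(cells, e)
        assert np.max(np.abs(dev)) < 1e-9

    def test_uniform_bins_within_3_se(self):
        cells = simulate_field(FieldConfig(n_cells=10_000, orientation_model="uniform",
                                           seed=8))
        h = bin_axial([c.axial_angle for c in cells])
        p = 1 / 12
        se = np.sqrt(p * (1 - p) / 10_000)
        assert np.all(np.abs(h.probabilities - p) <= 3 * se)

    def test_bimodal_axis_respected(self):
        cells = simulate_field(FieldConfig(n_cells=500, orientation_model="axial_bimodal",
                                           axis_angle=0.0, kappa=8.0, seed=2))
        axials = np.array([c.axial_angle for c in cells])
        assert np.mean(np.abs(axials) < 45.0) > 0.9


class TestPairsGenerator:
    def test_full_opposition(self):
        pairs = simulate_pairs(200, opposition_prob=1.0, angle_noise_sd=0.0, seed=1)
        assert all(pair_opposition(a, b) for a, b in pairs)

    def test_zero_opposition_matches_chance_rate(self):
        # cell 1 points exactly at its sibling; cell 2 is uniform, so the
        # geometric acceptance fraction is tolerance band 180/360 = 1/2
        pairs = simulate_pairs(10_000, opposition_prob=0.0, angle_noise_sd=0.0, seed=1)
        frac = np.mean([pair_opposition(a, b) for a, b in pairs])
        se = np.sqrt(0.25 / 10_000)
        assert abs(frac - 0.5) < 4 * se

    def test_empty(self):
        assert simulate_pairs(0) == []

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            simulate_pairs(5, opposition_prob=1.5)


class TestLabelImageGenerator:
    @pytest.mark.parametrize("angle", [0.0, 45.0])
    def test_orientation_round_trip(self, angle):
        from neuropol.cellshape import region_ellipse
        cell_list = [type("C", (), {})]
        from neuropol.orient import CellRecord
        cell = CellRecord(0, 40.0, 40.0, angle)
        img = simulate_label_image([cell], (81, 81), cell_axes=(10.0, 3.0))
        s = region_ellipse(img, 1)
        assert wrap_axial(s.axial_angle - angle) == pytest.approx(0.0, abs=1.0)

    def test_empty_cells_all_zero(self):
        img = simulate_label_image([], (50, 50))
        assert img.sum() == 0

    def test_labels_are_cell_id_plus_one(self):
        from neuropol.orient import CellRecord
        cells = [CellRecord(0, 20.0, 20.0, 0.0), CellRecord(1, 50.0, 50.0, 30.0)]
        img = simulate_label_image(cells, (81, 81), cell_axes=(8.0, 3.0))
        assert set(np.unique(img)) == {0, 1, 2}

    def test_impossible_packing_raises(self):
        from neuropol.orient import CellRecord
        cells = [CellRecord(i, 20.0, 20.0, 0.0) for i in range(30)]
        with pytest.raises(RuntimeError):
            simulate_label_image(cells, (41, 41), cell_axes=(15.0, 10.0), max_retries=3)


class TestProfileGenerator:
    def test_noiseless_peak_value(self):
        p = simulate_profile(ProfileConfig(amplitude=3.0, peak_center=0.0,
                                           baseline=1.0, noise_sd=0.0))
        assert np.max(p.intensity) == pytest.approx(4.0)
        assert p.angles[int(np.argmax(p.intensity))] == pytest.approx(0.0)

    def test_zero_amplitude_flat(self):
        p = simulate_profile(ProfileConfig(amplitude=0.0, baseline=2.0, noise_sd=0.0))
        assert np.allclose(p.intensity, 2.0)

    def test_determinism(self):
        cfg = ProfileConfig(noise_sd=0.3, seed=5)
        assert np.array_equal(simulate_profile(cfg).intensity,
                              simulate_profile(cfg).intensity)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            ProfileConfig(sigma=0.0)


class TestDivisionsGenerator:
    def test_radial_noiseless(self):
        for e in simulate_divisions(10, "radial", seed=3):
            assert division_angle(e) == pytest.approx(0.0, abs=1e-5)

    def test_tangential_noiseless(self):
        for e in simulate_divisions(10, "tangential", seed=3):
            assert division_angle(e) == pytest.approx(90.0, abs=1e-5)

    def test_uniform_mean_45(self):
        events = simulate_divisions(10_000, "uniform", seed=3)
        angles = [division_angle(e) for e in events]
        se = 90.0 / np.sqrt(12.0) / np.sqrt(10_000)
        assert abs(np.mean(angles) - 45.0) <= 3 * se

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            simulate_divisions(5, "spiral")


class TestGeneratorSelfConsistency:
    def test_concentric_fields_detected(self):
        hits = sum(
            concentricity_test(simulate_field(FieldConfig(
                n_cells=30, orientation_model="concentric", kappa=4.0, seed=s))).concentric
            for s in range(60))
        assert hits >= 57  # >= 95%

    def test_substreams_are_independent(self):
        # drawing a profile between two field calls must not perturb them
        cfg = FieldConfig(n_cells=10, seed=99)
        a = simulate_field(cfg)
        simulate_profile(ProfileConfig(seed=99, noise_sd=1.0))
        b = simulate_field(cfg)
        assert [(c.x, c.axial_angle) for c in a] == [(c.x, c.axial_angle) for c in b]
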