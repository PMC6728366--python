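"""Circular-statistics unit and property tests.

Exact tests (binomial, Fisher) are checked against independent brute-force
enumeration oracles; von Mises fitting against parameter-recovery
simulations; conventions (wrapping, binning, quadrants) against frozen
hand-derived values.
"""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuropol.circstats import (
    KAPPA_MAX,
    axial_difference,
    bin_axial,
    binomial_axis_test,
    chisq_uniform_test,
    fisher_axis_comparison,
    fit_von_mises_axial,
    freeman_halton_test,
    quadrant_counts,
    wrap_axial,
    wrap_directional,
)

finite_angles = st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False)


class TestWrapping:
    @pytest.mark.parametrize(
        "angle, expected",
        [(100.0, -80.0), (-90.0, 90.0), (45.0, 45.0), (90.0, 90.0),
         (180.0, 0.0), (270.0, 90.0), (-100.0, 80.0), (0.0, 0.0)],
    )
    def test_wrap_axial_values(self, angle, expected):
        assert wrap_axial(angle) == pytest.approx(expected)

    @given(finite_angles)
    def test_wrap_axial_idempotent_and_mod180(self, a):
        w = wrap_axial(a)
        assert -90.0 < w <= 90.0
        assert wrap_axial(w) == pytest.approx(w)
        assert math.isclose(math.cos(math.radians(2 * (w - a))), 1.0, abs_tol=1e-9)

    def test_wrap_rejects_non_finite(self):
        with pytest.raises(ValueError):
            wrap_axial(float("nan"))
        with pytest.raises(ValueError):
            wrap_directional(float("inf"))

    @pytest.mark.parametrize(
        "a, b, expected", [(10, 80, 70), (80, 10, -70), (0, 90, 90)]
    )
    def test_axial_difference_values(self, a, b, expected):
        assert axial_difference(a, b) == pytest.approx(expected)

    @given(finite_angles, finite_angles)
    def test_axial_difference_antisymmetric_off_tie(self, a, b):
        d1 = axial_difference(a, b)
        d2 = axial_difference(b, a)
        if abs(d1) < 90 - 1e-6:  # the +90 tie is one-sided by convention
            assert d1 == pytest.approx(-d2, abs=1e-9)


class TestBinning:
    def test_midpoints_fill_each_bin(self):
        mids = [-90 + 15 * (i + 0.5) for i in range(12)]
        h = bin_axial(mids)
        assert list(h.counts) == [1] * 12
        assert h.probabilities == pytest.approx([1 / 12] * 12)

    def test_minus_90_lands_in_last_bin(self):
        h = bin_axial([-90.0])
        assert h.counts[-1] == 1 and h.counts[:-1].sum() == 0

    def test_left_open_right_closed_edges(self):
        # an interior edge value belongs to the bin it closes on the right
        h = bin_axial([-75.0], n_bins=12)
        assert h.counts[0] == 1

    @given(st.lists(finite_angles, min_size=1, max_size=200),
           st.integers(2, 24))
    def test_counts_conserved_probabilities_sum(self, angles, n_bins):
        h = bin_axial(angles, n_bins)
        assert h.counts.sum() == len(angles)
        assert h.probabilities.sum() == pytest.approx(1.0)

    def test_empty_input_flagged(self):
        h = bin_axial([])
        assert h.empty and h.counts.sum() == 0
        assert np.all(np.isnan(h.probabilities))


class TestChisqUniform:
    def test_flat_counts_statistic_zero(self):
        h = bin_axial([-90 + 15 * (i + 0.5) for i in range(12)] * 2)
        r = chisq_uniform_test(h)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_fully_concentrated_statistic(self):
        # 24 in one of 12 bins: (24-2)^2/2 + 11*(0-2)^2/2 = 264
        h = bin_axial([7.5] * 24)
        r = chisq_uniform_test(h)
        assert r.statistic == pytest.approx(264.0)
        assert r.df == 11
        assert r.significant

    def test_statistic_invariant_under_bin_permutation(self, rng):
        angles = rng.uniform(-90, 90, 60)
        h = bin_axial(angles)
        base = chisq_uniform_test(h).statistic
        perm = rng.permutation(12)
        h.counts = h.counts[perm]
        assert chisq_uniform_test(h).statistic == pytest.approx(base)

    def test_p_monotone_in_statistic(self):
        hs = [bin_axial([0.0] * k + list(np.linspace(-89, 89, 24))) for k in (0, 6, 12)]
        rs = [chisq_uniform_test(h) for h in hs]
        stats_ = [r.statistic for r in rs]
        ps = [r.p_value for r in rs]
        assert stats_ == sorted(stats_)
        assert ps == sorted(ps, reverse=True)

    def test_low_expected_count_warns(self):
        r = chisq_uniform_test(bin_axial([0.0, 10.0, 20.0]))
        assert any("unreliable" in w for w in r.warnings)


class TestVonMises:
    def test_degenerate_concentration_capped(self):
        f = fit_von_mises_axial([30.0] * 10)
        assert f.mu == pytest.approx(30.0)
        assert f.kappa == KAPPA_MAX and f.kappa_capped

    def test_uniform_grid_gives_zero_kappa(self):
        f = fit_von_mises_axial(np.linspace(-89.75, 90.0, 720))
        assert f.mean_resultant_length < 1e-3
        assert f.kappa < 0.01

    def test_parameter_recovery(self, rng):
        draws = np.degrees(rng.vonmises(0.0, 4.0, 1000)) / 2.0
        f = fit_von_mises_axial(draws)
        assert abs(f.kappa - 4.0) / 4.0 < 0.15
        assert abs(f.mu) < 3.0

    @given(st.floats(-500, 500, allow_nan=False))
    def test_rotation_equivariance(self, delta):
        base = np.array([-40.0, -10.0, 0.0, 5.0, 20.0, 35.0, 60.0])
        f0 = fit_von_mises_axial(base)
        f1 = fit_von_mises_axial(base + delta)
        assert f1.kappa == pytest.approx(f0.kappa, rel=1e-9)
        assert abs(axial_difference(f0.mu + delta, f1.mu)) < 1e-6 or (
            abs(abs(axial_difference(f0.mu + delta, f1.mu)) - 90) < 1e-6
            and abs(f0.kappa) < 1e-9)

    def test_requires_two_angles(self):
        with pytest.raises(ValueError):
            fit_von_mises_axial([10.0])


def binom_two_sided_oracle(k, n, p=0.5):
    """Independent exact two-sided binomial p: sum of outcome
    probabilities no larger than the observed one."""
    probs = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    obs = probs[k]
    return sum(q for q in probs if q <= obs * (1 + 1e-12))


def fisher_two_sided_oracle(table):
    """Independent Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= obs * (1 + 1e-12))


class TestExactTests:
    def test_quadrant_conventions(self):
        q = quadrant_counts([0.0, 45.0, 90.0, 135.0, 180.0, -90.0, -45.0, -135.0])
        # 45 -> up, 135 -> left, -45 -> right, -135 -> down (half-open anticlockwise)
        assert q == {"right": 2, "up": 2, "left": 2, "down": 2}

    def test_all_right_p_closed_form(self):
        r = binomial_axis_test([0.0] * 20)
        assert r.p_value == pytest.approx(2 * 0.5**20, rel=1e-12)

    def test_balanced_axes_p_one(self):
        r = binomial_axis_test([0.0] * 10 + [90.0] * 10)
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("k,n", [(0, 1), (3, 7), (5, 12), (12, 20), (20, 20), (9, 17)])
    def test_binomial_matches_enumeration_oracle(self, k, n):
        angles = [0.0] * k + [90.0] * (n - k)
        r = binomial_axis_test(angles)
        assert r.p_value == pytest.approx(binom_two_sided_oracle(k, n), rel=1e-9)

    def test_fisher_identical_samples(self):
        r = fisher_axis_comparison([0.0, 90.0] * 5, [0.0, 90.0] * 5)
        assert r.p_value == pytest.approx(1.0)

    def test_fisher_disjoint_axes(self):
        r = fisher_axis_comparison([0.0] * 10, [90.0] * 10)
        assert r.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)

    @pytest.mark.parametrize("table", [
        [[3, 4], [5, 2]], [[1, 9], [8, 1]], [[0, 7], [6, 3]],
        [[5, 5], [5, 5]], [[2, 0], [9, 4]],
    ])
    def test_fisher_matches_enumeration_oracle(self, table):
        (a, b), (c, d) = table
        angles_a = [0.0] * a + [90.0] * b
        angles_b = [0.0] * c + [90.0] * d
        r = fisher_axis_comparison(angles_a, angles_b)
        assert r.p_value == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)

    def test_fisher_zero_margin_flagged(self):
        r = fisher_axis_comparison([0.0] * 5, [0.0] * 5)
        assert r.p_value == 1.0 and r.warnings

    def test_freeman_halton_reduces_to_fisher_on_2x2(self):
        table = [[3, 4], [5, 2]]
        fh = freeman_halton_test(*table)
        assert fh.p_value == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)

    def test_freeman_halton_2xk_probabilities_sum(self):
        # p of a table identical in both rows must be the largest -> p = 1
        fh = freeman_halton_test([2, 2, 2], [2, 2, 2])
        assert fh.p_value == pytest.approx(1.0, abs=1e-9)
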