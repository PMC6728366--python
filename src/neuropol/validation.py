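"""End-to-end validation metrics for the polarity pipeline.

Each function runs one pipeline stage against an independent oracle
(brute-force scan, closed form, enumeration, or Monte Carlo simulation at
the study's field sizes) and returns the measured quantity.  These back
both the acceptance test suite and ``scripts/acceptance.py``.

All randomness derives from an explicit seed; replicate r of a simulation
uses seed ``(base * 1009 + r) mod 2^31 - 1`` so different base seeds give
non-overlapping replicate streams.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np

from .circstats import binomial_axis_test, fisher_axis_comparison, fit_von_mises_axial, wrap_axial
from .concentric import concentricity_test
from .ellipse import EllipseModel, fit_ellipse_pca, nearest_point_on_ellipse
from .orient import CellRecord, division_angle
from .profilepol import AngularProfile, fit_gaussian_peak, polarity_ratio, wrapped_difference
from .synthgen import FieldConfig, ProfileConfig, simulate_divisions, simulate_field, simulate_label_image, simulate_profile

__all__ = [
    "projection_oracle_max_error",
    "ellipse_fit_recovery",
    "concentricity_label_rate",
    "von_mises_recovery",
    "exact_tests_max_discrepancy",
    "gaussian_noiseless_max_relative_error",
    "gaussian_mc_coverage",
    "polarity_ratio_checks",
    "shape_roundtrip_rms",
    "rotated_rectangle_orientation_error",
    "rigid_motion_max_shift",
]


def _rep_seed(base: int, r: int) -> int:
    return (base * 1009 + r) % (2**31 - 1)


# ---------------------------------------------------------------------------
# projection and ellipse fitting


def projection_oracle_max_error(n_pairs: int = 1000, n_scan: int = 1_000_000,
                                seed: int = 0) -> float:
    """Worst-case distance slack of the nearest-point solver, in units of
    the semi-major axis, against a dense parametric brute-force scan.

    For each random ellipse/point pair the solver's found distance is
    compared with the minimum over ``n_scan`` boundary samples; positive
    slack means the solver found a *worse* point than the scan.
    """
    rng = np.random.default_rng(seed)
    tgrid = np.linspace(0.0, 2 * math.pi, n_scan, endpoint=False)
    cos_t, sin_t = np.cos(tgrid), np.sin(tgrid)
    worst = -np.inf
    for _ in range(n_pairs):
        b = rng.uniform(1.0, 10.0)
        a = b * rng.uniform(1.0, 4.0)
        e = EllipseModel(rng.uniform(-20, 20), rng.uniform(-20, 20), a, b,
                         rng.uniform(-89.999, 90.0))
        # point in the ellipse frame (solver works there; scan does too)
        q = rng.uniform(-3 * a, 3 * a, 2)
        p_lab = e.center + np.array([
            q[0] * math.cos(math.radians(e.theta)) - q[1] * math.sin(math.radians(e.theta)),
            q[0] * math.sin(math.radians(e.theta)) + q[1] * math.cos(math.radians(e.theta))])
        pt, _, _ = nearest_point_on_ellipse(e, p_lab)
        d_found = float(np.hypot(*(pt - p_lab)))
        d_scan = float(np.min(np.hypot(a * cos_t - q[0], b * sin_t - q[1])))
        worst = max(worst, (d_found - d_scan) / a)
    return worst


def ellipse_fit_recovery(n_points: int = 720) -> dict:
    """Parameter-recovery errors of the PCA ellipse fit on a dense
    noiseless uniform-in-parameter boundary (a=10, b=4, theta=25,
    center (3, -7))."""
    cx, cy, a, b, theta = 3.0, -7.0, 10.0, 4.0, 25.0
    t = np.linspace(0, 2 * math.pi, n_points, endpoint=False)
    th = math.radians(theta)
    u, v = a * np.cos(t), b * np.sin(t)
    pts = np.c_[cx + u * np.cos(th) - v * np.sin(th),
                cy + u * np.sin(th) + v * np.cos(th)]
    e = fit_ellipse_pca(pts)
    return {
        "center_error": math.hypot(e.cx - cx, e.cy - cy),
        "theta_error_deg": abs(wrap_axial(e.theta - theta)),
        "a_rel_error": abs(e.a - a) / a,
        "b_rel_error": abs(e.b - b) / b,
    }


# ---------------------------------------------------------------------------
# concentricity operating characteristics


def concentricity_label_rate(model: str, n_reps: int = 200, n_cells: int = 30,
                             kappa: float = 4.0, seed: int = 0) -> float:
    """Fraction of simulated fields labelled Concentric.

    ``model="uniform"`` measures the type-I error of the label at the
    default alpha = 0.01; ``model="concentric"`` (kappa 4) measures power.
    """
    hits = 0
    for r in range(n_reps):
        cells = simulate_field(FieldConfig(
            n_cells=n_cells, orientation_model=model, kappa=kappa,
            seed=_rep_seed(seed, r)))
        hits += concentricity_test(cells).concentric
    return hits / n_reps


def von_mises_recovery(n: int = 1000, kappa: float = 4.0, seed: int = 0) -> dict:
    """Axial von Mises ML fit on n synthetic draws at (mu=0, kappa)."""
    rng = np.random.default_rng(seed)
    draws = np.degrees(rng.vonmises(0.0, kappa, n)) / 2.0
    fit = fit_von_mises_axial(draws)
    return {
        "kappa_hat": fit.kappa,
        "kappa_rel_error": abs(fit.kappa - kappa) / kappa,
        "mu_abs_error_deg": abs(fit.mu),
    }


# ---------------------------------------------------------------------------
# exact tests against enumeration


def _binom_two_sided(k: int, n: int) -> float:
    probs = [comb(n, i) * 0.5**n for i in range(n + 1)]
    obs = probs[k]
    return min(1.0, sum(q for q in probs if q <= obs * (1 + 1e-12)))


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = prob(a)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= obs * (1 + 1e-12)))


def exact_tests_max_discrepancy(n_max: int = 20) -> float:
    """Worst absolute p-value discrepancy between the package's exact
    tests and brute-force enumeration oracles, over every quadrant split
    with n <= n_max (binomial) and every 2x2 table with each sample of
    size <= n_max / 2 (Fisher)."""
    worst = 0.0
    for n in range(1, n_max + 1):
        for k in range(n + 1):
            angles = [0.0] * k + [90.0] * (n - k)
            p_pkg = binomial_axis_test(angles).p_value
            worst = max(worst, abs(p_pkg - _binom_two_sided(k, n)))
    half = n_max // 2
    for ra in range(1, half + 1):
        for rb in range(1, half + 1):
            for a in range(ra + 1):
                for c in range(rb + 1):
                    b, d = ra - a, rb - c
                    if (a + c == 0) or (b + d == 0):
                        continue  # zero margin: flagged p = 1 by design
                    angles_a = [0.0] * a + [90.0] * b
                    angles_b = [0.0] * c + [90.0] * d
                    p_pkg = fisher_axis_comparison(angles_a, angles_b).p_value
                    worst = max(worst, abs(p_pkg - _fisher_two_sided(a, b, c, d)))
    return worst


# ---------------------------------------------------------------------------
# Gaussian-peak chain


def gaussian_noiseless_max_relative_error(seed: int = 0) -> float:
    """Worst relative parameter error when refitting noiseless synthetic
    Gaussian-peak profiles (exact-model recovery)."""
    worst = 0.0
    for amp, sig, base in ((3.0, 25.0, 1.0), (10.0, 40.0, 2.0), (0.5, 15.0, 0.1)):
        p = simulate_profile(ProfileConfig(amplitude=amp, peak_center=0.0,
                                           sigma=sig, baseline=base,
                                           noise_sd=0.0, seed=seed))
        f = fit_gaussian_peak(p, n_mc=0)
        worst = max(worst,
                    abs(f.amplitude - amp) / amp,
                    abs(f.sigma - sig) / sig,
                    abs(f.baseline - base) / max(base, 1e-9))
    return worst


def gaussian_mc_coverage(n_truths: int = 200, noise_frac: float = 0.05,
                         n_mc: int = 100, n_samples: int = 90,
                         seed: int = 0) -> float:
    """Fraction of truths whose Monte Carlo 1-sigma amplitude error bar
    covers the true amplitude, at noise SD = noise_frac * amplitude.

    Nominal coverage of a 1-sigma interval is about 68%.
    """
    amp, sig, base = 3.0, 25.0, 1.0
    covered = 0
    for r in range(n_truths):
        s = _rep_seed(seed, r)
        p = simulate_profile(ProfileConfig(
            amplitude=amp, peak_center=0.0, sigma=sig, baseline=base,
            noise_sd=noise_frac * amp, n_samples=n_samples, seed=s))
        f = fit_gaussian_peak(p, n_mc=n_mc, seed=s)
        if f.param_errors["amplitude"] > 0 and \
                abs(f.amplitude - amp) <= f.param_errors["amplitude"]:
            covered += 1
    return covered / n_truths


def polarity_ratio_checks() -> dict:
    """Flat-profile exactness and the closed-form propagation check
    (a = 4 +- 0.4 over b = 2 +- 0.2 gives 2 +- 2 sqrt(0.02))."""
    n = 360
    step = 360.0 / n
    grid = -180.0 + step * np.arange(1, n + 1)
    flat = AngularProfile(grid, np.full(n, 7.0), sem=np.zeros(n), aligned=True)
    rf = polarity_ratio(flat)

    inten = np.ones(n)
    sem = np.zeros(n)
    for anchor, val, s in ((0.0, 4.0, 0.4), (90.0, 2.0, 0.2), (180.0, 2.0, 0.2)):
        idx = np.argsort(np.abs(wrapped_difference(grid, anchor)))[:3]
        inten[idx] = val
        sem[idx] = s * math.sqrt(3)  # 3-point mean SE becomes s
    shaped = AngularProfile(grid, inten, sem=sem, aligned=True)
    rs = polarity_ratio(shaped)
    expected_err = 2.0 * math.sqrt(0.02)
    return {
        "flat_ratio_0_180": rf.ratio_0_over_180,
        "flat_ratio_0_90": rf.ratio_0_over_90,
        "flat_err": rf.err_0_over_180,
        "propagated_err_abs_dev": abs(rs.err_0_over_90 - expected_err),
        "shaped_ratio": rs.ratio_0_over_90,
    }


# ---------------------------------------------------------------------------
# shape pipeline


def shape_roundtrip_rms(n_cells: int = 30, seed: int = 0) -> float:
    """RMS error (degrees) of orientations recovered by the moment-ellipse
    pipeline from a rendered label image of known cell orientations."""
    from .cellshape import all_region_ellipses

    rng = np.random.default_rng(seed)
    angles = rng.uniform(-89.0, 90.0, n_cells)
    cells = []
    for i, ang in enumerate(angles):
        gx, gy = i % 6, i // 6
        cells.append(CellRecord(i, 30.0 + 32.0 * gx, 30.0 + 32.0 * gy, float(ang)))
    side = 30 + 32 * 6
    img = simulate_label_image(cells, (side, side), cell_axes=(12.0, 5.0), seed=seed)
    gen = {c.cell_id + 1: c.axial_angle for c in cells}
    errs = [wrap_axial(s.axial_angle - gen[s.label])
            for s in all_region_ellipses(img) if not s.eccentricity_flag]
    return float(np.sqrt(np.mean(np.square(errs))))


def rotated_rectangle_orientation_error(angle: float = 45.0) -> float:
    """Absolute orientation error (degrees) of the moment ellipse of a
    high-resolution rectangle rendered at the given angle."""
    from .cellshape import region_ellipse

    h = w = 201
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - (w - 1) / 2.0
    y = (h - 1 - rows) - (h - 1) / 2.0
    th = math.radians(angle)
    u = x * math.cos(th) + y * math.sin(th)
    v = -x * math.sin(th) + y * math.cos(th)
    img = ((np.abs(u) <= 60) & (np.abs(v) <= 15)).astype(np.uint16)
    s = region_ellipse(img, 1)
    return abs(wrap_axial(s.axial_angle - angle))


# ---------------------------------------------------------------------------
# rigid-motion invariance


def rigid_motion_max_shift(n_trials: int = 20, seed: int = 0) -> dict:
    """Worst change in tangent deviations, uniformity p, and division
    angles under random rotations + translations of the input fields."""
    rng = np.random.default_rng(seed)
    cells = simulate_field(FieldConfig(n_cells=30, orientation_model="concentric",
                                       kappa=3.0, seed=seed))
    base = concentricity_test(cells)
    events = simulate_divisions(20, "uniform", seed=seed)
    base_div = np.array([division_angle(e) for e in events])

    worst_dev, worst_p, worst_ang = 0.0, 0.0, 0.0
    for _ in range(n_trials):
        delta = rng.uniform(0.0, 360.0)
        th = math.radians(delta)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        shift = rng.uniform(-100.0, 100.0, 2)
        moved = [CellRecord(c.cell_id, *(R @ c.position + shift),
                            wrap_axial(c.axial_angle + delta)) for c in cells]
        res = concentricity_test(moved)
        worst_dev = max(worst_dev, float(np.max(np.abs(res.deviations - base.deviations))))
        worst_p = max(worst_p, abs(res.p_value - base.p_value))
        moved_div = []
        for e in events:
            pts = [tuple(R @ np.asarray(p) + shift)
                   for p in (e.daughter1, e.daughter2, e.organ_center)]
            from .orient import DivisionEvent

            moved_div.append(division_angle(DivisionEvent(*pts)))
        worst_ang = max(worst_ang, float(np.max(np.abs(np.asarray(moved_div) - base_div))))
    return {"max_deviation_shift_deg": worst_dev,
            "max_p_shift": worst_p,
            "max_division_angle_shift_deg": worst_ang}
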