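"""Axial and directional circular statistics for planar-polarity data.

Hair-cell polarity axes are *axial* quantities: an orientation without a
direction, defined modulo 180 degrees and reported on the half-open interval
(-90, 90], measured anticlockwise from the anterior-posterior (+x) axis in a
y-up frame.  Kinocilium directions are *directional*: modulo 360, reported on
(-180, 180].

The module provides the wrapping and binning conventions, the chi-square
goodness-of-fit test against the uniform distribution on the 12-bin axial
histogram, maximum-likelihood von Mises fitting on doubled angles, and the
two exact tests used to compare orientation distributions between genotypes
(quadrant binomial test and Fisher's exact test on axis counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "KAPPA_MAX",
    "AngleHistogram",
    "VonMisesFit",
    "UniformityTestResult",
    "AxisTestResult",
    "wrap_axial",
    "wrap_directional",
    "axial_difference",
    "bin_axial",
    "chisq_uniform_test",
    "fit_von_mises_axial",
    "quadrant_counts",
    "binomial_axis_test",
    "fisher_axis_comparison",
    "freeman_halton_test",
]

#: Concentration cap: perfectly aligned samples (mean resultant length 1)
#: would give kappa = infinity; they are reported as KAPPA_MAX with a flag.
KAPPA_MAX = 1000.0


# ---------------------------------------------------------------------------
# wrapping


def wrap_axial(angle):
    """Wrap an angle (degrees) to the axial interval (-90, 90].

    Axial angles are defined modulo 180; the boundary convention maps -90
    to +90 (half-open on the left).  Accepts scalars or arrays.

    >>> wrap_axial(100.0)
    -80.0
    >>> wrap_axial(-90.0)
    90.0
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_axial requires finite angles")
    w = np.mod(a, 180.0)  # [0, 180)
    w = np.where(w > 90.0, w - 180.0, w)  # (-90, 90]
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(w)
    return w


def wrap_directional(angle):
    """Wrap an angle (degrees) to the directional interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_directional requires finite angles")
    w = np.mod(a, 360.0)  # [0, 360)
    w = np.where(w > 180.0, w - 360.0, w)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(w)
    return w


def axial_difference(from_angle, to_angle):
    """Signed axial difference ``to_angle - from_angle`` on (-90, 90].

    Positive means ``to_angle`` is anticlockwise of ``from_angle``; the
    90-degree tie is broken to +90 by the half-open wrapping convention.
    """
    return wrap_axial(np.asarray(to_angle, dtype=float) - np.asarray(from_angle, dtype=float))


# ---------------------------------------------------------------------------
# histogramming


@dataclass
class AngleHistogram:
    """Equal-width histogram of axial angles over (-90, 90].

    Attributes
    ----------
    bin_edges : ndarray, shape (n_bins + 1,)
        Ordered edges spanning [-90, 90]; bins are left-open, right-closed.
    counts : ndarray of int, shape (n_bins,)
    probabilities : ndarray, shape (n_bins,)
        counts / n; all-NaN (and ``empty`` set) when n == 0.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    probabilities: np.ndarray
    n: int
    empty: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def to_dict(self) -> dict:
        return {
            "bin_edges": list(map(float, self.bin_edges)),
            "counts": list(map(int, self.counts)),
            "probabilities": [None if np.isnan(p) else float(p) for p in self.probabilities],
            "n": int(self.n),
            "empty": bool(self.empty),
        }


def bin_axial(angles: Sequence[float], n_bins: int = 12) -> AngleHistogram:
    """Bin axial angles into ``n_bins`` equal-width bins over (-90, 90].

    Bins are left-open, right-closed, so an angle exactly on an interior
    edge falls in the bin to its left's right neighbour... concretely,
    edge value e belongs to the bin whose right edge is e.  An input of
    exactly -90 is wrapped to +90 first and lands in the last bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = wrap_axial(np.atleast_1d(np.asarray(angles, dtype=float)))
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    n = a.size
    if n == 0:
        counts = np.zeros(n_bins, dtype=int)
        return AngleHistogram(edges, counts, np.full(n_bins, np.nan), 0, empty=True)
    width = 180.0 / n_bins
    # left-open right-closed: index = ceil((a + 90)/width) - 1
    idx = np.ceil((a + 90.0) / width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return AngleHistogram(edges, counts, counts / n, n)


# ---------------------------------------------------------------------------
# uniformity test


@dataclass
class UniformityTestResult:
    """Chi-square goodness-of-fit test of a binned angle histogram
    against the uniform distribution."""

    statistic: float
    df: int
    p_value: float
    n: int
    alpha: float
    significant: bool
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "n": int(self.n),
            "alpha": float(self.alpha),
            "significant": bool(self.significant),
            "warnings": list(self.warnings),
        }


def chisq_uniform_test(hist: AngleHistogram, alpha: float = 0.01) -> UniformityTestResult:
    """Test the binned angle distribution against uniformity.

    statistic = sum_i (O_i - n/k)^2 / (n/k), df = k - 1, upper-tail p from
    the chi-square distribution.  ``significant`` is p < alpha (default
    0.01, the significance threshold used for the concentricity label).
    A low expected count (< 1 in any bin) attaches a validity warning.
    """
    counts = np.asarray(hist.counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("chisq_uniform_test requires a non-empty histogram")
    k = len(counts)
    expected = n / k
    statistic = float(np.sum((counts - expected) ** 2) / expected)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    warn = []
    if expected < 1.0:
        warn.append(f"expected count per bin {expected:.3g} < 1; chi-square approximation unreliable")
    return UniformityTestResult(statistic, df, p, int(n), alpha, p < alpha, warn)


# ---------------------------------------------------------------------------
# von Mises fitting (axial, via angle doubling)


@dataclass
class VonMisesFit:
    """Maximum-likelihood axial von Mises fit.

    Axial angles are doubled onto the full circle, mean direction and mean
    resultant length are computed there, kappa is the standard ML inversion
    of I1/I0, and mu is half the doubled mean direction, wrapped back to
    (-90, 90].
    """

    mu: float
    kappa: float
    mean_resultant_length: float
    n: int
    kappa_capped: bool = False

    def to_dict(self) -> dict:
        return {
            "mu": float(self.mu),
            "kappa": float(self.kappa),
            "mean_resultant_length": float(self.mean_resultant_length),
            "n": int(self.n),
            "kappa_capped": bool(self.kappa_capped),
        }


def _kappa_from_rbar(rbar: float) -> float:
    """Invert A(kappa) = I1(kappa)/I0(kappa) = rbar (ML concentration).

    Best & Fisher starting approximation, refined by Newton iterations on
    the exponentially-scaled Bessel ratio.  Returns KAPPA_MAX for rbar
    close to 1.
    """
    if rbar <= 1e-12:
        return 0.0
    if rbar >= 1.0 - 1e-9:
        return KAPPA_MAX
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    for _ in range(50):
        if k >= KAPPA_MAX:
            return KAPPA_MAX
        a = special.i1e(k) / special.i0e(k)
        # A'(k) = 1 - A/k - A^2
        deriv = 1.0 - a / k - a * a
        if deriv <= 0:
            break
        step = (a - rbar) / deriv
        k -= step
        if abs(step) < 1e-12 * max(1.0, k):
            break
    return float(min(max(k, 0.0), KAPPA_MAX))


def fit_von_mises_axial(angles: Sequence[float]) -> VonMisesFit:
    """Fit an axial von Mises distribution by maximum likelihood.

    Parameters
    ----------
    angles : sequence of axial angles, degrees

    Raises
    ------
    ValueError if fewer than 2 angles are given.
    """
    a = wrap_axial(np.atleast_1d(np.asarray(angles, dtype=float)))
    n = a.size
    if n < 2:
        raise ValueError("fit_von_mises_axial requires n >= 2")
    doubled = np.deg2rad(2.0 * a)
    c = float(np.mean(np.cos(doubled)))
    s = float(np.mean(np.sin(doubled)))
    rbar = math.hypot(c, s)
    mean_dir = math.degrees(math.atan2(s, c))  # doubled-angle frame
    mu = wrap_axial(mean_dir / 2.0)
    kappa = _kappa_from_rbar(rbar)
    capped = kappa >= KAPPA_MAX
    if rbar <= 1e-12:
        # mean direction undefined; report mu = 0 by convention
        mu = 0.0
    return VonMisesFit(mu=float(mu), kappa=float(kappa),
                       mean_resultant_length=float(rbar), n=int(n),
                       kappa_capped=bool(capped))


def von_mises_axial_pdf(theta_deg, fit: VonMisesFit):
    """Density of the fitted axial von Mises on (-90, 90], per degree.

    Useful for overlaying the fit on the deviation histogram (the red curve
    shown on rose diagrams/histograms).
    """
    th = np.deg2rad(2.0 * (np.asarray(theta_deg, dtype=float) - fit.mu))
    kappa = min(fit.kappa, 700.0)  # keep exp finite; display only
    dens = np.exp(kappa * np.cos(th)) / (2 * math.pi * special.i0e(kappa) * np.exp(kappa))
    # doubled-angle density, change of variables back to axial degrees
    return dens * 2.0 * math.pi / 180.0


# ---------------------------------------------------------------------------
# quadrant tests on directional angles


@dataclass
class AxisTestResult:
    """Result of an exact test on quadrant-binned directional angles."""

    p_value: float
    counts: dict
    n: int
    statistic: float | None = None
    table: list | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "p_value": float(self.p_value),
            "counts": {k: int(v) for k, v in self.counts.items()},
            "n": int(self.n),
            "table": self.table,
            "warnings": list(self.warnings),
        }


def quadrant_counts(directional_angles: Sequence[float]) -> dict:
    """Bin directional angles into the four quadrants right/up/left/down.

    Boundaries are half-open anticlockwise: right = (-45, 45],
    up = (45, 135], left = (135, 180] or (-180, -135], down = (-135, -45].
    An angle at exactly 45 counts as "up".
    """
    a = wrap_directional(np.atleast_1d(np.asarray(directional_angles, dtype=float)))
    right = int(np.sum((a > -45.0) & (a <= 45.0)))
    up = int(np.sum((a > 45.0) & (a <= 135.0)))
    left = int(np.sum((a > 135.0) | (a <= -135.0)))
    down = int(np.sum((a > -135.0) & (a <= -45.0)))
    return {"right": right, "up": up, "left": left, "down": down}


def binomial_axis_test(directional_angles: Sequence[float]) -> AxisTestResult:
    """Exact two-sided binomial test of A-P (right+left) counts vs 50%.

    Tests whether the number of cells oriented along the anterior-posterior
    axis differs from half the total, i.e. whether the population favours
    one body axis over the other.
    """
    counts = quadrant_counts(directional_angles)
    n = sum(counts.values())
    if n < 1:
        raise ValueError("binomial_axis_test requires at least one angle")
    k = counts["right"] + counts["left"]
    res = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return AxisTestResult(p_value=float(res.pvalue), counts=counts, n=n)


def _axis_table(angles_a, angles_b) -> np.ndarray:
    ca = quadrant_counts(angles_a)
    cb = quadrant_counts(angles_b)
    return np.array(
        [
            [ca["right"] + ca["left"], ca["up"] + ca["down"]],
            [cb["right"] + cb["left"], cb["up"] + cb["down"]],
        ],
        dtype=int,
    )


def fisher_axis_comparison(
    angles_a: Sequence[float], angles_b: Sequence[float]
) -> AxisTestResult:
    """Two-sided Fisher's exact test comparing axis usage of two samples.

    Each sample is reduced to (A-P count, D-V count) via the quadrants; the
    2x2 table is tested by hypergeometric enumeration.  A zero margin makes
    the table degenerate and p = 1 is returned with a flag.
    """
    a = np.atleast_1d(np.asarray(angles_a, dtype=float))
    b = np.atleast_1d(np.asarray(angles_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("fisher_axis_comparison requires two non-empty samples")
    table = _axis_table(a, b)
    warn = []
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warn.append("zero margin in 2x2 table; test degenerate, p = 1")
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    counts = {
        "a_ap": int(table[0, 0]), "a_dv": int(table[0, 1]),
        "b_ap": int(table[1, 0]), "b_dv": int(table[1, 1]),
    }
    return AxisTestResult(p_value=float(p), counts=counts,
                          n=int(table.sum()), table=table.tolist(), warnings=warn)


def freeman_halton_test(counts_a: Sequence[int], counts_b: Sequence[int]) -> AxisTestResult:
    """Exact Freeman-Halton test on a 2 x k contingency table.

    Optional finer-grained variant of :func:`fisher_axis_comparison` for
    comparing full bin profiles rather than the collapsed axis counts.
    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table.
    Practical for small samples (total n up to a few dozen).
    """
    row_a = np.asarray(counts_a, dtype=int)
    row_b = np.asarray(counts_b, dtype=int)
    if row_a.shape != row_b.shape or row_a.ndim != 1:
        raise ValueError("counts_a and counts_b must be equal-length 1-D count vectors")
    col_tot = row_a + row_b
    n_a = int(row_a.sum())
    n = int(col_tot.sum())
    if n == 0:
        raise ValueError("empty table")

    log_fact = special.gammaln(np.arange(n + 2) + 1.0)  # log k!

    def log_prob(row):
        # hypergeometric probability of a 2xk table given margins
        lp = (log_fact[n_a] + log_fact[n - n_a] - log_fact[n]
              + np.sum(log_fact[col_tot]))
        lp -= np.sum(log_fact[row]) + np.sum(log_fact[col_tot - row])
        return lp

    obs_lp = log_prob(row_a)
    k = len(col_tot)
    total_p = 0.0

    def recurse(j, remaining, row):
        nonlocal total_p
        if j == k - 1:
            if 0 <= remaining <= col_tot[j]:
                row[j] = remaining
                lp = log_prob(np.asarray(row))
                if lp <= obs_lp + 1e-9:
                    total_p += math.exp(lp)
            return
        lo = max(0, remaining - int(col_tot[j + 1:].sum()))
        hi = min(col_tot[j], remaining)
        for v in range(lo, hi + 1):
            row[j] = v
            recurse(j + 1, remaining - v, row)

    recurse(0, n_a, [0] * k)
    return AxisTestResult(p_value=float(min(total_p, 1.0)),
                          counts={"n_a": n_a, "n_b": n - n_a}, n=n,
                          table=[row_a.tolist(), row_b.tolist()])
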