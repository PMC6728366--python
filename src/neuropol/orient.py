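"""Hair-cell orientation from kinocilium-line annotations.

The polarity of a hair cell is read from a straight line drawn from the
pole opposite the kinocilium towards the kinocilium: the line's direction
is the cell's directional polarity angle, its axis the axial polarity
angle.  The module also scores kinocilium opposition within hair-cell
pairs, summarises directional angles for rose diagrams, and measures the
division angle of hair-cell progenitors with respect to the organ radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .circstats import wrap_axial, wrap_directional

__all__ = [
    "CellRecord",
    "DivisionEvent",
    "orientation_from_line",
    "rose_counts",
    "pair_opposition",
    "division_angle",
    "compare_division_angles",
    "TTestResult",
]


@dataclass
class CellRecord:
    """One annotated cell.

    Coordinates are in pixels in a y-up mathematical frame (image-derived
    y-down coordinates are negated at ingestion, see :mod:`neuropol.io`).
    ``axial_angle`` is the polarity axis on (-90, 90]; ``dir_angle`` is the
    optional kinocilium direction on (-180, 180] and, when present,
    satisfies axial_angle == wrap_axial(dir_angle).
    """

    cell_id: int
    x: float
    y: float
    axial_angle: float
    dir_angle: Optional[float] = None
    cell_class: str = "hair"

    def __post_init__(self):
        self.x = float(self.x)
        self.y = float(self.y)
        self.axial_angle = wrap_axial(float(self.axial_angle))
        if self.dir_angle is not None:
            self.dir_angle = wrap_directional(float(self.dir_angle))
            if abs(wrap_axial(self.axial_angle - wrap_axial(self.dir_angle))) > 1e-6:
                raise ValueError(
                    f"cell {self.cell_id}: axial_angle {self.axial_angle} inconsistent "
                    f"with dir_angle {self.dir_angle}"
                )

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class DivisionEvent:
    """A progenitor division: two daughter positions and the organ center
    at one timepoint.  Positions may be 2-D or 3-D (consistently)."""

    daughter1: tuple
    daughter2: tuple
    organ_center: tuple
    timepoint: float = 0.0

    def __post_init__(self):
        d1 = np.asarray(self.daughter1, dtype=float)
        d2 = np.asarray(self.daughter2, dtype=float)
        c = np.asarray(self.organ_center, dtype=float)
        if not (d1.shape == d2.shape == c.shape) or d1.ndim != 1 or d1.size not in (2, 3):
            raise ValueError("daughters and organ_center must all be 2-D or all 3-D points")
        if np.allclose(d1, d2):
            raise ValueError("daughters must be distinct")
        self.daughter1 = tuple(map(float, d1))
        self.daughter2 = tuple(map(float, d2))
        self.organ_center = tuple(map(float, c))


def orientation_from_line(x1: float, y1: float, x2: float, y2: float,
                          image_frame: bool = False) -> tuple[float, float]:
    """Directional and axial angle of the line (x1,y1) -> (x2,y2).

    The line points from the pole opposite the kinocilium towards the
    kinocilium, so its direction IS the cell's polarity direction.  When
    ``image_frame`` is true the coordinates come from an image viewer
    (y increases downward) and y is negated first, so anticlockwise stays
    positive on screen-displayed data.

    Returns
    -------
    (dir_angle, axial_angle) in degrees, on (-180, 180] and (-90, 90].
    """
    dx = float(x2) - float(x1)
    dy = float(y2) - float(y1)
    if image_frame:
        dy = -dy
    if dx == 0.0 and dy == 0.0:
        raise ValueError("zero-length kinocilium line")
    d = wrap_directional(math.degrees(math.atan2(dy, dx)))
    return d, wrap_axial(d)


def rose_counts(dir_angles: Sequence[float], n_bins: int = 12) -> np.ndarray:
    """Counts of directional angles in equal-width bins over (-180, 180].

    Bins are half-open anticlockwise (left-open, right-closed), matching
    the axial binning convention.  This is the tabulation behind a rose
    diagram.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    a = wrap_directional(np.atleast_1d(np.asarray(dir_angles, dtype=float)))
    width = 360.0 / n_bins
    if a.size == 0:
        return np.zeros(n_bins, dtype=int)
    idx = np.ceil((a + 180.0) / width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def pair_opposition(c1: CellRecord, c2: CellRecord, tolerance: float = 90.0) -> bool:
    """Do the kinocilia of two sibling hair cells point toward each other?

    True iff each cell's polarity direction is within ``tolerance`` degrees
    of the unit vector from that cell toward the other.  The default
    tolerance of 90 degrees is equivalent to both inner products being
    positive ("pointing into the facing half-plane").
    """
    if c1.dir_angle is None or c2.dir_angle is None:
        raise ValueError("pair_opposition requires directional angles on both cells")
    v = c2.position - c1.position
    if np.allclose(v, 0):
        raise ValueError("pair_opposition requires distinct positions")
    axis_12 = math.degrees(math.atan2(v[1], v[0]))
    off1 = abs(wrap_directional(c1.dir_angle - axis_12))
    off2 = abs(wrap_directional(c2.dir_angle - (axis_12 + 180.0)))
    return (off1 < tolerance) and (off2 < tolerance)


def division_angle(event: DivisionEvent) -> float:
    """Division angle with respect to the organ radius, in [0, 90] degrees.

    The angle between the daughter-daughter vector and the vector from the
    organ center to the center of division (the daughter midpoint); the
    smallest angle between the two undirected lines, so 0 = radial
    division, 90 = tangential.  Works in 2-D and 3-D.
    """
    d1 = np.asarray(event.daughter1, dtype=float)
    d2 = np.asarray(event.daughter2, dtype=float)
    c = np.asarray(event.organ_center, dtype=float)
    u = d2 - d1
    v = (d1 + d2) / 2.0 - c
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("division center coincides with organ center; angle undefined")
    cosang = abs(float(np.dot(u, v))) / (np.linalg.norm(u) * nv)
    cosang = min(1.0, max(-1.0, cosang))
    return math.degrees(math.acos(cosang))


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    warnings: list

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic), "p_value": float(self.p_value),
            "df": float(self.df), "mean_a": float(self.mean_a),
            "mean_b": float(self.mean_b), "n_a": int(self.n_a),
            "n_b": int(self.n_b), "warnings": list(self.warnings),
        }


def compare_division_angles(a: Sequence[float], b: Sequence[float],
                            equal_var: bool = False) -> TTestResult:
    """Two-sample t test (Welch by default) comparing division angles of
    two conditions, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    warn = []
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            warn.append("both samples have zero variance and equal means; p = 1")
            return TTestResult(0.0, 1.0, float(a.size + b.size - 2),
                               float(np.mean(a)), float(np.mean(b)),
                               a.size, b.size, warn)
        warn.append("both samples have zero variance; t statistic degenerate")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = getattr(res, "df", float("nan"))
    return TTestResult(float(res.statistic), float(res.pvalue), float(df),
                       float(np.mean(a)), float(np.mean(b)), a.size, b.size, warn)
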