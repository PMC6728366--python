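"""Ellipse geometry: PCA least-squares fitting, nearest-point projection,
and boundary tangents.

The organ outline of a neuromast is summarised by an ellipse fitted to the
hair-cell centers; each cell is then projected to the nearest point on that
ellipse and compared with the local tangent.  The nearest-point problem is
solved by a coarse parametric scan followed by bounded local refinement,
which is robust near the evolute where Newton iterations are unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .circstats import wrap_axial

__all__ = [
    "EllipseModel",
    "fit_ellipse_pca",
    "fit_ellipse_direct",
    "nearest_point_on_ellipse",
    "tangent_axial_angle",
]


@dataclass
class EllipseModel:
    """An ellipse: center, semi-axes (a >= b > 0) and major-axis rotation
    theta, an axial angle on (-90, 90]."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float
    conditioning_flag: bool = False  # theta ill-conditioned for near-circles

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError("ellipse requires a >= b > 0")
        self.theta = wrap_axial(float(self.theta))
        if self.a / self.b < 1.05:
            self.conditioning_flag = True

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy], dtype=float)

    def point(self, t):
        """Boundary point(s) at parameter t: center + R(theta)·(a cos t, b sin t)."""
        t = np.asarray(t, dtype=float)
        th = math.radians(self.theta)
        u = self.a * np.cos(t)
        v = self.b * np.sin(t)
        x = self.cx + u * math.cos(th) - v * math.sin(th)
        y = self.cy + u * math.sin(th) + v * math.cos(th)
        return np.stack([x, y], axis=-1)

    def to_dict(self) -> dict:
        return {
            "cx": float(self.cx), "cy": float(self.cy),
            "a": float(self.a), "b": float(self.b),
            "theta": float(self.theta),
            "conditioning_flag": bool(self.conditioning_flag),
        }


def fit_ellipse_pca(points) -> EllipseModel:
    """Least-squares ellipse fit based on principal component analysis.

    Center = centroid of the points; rotation = orientation of the first
    principal axis; semi-axes = sqrt(2) times the standard deviations along
    the principal axes.  For points sampled uniformly in the ellipse
    parameter t on a boundary (x = a cos t has variance a^2/2), this
    recovers the generating ellipse exactly in the dense noiseless limit.

    Raises a ValueError for < 3 points or a rank-deficient (collinear)
    scatter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("fit_ellipse_pca requires >= 3 points of shape (n, 2)")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise ValueError("points are (nearly) collinear; ellipse fit is rank-deficient")
    a = math.sqrt(2.0 * evals[1])
    b = math.sqrt(2.0 * evals[0])
    major = evecs[:, 1]
    theta = wrap_axial(math.degrees(math.atan2(major[1], major[0])))
    return EllipseModel(float(centroid[0]), float(centroid[1]), a, b, theta)


def fit_ellipse_direct(points) -> EllipseModel:
    """Algebraic direct least-squares conic fit (sensitivity-check option).

    Fits the conic ax^2 + bxy + cy^2 + dx + ey + f = 0 with the ellipse
    constraint 4ac - b^2 = 1 by the stable generalized-eigenvalue method,
    then converts to geometric parameters.  Used to cross-check the PCA
    fit; the PCA fit is the default throughout.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("direct conic fit requires >= 5 points")
    x = pts[:, 0] - pts[:, 0].mean()
    y = pts[:, 1] - pts[:, 1].mean()
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    t = -np.linalg.solve(s3, s2.T)
    m = s1 + s2 @ t
    c_inv = np.array([[0, 0, 0.5], [0, -1, 0], [0.5, 0, 0]])
    evals, evecs = np.linalg.eig(c_inv @ m)
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    a1 = evecs[:, np.real(cond) > 0][:, 0].real
    coeffs = np.concatenate([a1, t @ a1])  # A,B,C,D,E,F on centered coords
    A, B, C, D, E, F = coeffs
    # geometric conversion
    den = B * B - 4 * A * C
    cx0 = (2 * C * D - B * E) / den
    cy0 = (2 * A * E - B * D) / den
    num = 2 * (A * E * E + C * D * D + F * B * B - B * D * E - 4 * A * C * F)
    s = math.sqrt((A - C) ** 2 + B * B)
    ax1 = math.sqrt(abs(num / (den * ((A + C) + s))))
    ax2 = math.sqrt(abs(num / (den * ((A + C) - s))))
    a_len, b_len = max(ax1, ax2), min(ax1, ax2)
    theta = 0.5 * math.degrees(math.atan2(B, A - C))
    # atan2 convention gives the axis of ax1 (associated with (A+C)+s)
    if ax1 < ax2:
        theta += 90.0
    return EllipseModel(float(cx0 + pts[:, 0].mean()), float(cy0 + pts[:, 1].mean()),
                        a_len, b_len, wrap_axial(theta))


def _to_ellipse_frame(ellipse: EllipseModel, p) -> np.ndarray:
    th = math.radians(ellipse.theta)
    d = np.asarray(p, dtype=float) - ellipse.center
    return np.array([d[0] * math.cos(th) + d[1] * math.sin(th),
                     -d[0] * math.sin(th) + d[1] * math.cos(th)])


def nearest_point_on_ellipse(ellipse: EllipseModel, p, n_coarse: int = 720):
    """Project a point to the closest point on the ellipse boundary.

    Minimises the Euclidean distance over the parameter t with a coarse
    grid of ``n_coarse`` samples followed by bounded Brent refinement in
    the bracketing interval; accurate to well below 1e-6 * a in distance.

    Returns
    -------
    (point, t, degenerate) : boundary point (ndarray shape (2,)), the
    parameter t of that point, and a flag set when p is at the ellipse
    center (all boundary directions equidistant for a circle; the
    major-axis vertex t = 0 is returned by convention).
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("nearest_point_on_ellipse requires a finite point")
    q = _to_ellipse_frame(ellipse, p)
    degenerate = bool(np.hypot(q[0], q[1]) < 1e-12 * ellipse.a)
    if degenerate:
        return ellipse.point(0.0), 0.0, True

    a, b = ellipse.a, ellipse.b

    def dist2(t):
        return (a * np.cos(t) - q[0]) ** 2 + (b * np.sin(t) - q[1]) ** 2

    ts = np.linspace(0.0, 2 * math.pi, n_coarse, endpoint=False)
    i = int(np.argmin(dist2(ts)))
    dt = 2 * math.pi / n_coarse
    lo, hi = ts[i] - dt, ts[i] + dt
    res = minimize_scalar(dist2, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    t_best = float(res.x)
    # safeguarded Newton polish on the stationarity condition
    # g(t) = (P(t) - q) . P'(t) = 0; Brent alone leaves O(sqrt(eps)) slack
    for _ in range(5):
        ct, st = math.cos(t_best), math.sin(t_best)
        ex, ey = a * ct - q[0], b * st - q[1]
        g = -ex * a * st + ey * b * ct
        gp = a * a * st * st - ex * a * ct + b * b * ct * ct - ey * b * st
        if gp == 0:
            break
        step = g / gp
        if not (lo - dt <= t_best - step <= hi + dt):
            break
        t_best -= step
        if abs(step) < 1e-14:
            break
    t_best %= 2 * math.pi
    return ellipse.point(t_best), t_best, False


def tangent_axial_angle(ellipse: EllipseModel, t: float) -> float:
    """Axial angle of the ellipse tangent at parameter t.

    The tangent direction is (-a sin t, b cos t) rotated by the ellipse
    rotation; reported on (-90, 90].
    """
    th = math.radians(ellipse.theta)
    dx0 = -ellipse.a * math.sin(t)
    dy0 = ellipse.b * math.cos(t)
    dx = dx0 * math.cos(th) - dy0 * math.sin(th)
    dy = dx0 * math.sin(th) + dy0 * math.cos(th)
    return wrap_axial(math.degrees(math.atan2(dy, dx)))
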