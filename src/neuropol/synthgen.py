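"""Synthetic neuromast generator.

Produces annotated polarity fields, hair-cell pairs, segmented label
images, cortical intensity profiles, and progenitor division events with
the statistical structure the downstream analyses assume, so every stage
of the pipeline can be exercised and validated without microscopy data.

The generator emulates the phenotype classes seen in neuromasts:

* ``uniform`` — axial polarity angles uniform on (-90, 90] (PCP-mutant-like
  randomised fields);
* ``axial_bimodal`` — kinocilium directions split between the two poles of
  one body axis (wild-type A-P or D-V coordination);
* ``concentric`` — polarity axes aligned with the local tangent of the
  organ ellipse plus axial von Mises noise (Wnt-type concentric fields).

All randomness flows from a single seed through fixed per-component
substreams, so adding one generator call does not shift the output of the
others, and identical seed + config gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circstats import KAPPA_MAX, wrap_axial, wrap_directional
from .ellipse import EllipseModel
from .orient import CellRecord, DivisionEvent
from .profilepol import AngularProfile, angular_grid, wrapped_difference

__all__ = [
    "FieldConfig",
    "ProfileConfig",
    "simulate_field",
    "simulate_pairs",
    "simulate_label_image",
    "simulate_profile",
    "simulate_divisions",
]

_ORIENTATION_MODELS = ("uniform", "axial_bimodal", "concentric")

# fixed substream keys: one per generator component
_SUB_FIELD, _SUB_PAIRS, _SUB_LABELS, _SUB_PROFILE, _SUB_DIVISIONS = range(5)


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


@dataclass
class FieldConfig:
    """Configuration of one synthetic polarity field.

    n_cells cells are placed on a boundary band of the organ ellipse
    (uniform in the ellipse parameter t; ``radial_jitter`` is the band
    thickness as a fraction of the radius, matching the rosette geometry
    the fitted-ellipse concentricity measure assumes).  ``kappa`` is the
    von Mises concentration of the orientation noise, applied on doubled
    angles so it has its standard circular meaning; kappa >= 1000 is
    treated as the noiseless limit.
    """

    n_cells: int = 30
    ellipse: EllipseModel = None
    radial_jitter: float = 0.15
    orientation_model: str = "uniform"
    axis_angle: float = 0.0
    kappa: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.ellipse is None:
            self.ellipse = EllipseModel(100.0, 100.0, 40.0, 30.0, 0.0)
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.radial_jitter < 1:
            raise ValueError("radial_jitter must be in [0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.orientation_model not in _ORIENTATION_MODELS:
            raise ValueError(
                f"unknown orientation_model {self.orientation_model!r}; "
                f"expected one of {_ORIENTATION_MODELS}")


@dataclass
class ProfileConfig:
    """Configuration of one synthetic cortical intensity profile:
    a Gaussian angular peak on a constant baseline plus i.i.d. Gaussian
    noise, sampled on a uniform angular grid over (-180, 180]."""

    amplitude: float = 3.0
    peak_center: float = 0.0
    sigma: float = 25.0
    baseline: float = 1.0
    noise_sd: float = 0.0
    n_samples: int = 360
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if self.baseline < 0 or self.noise_sd < 0:
            raise ValueError("baseline and noise_sd must be >= 0")
        self.peak_center = wrap_directional(float(self.peak_center))


def _axial_vm_noise(rng: np.random.Generator, kappa: float, size: int) -> np.ndarray:
    """Axial von Mises noise in degrees: draw on the doubled circle with
    concentration kappa, halve back to the axial domain."""
    if kappa >= KAPPA_MAX:
        return np.zeros(size)
    if kappa == 0:
        return rng.uniform(-90.0, 90.0, size)
    doubled = rng.vonmises(0.0, kappa, size)
    return np.degrees(doubled) / 2.0


def simulate_field(config: FieldConfig) -> list[CellRecord]:
    """Generate one annotated polarity field.

    Cells are placed at uniform ellipse parameter t on the boundary band;
    each orientation model assigns axial polarity angles as documented in
    the module docstring.  Deterministic given config.seed.
    """
    rng = _rng(config.seed, _SUB_FIELD)
    e = config.ellipse
    n = config.n_cells
    t = rng.uniform(0.0, 2 * math.pi, n)
    s = 1.0 - config.radial_jitter * rng.uniform(0.0, 1.0, n)
    th = math.radians(e.theta)
    u = s * e.a * np.cos(t)
    v = s * e.b * np.sin(t)
    x = e.cx + u * math.cos(th) - v * math.sin(th)
    y = e.cy + u * math.sin(th) + v * math.cos(th)

    dir_angles = [None] * n
    if config.orientation_model == "uniform":
        axial = rng.uniform(-90.0, 90.0, n)
        axial[axial == -90.0] = 90.0
    elif config.orientation_model == "axial_bimodal":
        flip = rng.integers(0, 2, n) * 180.0
        if config.kappa >= KAPPA_MAX:
            noise = np.zeros(n)
        elif config.kappa == 0:
            noise = rng.uniform(-180.0, 180.0, n)
        else:
            noise = np.degrees(rng.vonmises(0.0, config.kappa, n))
        d = wrap_directional(config.axis_angle + flip + noise)
        dir_angles = list(map(float, np.atleast_1d(d)))
        axial = wrap_axial(np.atleast_1d(d))
    else:  # concentric: tangent of the (similar) ellipse at parameter t
        tang = np.degrees(np.arctan2(
            (-e.a * np.sin(t)) * math.sin(th) + (e.b * np.cos(t)) * math.cos(th),
            (-e.a * np.sin(t)) * math.cos(th) - (e.b * np.cos(t)) * math.sin(th),
        ))
        axial = wrap_axial(tang + _axial_vm_noise(rng, config.kappa, n))

    axial = np.atleast_1d(axial)
    return [
        CellRecord(cell_id=i, x=float(x[i]), y=float(y[i]),
                   axial_angle=float(axial[i]), dir_angle=dir_angles[i],
                   cell_class="hair")
        for i in range(n)
    ]


def simulate_pairs(n_pairs: int, opposition_prob: float = 1.0,
                   angle_noise_sd: float = 0.0, seed: int = 0,
                   ) -> list[tuple[CellRecord, CellRecord]]:
    """Generate sibling hair-cell pairs with kinocilium directions.

    Each pair sits on a random axis 8 px apart.  The first cell points
    toward its sibling (plus Gaussian angular noise of ``angle_noise_sd``
    degrees); with probability ``opposition_prob`` the second points back
    toward the first (plus noise), otherwise its direction is uniform.
    """
    if not 0.0 <= opposition_prob <= 1.0:
        raise ValueError("opposition_prob must be in [0, 1]")
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    rng = _rng(seed, _SUB_PAIRS)
    pairs = []
    for k in range(n_pairs):
        cx, cy = rng.uniform(20.0, 180.0, 2)
        phi = rng.uniform(-180.0, 180.0)
        ux, uy = math.cos(math.radians(phi)), math.sin(math.radians(phi))
        d1 = wrap_directional(phi + rng.normal(0.0, angle_noise_sd)) if angle_noise_sd > 0 else phi
        if rng.uniform() < opposition_prob:
            d2 = phi + 180.0 + (rng.normal(0.0, angle_noise_sd) if angle_noise_sd > 0 else 0.0)
        else:
            d2 = rng.uniform(-180.0, 180.0)
        d1, d2 = wrap_directional(d1), wrap_directional(d2)
        c1 = CellRecord(cell_id=2 * k, x=cx - 4.0 * ux, y=cy - 4.0 * uy,
                        axial_angle=wrap_axial(d1), dir_angle=d1)
        c2 = CellRecord(cell_id=2 * k + 1, x=cx + 4.0 * ux, y=cy + 4.0 * uy,
                        axial_angle=wrap_axial(d2), dir_angle=d2)
        pairs.append((c1, c2))
    return pairs


def simulate_label_image(cells: Sequence[CellRecord], shape: tuple[int, int],
                         cell_axes: tuple[float, float] = (10.0, 4.0),
                         max_retries: int = 50, seed: int = 0) -> np.ndarray:
    """Render cells as non-overlapping elliptical regions in a label image.

    Each cell is drawn as a filled ellipse with semi-axes ``cell_axes``
    (major, minor) whose major axis follows the cell's axial polarity
    angle.  Cell coordinates are in the y-up math frame; the image is
    row-major with row = height - 1 - y, so a cell with axial angle theta
    appears rotated anticlockwise by theta on a y-up display of the image.
    Overlapping cells are re-jittered up to ``max_retries`` times, then a
    RuntimeError is raised.  Background label is 0, cells are labelled
    cell_id + 1.
    """
    h, w = shape
    amaj, amin = cell_axes
    if amaj < amin:
        raise ValueError("cell_axes must be (major, minor) with major >= minor")
    img = np.zeros((h, w), dtype=np.uint16)
    rng = _rng(seed, _SUB_LABELS)
    rows, cols = np.mgrid[0:h, 0:w]
    xg = cols.astype(float)
    yg = (h - 1 - rows).astype(float)
    for c in cells:
        placed = False
        cx, cy = c.x, c.y
        for attempt in range(max_retries + 1):
            th = math.radians(c.axial_angle)
            dx, dy = xg - cx, yg - cy
            uu = dx * math.cos(th) + dy * math.sin(th)
            vv = -dx * math.sin(th) + dy * math.cos(th)
            mask = (uu / amaj) ** 2 + (vv / amin) ** 2 <= 1.0
            inside = (cx - amaj >= 0 and cx + amaj < w and cy - amaj >= 0 and cy + amaj < h)
            if inside and not np.any(img[mask]):
                img[mask] = c.cell_id + 1
                placed = True
                break
            # widen the jitter as retries accumulate so crowded rings relax
            jit = rng.normal(0.0, amin * (1.0 + attempt / 5.0), 2)
            cx, cy = c.x + jit[0], c.y + jit[1]
        if not placed:
            raise RuntimeError(
                f"could not place cell {c.cell_id} without overlap after {max_retries} retries")
    return img


def simulate_profile(config: ProfileConfig) -> AngularProfile:
    """Generate a cortical intensity profile: Gaussian angular peak on a
    baseline plus i.i.d. Gaussian noise.  Deterministic given config.seed."""
    rng = _rng(config.seed, _SUB_PROFILE)
    angles = angular_grid(config.n_samples)
    delta = wrapped_difference(angles, config.peak_center)
    intensity = config.baseline + config.amplitude * np.exp(
        -(delta ** 2) / (2.0 * config.sigma ** 2))
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, config.n_samples)
    return AngularProfile(angles=angles, intensity=intensity)


def simulate_divisions(n: int, angle_model: str = "uniform", seed: int = 0,
                       angle_noise_sd: float = 0.0,
                       organ_center: tuple[float, float] = (50.0, 50.0),
                       ) -> list[DivisionEvent]:
    """Generate progenitor division events around a fixed organ center.

    ``radial`` divisions have the daughter-daughter axis along the organ
    radius (division angle 0), ``tangential`` perpendicular to it (90),
    ``uniform`` draws the division angle uniformly on [0, 90].
    ``angle_noise_sd`` adds Gaussian noise (degrees) to the division angle,
    clipped back to [0, 90].
    """
    if angle_model not in ("radial", "tangential", "uniform"):
        raise ValueError(f"unknown angle_model {angle_model!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed, _SUB_DIVISIONS)
    cx, cy = organ_center
    events = []
    for k in range(n):
        r = rng.uniform(10.0, 30.0)
        psi = rng.uniform(0.0, 360.0)  # direction of the division center
        mx = cx + r * math.cos(math.radians(psi))
        my = cy + r * math.sin(math.radians(psi))
        if angle_model == "radial":
            alpha = 0.0
        elif angle_model == "tangential":
            alpha = 90.0
        else:
            alpha = rng.uniform(0.0, 90.0)
        if angle_noise_sd > 0:
            alpha = float(np.clip(alpha + rng.normal(0.0, angle_noise_sd), 0.0, 90.0))
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        axis = psi + sign * alpha
        half = 3.0
        ax, ay = math.cos(math.radians(axis)), math.sin(math.radians(axis))
        events.append(DivisionEvent(
            daughter1=(mx - half * ax, my - half * ay),
            daughter2=(mx + half * ax, my + half * ay),
            organ_center=(cx, cy),
            timepoint=float(k),
        ))
    return events
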