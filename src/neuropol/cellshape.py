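"""Support-cell orientation from segmented label images.

Support cells in a neuromast elongate and orient coherently under Wnt
signalling.  Given a label image of segmented support cells, each region
is summarised by the ellipse with the same second central moments
(centroid, major/minor axis lengths, major-axis orientation); the
orientations, folded to the unsigned range [0, 90] degrees against the
horizontal, are histogrammed and tested against uniformity with a one-way
chi-square test.

Near-circular regions carry no meaningful orientation and are flagged and
excluded from the histogram; their signed axial angle is still reported
for downstream reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .circstats import AngleHistogram, UniformityTestResult, chisq_uniform_test, wrap_axial

__all__ = [
    "RegionShape",
    "region_ellipse",
    "orientation_histogram",
    "support_cell_pipeline",
    "SupportCellResult",
]

#: Regions smaller than this (pixels) cannot support a moment ellipse.
MIN_AREA = 5
#: Regions with major/minor axis ratio below this are flagged near-circular.
CIRCULARITY_RATIO = 1.05


@dataclass
class RegionShape:
    """Moment-ellipse summary of one labelled region.

    ``orientation`` is the unsigned angle in [0, 90] between the major
    axis and the horizontal; ``axial_angle`` is the signed equivalent on
    (-90, 90] in the y-up math frame.  ``eccentricity_flag`` marks
    near-circular regions whose orientation is unreliable.
    """

    label: int
    centroid: tuple
    major_len: float
    minor_len: float
    orientation: float
    axial_angle: float
    area: int
    eccentricity_flag: bool

    def to_dict(self) -> dict:
        return {
            "label": int(self.label),
            "centroid_x": float(self.centroid[0]),
            "centroid_y": float(self.centroid[1]),
            "major_len": float(self.major_len),
            "minor_len": float(self.minor_len),
            "orientation": float(self.orientation),
            "axial_angle": float(self.axial_angle),
            "area": int(self.area),
            "eccentricity_flag": bool(self.eccentricity_flag),
        }


def _shape_from_prop(p) -> RegionShape:
    # regionprops orientation o: angle between the row axis and the major
    # axis, anticlockwise, (-pi/2, pi/2].  In the y-up math frame the
    # major-axis axial angle is wrap_axial(90 + degrees(o)) (empirically
    # calibrated against rendered ellipses).
    axial = wrap_axial(90.0 + np.degrees(p.orientation))
    major = float(p.axis_major_length)
    minor = float(p.axis_minor_length)
    flagged = minor <= 0 or (major / minor) < CIRCULARITY_RATIO
    row, col = p.centroid
    return RegionShape(
        label=int(p.label),
        centroid=(float(col), float(row)),  # (x, y_image)
        major_len=major, minor_len=minor,
        orientation=float(abs(axial)),
        axial_angle=float(axial),
        area=int(p.area),
        eccentricity_flag=bool(flagged),
    )


def region_ellipse(label_image: np.ndarray, label: int) -> RegionShape:
    """Moment-ellipse of a single labelled region.

    Raises KeyError for a missing label, ValueError for a region smaller
    than MIN_AREA pixels.
    """
    mask = (np.asarray(label_image) == label)
    area = int(mask.sum())
    if area == 0:
        raise KeyError(f"label {label} not present in image")
    if area < MIN_AREA:
        raise ValueError(f"region {label} has area {area} < {MIN_AREA} pixels")
    p = regionprops(mask.astype(np.uint8))[0]
    shape = _shape_from_prop(p)
    return RegionShape(**{**shape.__dict__, "label": int(label)})


def all_region_ellipses(label_image: np.ndarray) -> list[RegionShape]:
    """Moment ellipses of every labelled region (area >= MIN_AREA)."""
    img = np.asarray(label_image)
    shapes = []
    for p in regionprops(img.astype(np.int64)):
        if p.area < MIN_AREA:
            continue
        shapes.append(_shape_from_prop(p))
    return shapes


def orientation_histogram(shapes: Sequence[RegionShape], n_bins: int = 9) -> AngleHistogram:
    """Histogram of unsigned orientations over [0, 90].

    Bins are equal-width; the first bin is closed at 0 and all bins are
    right-closed, so 90 lands in the last bin.  Near-circular flagged
    shapes are excluded.
    """
    included = [s for s in shapes if not s.eccentricity_flag]
    if not included:
        raise ValueError("no unflagged shapes to histogram")
    angles = np.array([s.orientation for s in included])
    width = 90.0 / n_bins
    idx = np.ceil(angles / width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    return AngleHistogram(edges, counts, counts / counts.sum(), int(counts.sum()))


@dataclass
class SupportCellResult:
    """Full support-cell orientation analysis of one label image."""

    shapes: list
    histogram: AngleHistogram
    uniform_test: UniformityTestResult
    excluded_labels: list
    n_bins: int
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_dict() for s in self.shapes])

    def to_dict(self) -> dict:
        return {
            "shapes": [s.to_dict() for s in self.shapes],
            "histogram": self.histogram.to_dict(),
            "uniform_test": self.uniform_test.to_dict(),
            "excluded_labels": [
                {"label": int(l), "reason": r} for l, r in self.excluded_labels],
            "n_bins": int(self.n_bins),
            "warnings": list(self.warnings),
        }


def support_cell_pipeline(label_image: np.ndarray, n_bins: int = 9,
                          alpha: float = 0.01) -> SupportCellResult:
    """Support-cell orientation pipeline.

    Moment-ellipse every region, histogram the unsigned orientations over
    [0, 90] in ``n_bins`` bins, and run the one-way chi-square test
    against uniformity at ``alpha``.  Records which labels were excluded
    (too small or near-circular) and why.
    """
    img = np.asarray(label_image)
    excluded = []
    shapes = []
    for p in regionprops(img.astype(np.int64)):
        if p.area < MIN_AREA:
            excluded.append((int(p.label), f"area {int(p.area)} < {MIN_AREA}"))
            continue
        s = _shape_from_prop(p)
        shapes.append(s)
        if s.eccentricity_flag:
            excluded.append((int(p.label), "near-circular; orientation unreliable"))
    usable = [s for s in shapes if not s.eccentricity_flag]
    if len(usable) < 5:
        raise ValueError(f"only {len(usable)} usable regions (< 5); cannot test orientation")
    hist = orientation_histogram(shapes, n_bins=n_bins)
    utest = chisq_uniform_test(hist, alpha=alpha)
    return SupportCellResult(shapes=shapes, histogram=hist, uniform_test=utest,
                             excluded_labels=excluded, n_bins=n_bins)
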