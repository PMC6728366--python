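"""Concentricity analysis of hair-cell polarity fields.

A neuromast whose hair-cell axes follow a concentric (Wnt-type) pattern has
polarity axes aligned with the tangent of the organ outline; a PCP-type
mutant has random axes.  The analysis fits an ellipse to the cell centers,
projects each cell to the nearest boundary point, and measures the signed
axial deviation of the cell's polarity axis from the local tangent.  The
deviations are binned into 12 bins on (-90, 90] and tested against the
uniform distribution by a chi-square goodness-of-fit test; a field is
labelled "Concentric" when uniformity is rejected at p < 0.01.  A von Mises
fit on the deviations summarises where the deviations concentrate (mu near
0 for tangent alignment) and how tightly (kappa).

The statsmodels-style entry point is :class:`ConcentricityModel`::

    model = ConcentricityModel.from_dataframe(df)
    res = model.fit()
    print(res.summary())

The function :func:`concentricity_test` is the equivalent one-shot pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circstats import (
    AngleHistogram,
    UniformityTestResult,
    VonMisesFit,
    axial_difference,
    bin_axial,
    chisq_uniform_test,
    fit_von_mises_axial,
)
from .ellipse import EllipseModel, fit_ellipse_pca, nearest_point_on_ellipse, tangent_axial_angle
from .orient import CellRecord

__all__ = [
    "NeighborAlignment",
    "ConcentricityResults",
    "ConcentricityModel",
    "tangent_deviations",
    "nearest_neighbor_alignment",
    "concentricity_test",
]

#: Fields with fewer cells than this get a low-n validity warning.
MIN_CELLS = 5


@dataclass
class NeighborAlignment:
    """Per-cell nearest-neighbour polarity alignment.

    For each cell: the Euclidean-nearest other cell and the signed axial
    difference between their polarity axes (positive = neighbour's axis is
    anticlockwise of the cell's).  Ties in distance are broken toward the
    lower cell_id.
    """

    cell_ids: np.ndarray
    neighbor_ids: np.ndarray
    differences: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "neighbor_id": self.neighbor_ids,
            "angle_difference_deg": self.differences,
        })


def tangent_deviations(cells: Sequence[CellRecord], ellipse: EllipseModel) -> np.ndarray:
    """Signed deviation of each cell's polarity axis from the ellipse
    tangent at its nearest boundary point, degrees on (-90, 90].

    Positive means the cell's axis is anticlockwise of the tangent.
    """
    if len(cells) < 1:
        raise ValueError("tangent_deviations requires at least one cell")
    out = np.empty(len(cells))
    for i, c in enumerate(cells):
        _, t, _ = nearest_point_on_ellipse(ellipse, (c.x, c.y))
        tang = tangent_axial_angle(ellipse, t)
        out[i] = axial_difference(tang, c.axial_angle)
    return out


def nearest_neighbor_alignment(cells: Sequence[CellRecord]) -> NeighborAlignment:
    """Signed axial polarity difference between each cell and its
    Euclidean nearest neighbour."""
    if len(cells) < 2:
        raise ValueError("nearest_neighbor_alignment requires >= 2 cells")
    pos = np.array([[c.x, c.y] for c in cells])
    ids = np.array([c.cell_id for c in cells])
    angles = np.array([c.axial_angle for c in cells])
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nbr = np.empty(len(cells), dtype=int)
    for i in range(len(cells)):
        best = np.min(d2[i])
        candidates = np.where(d2[i] <= best * (1 + 1e-12))[0]
        # tie broken by lower cell_id
        nbr[i] = candidates[np.argmin(ids[candidates])]
    diffs = axial_difference(angles, angles[nbr])
    return NeighborAlignment(ids, ids[nbr], np.atleast_1d(diffs))


@dataclass
class ConcentricityResults:
    """Fitted concentricity analysis of one polarity field.

    Carries the fitted organ ellipse, the per-cell tangent deviations, the
    12-bin deviation histogram, the uniformity test, the axial von Mises
    fit of the deviations, and the Concentric / Not Concentric label
    (Concentric iff the uniformity test rejects at the model alpha).
    """

    ellipse: EllipseModel
    deviations: np.ndarray
    histogram: AngleHistogram
    uniform_test: UniformityTestResult
    vm_fit: VonMisesFit
    label: str
    alpha: float
    cell_ids: np.ndarray
    neighbor_alignment: Optional[NeighborAlignment] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def concentric(self) -> bool:
        return self.label == "Concentric"

    @property
    def p_value(self) -> float:
        return self.uniform_test.p_value

    def to_frame(self) -> pd.DataFrame:
        """Per-cell table of tangent deviations."""
        return pd.DataFrame({"cell_id": self.cell_ids,
                             "tangent_deviation_deg": self.deviations})

    def to_dict(self) -> dict:
        d = {
            "ellipse": self.ellipse.to_dict(),
            "deviations": list(map(float, self.deviations)),
            "cell_ids": list(map(int, self.cell_ids)),
            "histogram": self.histogram.to_dict(),
            "uniform_test": self.uniform_test.to_dict(),
            "vm_fit": self.vm_fit.to_dict(),
            "label": self.label,
            "alpha": float(self.alpha),
            "warnings": list(self.warnings),
        }
        if self.neighbor_alignment is not None:
            d["neighbor_alignment"] = {
                "cell_id": list(map(int, self.neighbor_alignment.cell_ids)),
                "neighbor_id": list(map(int, self.neighbor_alignment.neighbor_ids)),
                "difference_deg": list(map(float, self.neighbor_alignment.differences)),
            }
        return d

    def summary(self) -> str:
        e = self.ellipse
        u = self.uniform_test
        v = self.vm_fit
        lines = [
            "Concentricity analysis",
            "=" * 58,
            f"n cells                {len(self.deviations):>10d}",
            f"ellipse center         ({e.cx:10.3f}, {e.cy:10.3f}) px",
            f"semi-axes (a, b)       ({e.a:10.3f}, {e.b:10.3f}) px",
            f"rotation theta         {e.theta:10.3f} deg"
            + ("  [near-circular: theta ill-conditioned]" if e.conditioning_flag else ""),
            "-" * 58,
            f"uniformity chi-square  {u.statistic:10.4f}  (df = {u.df})",
            f"uniformity p-value     {u.p_value:10.4g}  (alpha = {self.alpha})",
            f"von Mises mu           {v.mu:10.3f} deg",
            f"von Mises kappa        {v.kappa:10.4f}"
            + ("  [capped]" if v.kappa_capped else ""),
            f"mean resultant length  {v.mean_resultant_length:10.4f}",
            "-" * 58,
            f"label                  {self.label:>10s}",
        ]
        for w in self.warnings + u.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


class ConcentricityModel:
    """Concentricity model for one annotated polarity field.

    Parameters
    ----------
    cells : sequence of CellRecord
        Annotated hair cells (positions + axial polarity angles, y-up frame).
    alpha : float
        Significance threshold for the uniformity test (default 0.01).
    n_bins : int
        Histogram bins over (-90, 90] (default 12).
    reference_cells : optional sequence of CellRecord
        If given, the ellipse is fitted to these cells' centers instead of
        the scored cells (e.g. fit to all cells, score hair cells only).
        Default: fit to the scored cells themselves.
    require_tangential_mu : bool
        Optional stricter label criterion additionally requiring
        |mu| < 30 degrees, since a strongly *radial* field is also
        non-uniform.  Off by default.
    """

    def __init__(self, cells: Sequence[CellRecord], alpha: float = 0.01,
                 n_bins: int = 12, reference_cells: Optional[Sequence[CellRecord]] = None,
                 require_tangential_mu: bool = False):
        self.cells = list(cells)
        self.alpha = float(alpha)
        self.n_bins = int(n_bins)
        self.reference_cells = list(reference_cells) if reference_cells is not None else None
        self.require_tangential_mu = bool(require_tangential_mu)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ConcentricityModel":
        """Build from a cell table with columns cell_id, x, y,
        axial_angle_deg (and optionally dir_angle_deg, cell_class)."""
        cells = []
        for _, row in df.iterrows():
            dir_angle = row.get("dir_angle_deg")
            if dir_angle is not None and pd.isna(dir_angle):
                dir_angle = None
            cells.append(CellRecord(
                cell_id=int(row["cell_id"]), x=float(row["x"]), y=float(row["y"]),
                axial_angle=float(row["axial_angle_deg"]),
                dir_angle=None if dir_angle is None else float(dir_angle),
                cell_class=str(row.get("cell_class", "hair")),
            ))
        return cls(cells, **kwargs)

    def fit(self, with_neighbors: bool = True) -> ConcentricityResults:
        """Run the pipeline: ellipse fit -> tangent deviations -> 12-bin
        histogram -> uniformity test -> von Mises fit -> label."""
        cells = self.cells
        if len(cells) < 3:
            raise ValueError("concentricity analysis requires >= 3 cells for the ellipse fit")
        warnings = []
        if len(cells) < MIN_CELLS:
            warnings.append(f"only {len(cells)} cells (< {MIN_CELLS}); result validity limited")
        ref = self.reference_cells if self.reference_cells is not None else cells
        ellipse = fit_ellipse_pca([(c.x, c.y) for c in ref])
        deviations = tangent_deviations(cells, ellipse)
        hist = bin_axial(deviations, self.n_bins)
        utest = chisq_uniform_test(hist, self.alpha)
        vm = fit_von_mises_axial(deviations)
        concentric = utest.significant
        if self.require_tangential_mu:
            concentric = concentric and abs(vm.mu) < 30.0
        label = "Concentric" if concentric else "Not Concentric"
        nbr = nearest_neighbor_alignment(cells) if (with_neighbors and len(cells) >= 2) else None
        return ConcentricityResults(
            ellipse=ellipse, deviations=deviations, histogram=hist,
            uniform_test=utest, vm_fit=vm, label=label, alpha=self.alpha,
            cell_ids=np.array([c.cell_id for c in cells]),
            neighbor_alignment=nbr, warnings=warnings,
        )


def concentricity_test(cells: Sequence[CellRecord], alpha: float = 0.01,
                       n_bins: int = 12, **kwargs) -> ConcentricityResults:
    """One-shot concentricity pipeline (see :class:`ConcentricityModel`)."""
    return ConcentricityModel(cells, alpha=alpha, n_bins=n_bins, **kwargs).fit()
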