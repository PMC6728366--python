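"""Rose diagrams and deviation histograms (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .circstats import AngleHistogram, VonMisesFit, von_mises_axial_pdf
from .orient import rose_counts

__all__ = ["rose_diagram", "deviation_histogram"]


def rose_diagram(dir_angles, n_bins: int = 12, ax=None, color="tab:blue"):
    """Polar rose diagram of directional angles over (-180, 180]."""
    counts = rose_counts(dir_angles, n_bins)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    width = 2 * np.pi / n_bins
    centers = -np.pi + width * (np.arange(n_bins) + 0.5)
    ax.bar(centers, counts, width=width, bottom=0.0, color=color,
           edgecolor="black", alpha=0.8)
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(1)
    return ax


def deviation_histogram(hist: AngleHistogram, vm_fit: VonMisesFit | None = None,
                        ax=None, color="tab:orange"):
    """Probability histogram of tangent deviations on (-90, 90], with the
    fitted axial von Mises density overlaid in red when provided."""
    if ax is None:
        _, ax = plt.subplots()
    widths = np.diff(hist.bin_edges)
    ax.bar(hist.bin_edges[:-1], hist.probabilities / widths, width=widths,
           align="edge", color=color, edgecolor="black", alpha=0.8)
    if vm_fit is not None:
        th = np.linspace(-90, 90, 361)
        ax.plot(th, von_mises_axial_pdf(th, vm_fit), color="red", lw=2)
    ax.set_xlabel("deviation from tangent (deg)")
    ax.set_ylabel("probability density (per deg)")
    ax.set_xlim(-90, 90)
    return ax
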