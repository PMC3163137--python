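"""Spatial statistics of vessel distribution around the tumor.

Two summaries of the vessel point pattern relative to the tumor:

* a histogram of vessel counts versus distance to the tumor edge, which
  reveals clustering (e.g. a bimodal pattern with a peritumoral cluster
  and a second population near the tissue border);
* a directional profile over eight 45°-wide sectors around the tumor mass
  centre, each carrying the linear vessel density (vessels per mm of
  radial depth) within a radial window — default (0, 2] mm — drawn as a
  polar graph to visualize anisotropy of the lymphatic network.

Angle convention: image coordinates are (row, col) with row 0 at the top,
so the angle of a vessel seen from the tumor centre is
``atan2(-(row - row_t), col - col_t)`` mapped to [0, 360): 0° points
right and angles increase counter-clockwise on the displayed image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .errors import UndefinedAngleError
from .quantification import VesselRecord

#: Centres (degrees) of the eight directional sectors.
SECTOR_CENTERS_DEG = (0, 45, 90, 135, 180, 225, 270, 315)
_SECTOR_WIDTH = 45.0


@dataclass
class DistanceProfile:
    """Binned vessel counts versus distance to the tumor (mm)."""

    bin_edges_mm: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray


@dataclass
class DirectionalProfile:
    """Vessel counts and linear densities per 45° sector around the tumor."""

    sector_centers_deg: np.ndarray
    sector_counts: np.ndarray
    linear_density_per_mm: np.ndarray
    radial_window_mm: tuple[float, float]


def distance_histogram(
    records: list[VesselRecord],
    bin_width_mm: float = 0.1,
    max_mm: float | None = None,
) -> DistanceProfile:
    """Histogram of vessel-to-tumor distances with half-open bins.

    Bins are ``[e_i, e_{i+1})``.  When ``max_mm`` is omitted the range
    extends to the smallest bin multiple strictly covering the largest
    distance, so every vessel falls in a bin; an explicit ``max_mm`` drops
    vessels at or beyond it.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be positive")
    distances = np.array([r.distance_to_tumor_mm for r in records], dtype=float)
    if max_mm is None:
        dmax = distances.max() if distances.size else 0.0
        n_bins = int(math.floor(dmax / bin_width_mm)) + 1
    else:
        n_bins = max(int(math.ceil(max_mm / bin_width_mm)), 1)
    edges = np.arange(n_bins + 1) * bin_width_mm
    # floor-index binning guarantees half-open bins exactly
    idx = np.floor(distances / bin_width_mm).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    total = counts.sum()
    normalized = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    return DistanceProfile(bin_edges_mm=edges, counts=counts, normalized=normalized)


def vessel_angle(
    centroid_rc: tuple[float, float], tumor_centroid_rc: tuple[float, float]
) -> float:
    """Angle (degrees in [0, 360)) of a vessel seen from the tumor centre."""
    dr = centroid_rc[0] - tumor_centroid_rc[0]
    dc = centroid_rc[1] - tumor_centroid_rc[1]
    if dr == 0 and dc == 0:
        raise UndefinedAngleError("vessel centroid coincides with tumor centre")
    return math.degrees(math.atan2(-dr, dc)) % 360.0


def sector_index(angle_deg: float) -> int:
    """Index of the 45°-wide sector containing an angle.

    Sector *s* covers ``[center_s - 22.5°, center_s + 22.5°)`` with
    wrap-around at 360°, so e.g. 22.5° belongs to the 45° sector.
    """
    return int(((angle_deg + _SECTOR_WIDTH / 2) % 360.0) // _SECTOR_WIDTH)


def directional_profile(
    records: list[VesselRecord],
    window_mm: tuple[float, float] = (0.0, 2.0),
) -> DirectionalProfile:
    """Sector counts and linear densities within a radial window.

    Vessels with ``low < distance <= high`` are assigned to sectors by
    their angle; the linear density of a sector is its count divided by
    the window length (vessels/mm).
    """
    low, high = window_mm
    if not low < high:
        raise ValueError(f"radial window must satisfy low < high, got {window_mm}")
    counts = np.zeros(len(SECTOR_CENTERS_DEG), dtype=np.int64)
    for rec in records:
        if low < rec.distance_to_tumor_mm <= high:
            counts[sector_index(rec.angle_deg)] += 1
    density = counts / (high - low)
    return DirectionalProfile(
        sector_centers_deg=np.array(SECTOR_CENTERS_DEG, dtype=float),
        sector_counts=counts,
        linear_density_per_mm=density,
        radial_window_mm=(float(low), float(high)),
    )


def polar_export(profile: DirectionalProfile, path: str | Path) -> tuple[Path, Path]:
    """Write a polar plot and a CSV of a directional profile.

    ``path`` may be a plot filename (``.png``/``.svg``; the CSV lands next
    to it) or an extensionless stem for both files.  Returns the two paths
    written (plot, csv).
    """
    path = Path(path)
    if path.suffix.lower() in (".png", ".svg"):
        plot_path = path
        csv_path = path.with_suffix(".csv")
    else:
        plot_path = path.with_suffix(".png")
        csv_path = path.with_suffix(".csv")

    frame = pd.DataFrame(
        {
            "sector_center_deg": profile.sector_centers_deg.astype(int),
            "count": profile.sector_counts,
            "density_per_mm": profile.linear_density_per_mm,
        }
    )
    frame.to_csv(csv_path, index=False)

    theta = np.deg2rad(profile.sector_centers_deg)
    theta = np.append(theta, theta[0])
    rho = np.append(profile.linear_density_per_mm, profile.linear_density_per_mm[0])
    fig = Figure(figsize=(5, 5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(projection="polar")
    ax.plot(theta, rho, marker="o", color="firebrick")
    ax.fill(theta, rho, color="firebrick", alpha=0.25)
    lo, hi = profile.radial_window_mm
    ax.set_title(f"Vessel density per unit length ({lo:g}-{hi:g} mm window)")
    fig.savefig(plot_path, dpi=120, bbox_inches="tight")
    return plot_path, csv_path
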