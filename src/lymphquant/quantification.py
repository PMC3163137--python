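"""Region geometry and lymphatic vessel density (LVD).

LVD is the number of lymphatic vessel sections per mm² of stromal tissue.
The stroma is operationalized as detected tissue minus the tumor mask,
and the peritumoral region as the tissue within a fixed straight-line
(Euclidean) distance of the tumor invasion edge — 2 mm by default.
Vessel-to-tumor distances are read off the exact Euclidean distance
transform of the tumor-mask complement at each vessel's centre of mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .errors import NoTumorError, RegistrationError, ZeroAreaError
from .imgio import BinaryMask

log = logging.getLogger(__name__)


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (µm) to the nearest tumor pixel."""

    values: np.ndarray
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class VesselRecord:
    """One detected vessel section and its geometry relative to the tumor.

    ``centroid_rc`` is the unweighted mean of the object's pixel
    coordinates; ``distance_to_tumor_mm`` is the distance-map value at the
    nearest integer pixel to the centroid; ``angle_deg`` is measured from
    the tumor mass centre, 0° pointing right and increasing
    counter-clockwise on the displayed image.
    """

    label: int
    centroid_rc: tuple[float, float]
    area_px: int
    area_um2: float
    distance_to_tumor_mm: float
    angle_deg: float


@dataclass
class LVDReport:
    """Vessel count and density over a named region."""

    region: str
    surface_mm2: float
    vessel_count: int
    lvd_per_mm2: float

    def to_dict(self) -> dict:
        return asdict(self)


def distance_map(tumor_mask: BinaryMask) -> DistanceMap:
    """Exact Euclidean distance transform of the tumor-mask complement.

    Each pixel holds ``pixel_size_um`` times its centre-to-centre distance
    (in pixels) to the nearest tumor pixel; tumor pixels hold 0.
    """
    if not tumor_mask.values.any():
        raise NoTumorError("tumor mask is empty: distance map undefined")
    dist_px = ndimage.distance_transform_edt(~tumor_mask.values)
    return DistanceMap(dist_px * tumor_mask.pixel_size_um, tumor_mask.pixel_size_um)


def peritumoral_mask(
    tumor_mask: BinaryMask,
    tissue_mask: BinaryMask,
    band_mm: float = 2.0,
) -> BinaryMask:
    """Tissue within ``band_mm`` of the tumor invasion edge.

    The band is open at 0 (tumor pixels excluded) and closed at
    ``band_mm``; it is intersected with the tissue mask, so glass inside
    the band does not count as peritumoral surface.
    """
    if tumor_mask.shape != tissue_mask.shape:
        raise RegistrationError(
            f"tumor {tumor_mask.shape} and tissue {tissue_mask.shape} masks "
            "must share a grid; decimate or upsample first"
        )
    dmap = distance_map(tumor_mask)
    band_um = band_mm * 1000.0
    values = (dmap.values > 0) & (dmap.values <= band_um) & tissue_mask.values
    return BinaryMask(values, tumor_mask.pixel_size_um, "peritumoral")


def stroma_mask(tissue_mask: BinaryMask, tumor_mask: BinaryMask) -> BinaryMask:
    """Stroma = tissue minus tumor, on a shared grid."""
    if tumor_mask.shape != tissue_mask.shape:
        raise RegistrationError("tissue and tumor masks must share a grid")
    return BinaryMask(
        tissue_mask.values & ~tumor_mask.values, tissue_mask.pixel_size_um, "stroma"
    )


def vessel_records(
    vessel_labels: np.ndarray,
    dmap: DistanceMap,
    tumor_centroid_rc: tuple[float, float],
    label_pixel_size_um: float | None = None,
) -> list[VesselRecord]:
    """Per-vessel centroid, area, tumor distance and angle.

    The label map and distance map share a grid by default; passing
    ``label_pixel_size_um`` allows a distance map computed on a coarser
    (decimated) grid, with centroids rescaled for the lookup.  An empty
    label map yields an empty list.  A centroid landing on a tumor pixel
    gets distance 0 with a logged warning; its angle is still computed
    from the tumor mass centre (given in label-grid coordinates).
    """
    from .spatialstats import vessel_angle  # local import to avoid a cycle
    from .errors import UndefinedAngleError

    vessel_labels = np.asarray(vessel_labels)
    if label_pixel_size_um is None:
        if vessel_labels.shape != dmap.shape:
            raise RegistrationError("label map and distance map must share a grid")
        label_pixel_size_um = dmap.pixel_size_um
    scale = label_pixel_size_um / dmap.pixel_size_um
    labels = np.unique(vessel_labels)
    labels = labels[labels > 0]
    if labels.size == 0:
        return []

    ones = np.ones_like(vessel_labels, dtype=np.float64)
    centroids = ndimage.center_of_mass(ones, vessel_labels, labels)
    areas = ndimage.sum_labels(ones, vessel_labels, labels).astype(np.int64)

    nrows, ncols = dmap.shape
    records: list[VesselRecord] = []
    for label, (cr, cc), area in zip(labels, centroids, areas):
        ri = min(max(int(round(cr * scale)), 0), nrows - 1)
        ci = min(max(int(round(cc * scale)), 0), ncols - 1)
        dist_mm = float(dmap.values[ri, ci]) / 1000.0
        if dist_mm == 0.0:
            log.warning("vessel %d centroid falls on a tumor pixel; distance 0", label)
        try:
            angle = vessel_angle((cr, cc), tumor_centroid_rc)
        except UndefinedAngleError:
            log.warning("vessel %d centroid coincides with tumor centre; angle set to 0", label)
            angle = 0.0
        records.append(
            VesselRecord(
                label=int(label),
                centroid_rc=(float(cr), float(cc)),
                area_px=int(area),
                area_um2=float(area) * label_pixel_size_um**2,
                distance_to_tumor_mm=dist_mm,
                angle_deg=float(angle),
            )
        )
    return records


def compute_lvd(
    records: list[VesselRecord],
    region_mask: BinaryMask,
    region_name: str,
    record_pixel_size_um: float | None = None,
) -> LVDReport:
    """Count vessels whose centroid lies in a region and divide by its surface.

    A vessel belongs to the region iff the nearest integer pixel to its
    centroid is true in ``region_mask``; a vessel straddling a region
    boundary therefore counts exactly once.  ``record_pixel_size_um``
    rescales record centroids when the region mask lives on a coarser
    (decimated) grid; by default records and mask share a grid.
    """
    surface = region_mask.area_mm2()
    if surface <= 0:
        raise ZeroAreaError(f"region {region_name!r} has zero surface")
    scale = 1.0
    if record_pixel_size_um is not None:
        scale = record_pixel_size_um / region_mask.pixel_size_um
    nrows, ncols = region_mask.shape
    count = 0
    for rec in records:
        ri = int(round(rec.centroid_rc[0] * scale))
        ci = int(round(rec.centroid_rc[1] * scale))
        if 0 <= ri < nrows and 0 <= ci < ncols and region_mask.values[ri, ci]:
            count += 1
    return LVDReport(
        region=region_name,
        surface_mm2=surface,
        vessel_count=count,
        lvd_per_mm2=count / surface,
    )


def lvd_from_counts(
    vessel_count: int, surface_mm2: float, region: str = "custom"
) -> LVDReport:
    """LVD from an externally determined count and surface.

    Useful for desk calculations and for comparing against counts obtained
    by other protocols (e.g. hot-spot fields).
    """
    if surface_mm2 <= 0:
        raise ZeroAreaError(f"region {region!r} has zero surface")
    if vessel_count < 0:
        raise ValueError("vessel_count must be non-negative")
    return LVDReport(
        region=region,
        surface_mm2=float(surface_mm2),
        vessel_count=int(vessel_count),
        lvd_per_mm2=vessel_count / surface_mm2,
    )
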