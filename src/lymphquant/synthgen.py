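"""Ground-truthed synthetic stained-slide generator.

Emulates the appearance of a podoplanin (permanent red) stained section on
a hematoxylin counterstain as seen by a slide scanner: a pinkish tissue
blob on near-white glass, lymphatic vessels rendered as red annular walls
around bright lumens, one or more tumor blobs in a distinct color, and
optional red "confounder" clumps inside the tumor margin that mimic
podoplanin-positive tumor cells.  Every rendered structure is recorded in
a ground-truth bundle so each pipeline stage can be scored without a real
slide.

A single seeded NumPy generator drives all placements and the pixel
noise, so a configuration plus a seed reproduces a slide bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import ConfigError, PlacementError
from .imgio import BinaryMask, SlideImage

# Palette (R, G, B).  Excess-red (2R-B-G): walls 260, tissue 50-90, glass -1,
# lumens -3, tumor 20 — a wide margin around the wall class so that
# default-config segmentation is near-perfect and failure modes can be
# probed by raising the noise instead.  Tissue blue is not flat: a smooth
# blotch field spreads it over ~150-190 like a real counterstain, which is
# what makes a percentile-based tissue threshold land at the top of the
# tissue mode instead of knife-edging through it.
GLASS_RGB = (245, 245, 248)
TISSUE_RGB = (220, 200, 170)  # blue varies 150-190 around this value
TISSUE_BLUE_RANGE = (150, 190)
WALL_RGB = (210, 60, 100)
LUMEN_RGB = (237, 236, 241)
TUMOR_RGB = (150, 120, 160)

_MAX_REJECTIONS = 10_000

#: Minimum clear gap between distinct structures (µm).  Two vessels closer
#: than this would be one object to any observer (and to any segmenter), so
#: the ground truth keeps them separable.
_MIN_GAP_UM = 5.0


@dataclass
class SynthConfig:
    """Layout and rendering parameters of a synthetic slide.

    Defaults describe the standard validation slide: a 2000x2000 px
    (1.3x1.3 mm at 0.65 µm/px) section with 50 vessels of 15-45 µm lumen
    radius, a single central tumor blob, and mild sensor noise.
    """

    image_size_px: tuple[int, int] = (2000, 2000)
    pixel_size_um: float = 0.65
    n_vessels: int = 50
    vessel_radius_um: tuple[float, float] = (15.0, 45.0)
    wall_thickness_um: float = 3.0
    n_tumor_blobs: int = 1
    tumor_radius_um: tuple[float, float] = (150.0, 260.0)
    anisotropy: tuple[float, float] | None = None
    clustering_band_mm: tuple[float, float] | None = None
    n_confounders: int = 0
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 0:
            raise ConfigError("n_vessels must be >= 0")
        if self.n_tumor_blobs < 0:
            raise ConfigError("n_tumor_blobs must be >= 0")
        if self.n_confounders < 0:
            raise ConfigError("n_confounders must be >= 0")
        if min(self.vessel_radius_um) <= 0 or min(self.tumor_radius_um) <= 0:
            raise ConfigError("radii must be positive")
        if self.wall_thickness_um <= 0:
            raise ConfigError("wall_thickness_um must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown SynthConfig keys: {sorted(unknown)}")
        for key in ("image_size_px", "vessel_radius_um", "tumor_radius_um",
                    "anisotropy", "clustering_band_mm"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class GroundTruth:
    """Everything the generator knows about what it rendered."""

    vessel_label_map: np.ndarray
    tumor_mask: BinaryMask
    tissue_mask: BinaryMask
    confounder_mask: BinaryMask
    vessels: pd.DataFrame  # label, row, col, lumen_radius_um, outer_radius_um,
    #                        distance_mm, angle_deg
    tumor_centroid_rc: tuple[float, float] | None

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float
          ) -> tuple[slice, slice, np.ndarray]:
    """Boolean disc restricted to its bounding box (returns slices + local mask)."""
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, shape[1])
    rr, cc = np.ogrid[r0:r1, c0:c1]
    local = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return slice(r0, r1), slice(c0, c1), local


def _angle_in_interval(angle: float, interval: tuple[float, float]) -> bool:
    lo, hi = interval
    lo %= 360.0
    hi %= 360.0
    if lo < hi:
        return lo < angle < hi
    return angle > lo or angle < hi  # interval wraps through 0


def generate_slide(config: SynthConfig | None = None) -> tuple[SlideImage, GroundTruth]:
    """Render one synthetic slide with full ground truth.

    Placement is by rejection sampling: vessels must sit wholly inside the
    tissue, clear of the tumor, of each other and of the glass margin, and
    satisfy any anisotropy / radial-clustering constraint.  Exceeding
    10,000 consecutive rejections raises :class:`PlacementError` naming
    the structure that failed.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.image_size_px
    ps = config.pixel_size_um
    shape = (nrows, ncols)

    # --- tissue: centred ellipse with a glass margin -----------------------
    rr, cc = np.ogrid[:nrows, :ncols]
    cy, cx = (nrows - 1) / 2.0, (ncols - 1) / 2.0
    ay, ax = 0.46 * nrows, 0.46 * ncols
    tissue = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    tissue_depth = ndimage.distance_transform_edt(tissue)  # px to tissue edge

    # --- tumor blobs -------------------------------------------------------
    tumor = np.zeros(shape, dtype=bool)
    r_lo, r_hi = (r / ps for r in config.tumor_radius_um)
    for i in range(config.n_tumor_blobs):
        radius = rng.uniform(r_lo, r_hi)
        for attempt in range(_MAX_REJECTIONS):
            # bias the first blob toward the centre so a peritumoral band fits
            jitter = 0.15 if i == 0 else 0.5
            center = (
                cy + rng.uniform(-jitter, jitter) * nrows,
                cx + rng.uniform(-jitter, jitter) * ncols,
            )
            if tissue_depth[int(center[0]) % nrows, int(center[1]) % ncols] > radius + 4:
                break
        else:
            raise PlacementError(
                f"tumor blob {i}: no position keeps radius {radius:.0f}px inside tissue"
            )
        sr, sc, local = _disc(shape, center, radius)
        tumor[sr, sc] |= local

    if tumor.any():
        tumor_dist_px = ndimage.distance_transform_edt(~tumor)
        coords = np.argwhere(tumor)
        tumor_centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    else:
        tumor_dist_px = np.full(shape, np.inf)
        tumor_centroid = None

    # --- vessels -----------------------------------------------------------
    label_map = np.zeros(shape, dtype=np.int32)
    gap_px = _MIN_GAP_UM / ps
    wall_px = config.wall_thickness_um / ps
    lumen_lo, lumen_hi = (r / ps for r in config.vessel_radius_um)
    placed: list[tuple[float, float, float]] = []  # row, col, outer radius
    rows_t: list[dict] = []
    walls = np.zeros(shape, dtype=bool)
    lumens = np.zeros(shape, dtype=bool)

    for i in range(config.n_vessels):
        lumen_r = rng.uniform(lumen_lo, lumen_hi)
        outer_r = lumen_r + wall_px
        failures = 0
        while True:
            center = (rng.uniform(0, nrows), rng.uniform(0, ncols))
            ri, ci = int(center[0]), int(center[1])
            ok = tissue_depth[ri, ci] > outer_r + gap_px
            ok = ok and tumor_dist_px[ri, ci] > outer_r + gap_px
            if ok:
                for pr, pc, pradius in placed:
                    if (center[0] - pr) ** 2 + (center[1] - pc) ** 2 <= (
                        pradius + outer_r + gap_px
                    ) ** 2:
                        ok = False
                        break
            if ok and tumor_centroid is not None:
                dist_mm = tumor_dist_px[ri, ci] * ps / 1000.0
                if config.anisotropy is not None:
                    from .spatialstats import vessel_angle

                    angle = vessel_angle(center, tumor_centroid)
                    ok = _angle_in_interval(angle, config.anisotropy)
                if ok and config.clustering_band_mm is not None:
                    lo, hi = config.clustering_band_mm
                    ok = lo < dist_mm <= hi
            if ok:
                break
            failures += 1
            if failures > _MAX_REJECTIONS:
                raise PlacementError(
                    f"vessel {i}: {failures} rejections; constraints "
                    "(tissue fit / tumor clearance / overlap / anisotropy / "
                    "clustering band) cannot be met at this density"
                )
        placed.append((center[0], center[1], outer_r))
        sr, sc, outer = _disc(shape, center, outer_r)
        rr_l, cc_l = np.ogrid[sr, sc]
        inner = (rr_l - center[0]) ** 2 + (cc_l - center[1]) ** 2 <= lumen_r**2
        walls[sr, sc] |= outer & ~inner
        lumens[sr, sc] |= inner
        label_map[sr, sc][outer] = i + 1

        if tumor_centroid is not None:
            from .spatialstats import vessel_angle

            ri = min(max(int(round(center[0])), 0), nrows - 1)
            ci = min(max(int(round(center[1])), 0), ncols - 1)
            dist_mm = float(tumor_dist_px[ri, ci]) * ps / 1000.0
            angle = vessel_angle(center, tumor_centroid)
        else:
            dist_mm = float("nan")
            angle = float("nan")
        rows_t.append(
            {
                "label": i + 1,
                "row": center[0],
                "col": center[1],
                "lumen_radius_um": lumen_r * ps,
                "outer_radius_um": outer_r * ps,
                "distance_mm": dist_mm,
                "angle_deg": angle,
            }
        )

    # --- confounders: red clumps inside the tumor margin -------------------
    confounders = np.zeros(shape, dtype=bool)
    if config.n_confounders > 0:
        if not tumor.any():
            raise PlacementError("confounders require at least one tumor blob")
        tumor_depth = ndimage.distance_transform_edt(tumor)
        clump_r = max(6.0, 3.0 / ps)
        extent = clump_r * 2.5
        clump_centers: list[np.ndarray] = []
        for i in range(config.n_confounders):
            candidates = np.argwhere(tumor_depth > extent + 2)
            if candidates.size == 0:
                raise PlacementError(f"confounder {i}: tumor too small for clump")
            for _ in range(_MAX_REJECTIONS):
                center = candidates[rng.integers(len(candidates))].astype(float)
                # clumps stay mutually separate so each is one excludable object
                if all(np.hypot(*(center - c)) > 2 * extent + gap_px
                       for c in clump_centers):
                    break
            else:
                raise PlacementError(f"confounder {i}: no separated position in tumor")
            clump_centers.append(center)
            for _ in range(3):  # small overlapping discs -> irregular clump
                jit = center + rng.uniform(-clump_r, clump_r, size=2)
                sr, sc, local = _disc(shape, tuple(jit), clump_r)
                confounders[sr, sc] |= local
        confounders &= tumor  # never encroach on stroma or vessels

    # --- compose and add noise --------------------------------------------
    img = np.empty((*shape, 3), dtype=np.float64)
    img[:] = GLASS_RGB
    img[tissue] = TISSUE_RGB
    # counterstain texture: smooth blotch field over the tissue blue channel
    coarse = rng.normal(size=(nrows // 64 + 2, ncols // 64 + 2))
    blotch = np.kron(coarse, np.ones((64, 64)))[:nrows, :ncols]
    blotch = ndimage.gaussian_filter(blotch, 32)
    std = blotch.std() or 1.0
    lo_b, hi_b = TISSUE_BLUE_RANGE
    mid = (lo_b + hi_b) / 2.0
    # +/-3 sigma spans the stated range, so clipping stays negligible and the
    # decimated blue histogram keeps a smooth tissue hump
    blue_field = np.clip(mid + blotch * ((hi_b - lo_b) / 6.0) / std, lo_b, hi_b)
    img[..., 2][tissue] = blue_field[tissue]
    img[tumor] = TUMOR_RGB
    img[lumens] = LUMEN_RGB
    img[walls] = WALL_RGB
    img[confounders] = WALL_RGB
    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        vessel_label_map=label_map,
        tumor_mask=BinaryMask(tumor, ps, "tumor"),
        tissue_mask=BinaryMask(tissue, ps, "tissue"),
        confounder_mask=BinaryMask(confounders, ps, "confounder"),
        vessels=pd.DataFrame(
            rows_t,
            columns=["label", "row", "col", "lumen_radius_um",
                     "outer_radius_um", "distance_mm", "angle_deg"],
        ),
        tumor_centroid_rc=tumor_centroid,
    )
    return SlideImage(pixels, ps), truth


def generate_anisotropic_case(seed: int) -> tuple[SlideImage, GroundTruth]:
    """Slide with all vessels confined to the 90°-270° half, within 2 mm.

    Reproduces the qualitative scenario of a lymphatic network clustered
    on one side of the tumor, which the directional profile should report
    as empty sectors at 315°, 0° and 45°.
    """
    config = SynthConfig(
        seed=seed,
        anisotropy=(90.0, 270.0),
        clustering_band_mm=(0.0, 2.0),
    )
    return generate_slide(config)


def exclusion_from_confounders(truth: GroundTruth, dilation_px: int = 3) -> BinaryMask:
    """Exclusion mask covering the rendered confounder clumps.

    Stands in for an annotator circling non-lymphatic podoplanin-positive
    detections: the confounder mask dilated a few pixels so segmentation
    boundary noise cannot slip an object past it.
    """
    values = ndimage.binary_dilation(
        truth.confounder_mask.values, iterations=dilation_px
    )
    return BinaryMask(values, truth.confounder_mask.pixel_size_um, "exclusion")


def evaluate_detection(
    detected_labels: np.ndarray,
    truth_labels: np.ndarray,
    iou_threshold: float = 0.3,
) -> dict:
    """Match detected objects to ground-truth vessels by IoU.

    Greedy one-to-one matching in decreasing IoU order; a pair matches if
    its intersection-over-union is at least ``iou_threshold``.  Returns
    recall, precision and the raw counts.
    """
    detected_labels = np.asarray(detected_labels)
    truth_labels = np.asarray(truth_labels)
    if detected_labels.shape != truth_labels.shape:
        raise ValueError("label maps must share a shape")

    true_ids, true_areas = np.unique(truth_labels[truth_labels > 0], return_counts=True)
    det_ids, det_areas = np.unique(detected_labels[detected_labels > 0], return_counts=True)
    n_true, n_det = len(true_ids), len(det_ids)
    if n_true == 0 or n_det == 0:
        return {
            "recall": 0.0 if n_true else 1.0,
            "precision": 0.0 if n_det else 1.0,
            "n_true": n_true,
            "n_detected": n_det,
            "n_matched": 0,
        }

    overlap = (truth_labels > 0) & (detected_labels > 0)
    pair_key = (
        truth_labels[overlap].astype(np.int64) * (detected_labels.max() + 1)
        + detected_labels[overlap]
    )
    keys, inter = np.unique(pair_key, return_counts=True)
    t_of = dict(zip(true_ids, true_areas))
    d_of = dict(zip(det_ids, det_areas))
    base = detected_labels.max() + 1
    pairs = []
    for key, n_inter in zip(keys, inter):
        t_id, d_id = int(key // base), int(key % base)
        union = t_of[t_id] + d_of[d_id] - n_inter
        iou = n_inter / union
        if iou >= iou_threshold:
            pairs.append((iou, t_id, d_id))
    pairs.sort(reverse=True)
    matched_t: set[int] = set()
    matched_d: set[int] = set()
    for _, t_id, d_id in pairs:
        if t_id not in matched_t and d_id not in matched_d:
            matched_t.add(t_id)
            matched_d.add(d_id)
    n_matched = len(matched_t)
    return {
        "recall": n_matched / n_true,
        "precision": n_matched / n_det,
        "n_true": n_true,
        "n_detected": n_det,
        "n_matched": n_matched,
    }
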