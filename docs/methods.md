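# Methods

This note records how the pipeline is defined, the parameters that
matter, what the synthetic slides do and do not emulate, and the design
choices taken where the published description of this class of methods
leaves room.

## Segmentation chain

**Excess red.** `ER = 2R − B − G`, computed signed in [−510, 510] with
no clamping. For a permanent-red stain on a hematoxylin counterstain the
transform separates endothelium (ER ≳ 250) from pink tissue
(ER ≈ 50–90), glass and lumens (ER ≈ 0) and tumor.

**Maximum-entropy wall threshold (Kapur–Sahoo–Wong).** The ER histogram
is built with one bin per integer level over the occupied range (not 256
fixed bins — ER is signed), and the threshold maximizes the sum of the
Shannon entropies of the two classes. Empty-class splits are skipped;
exact criterion ties resolve to the lowest threshold, so results are
reproducible bit for bit. The threshold is computed once, globally, per
image.

*Red-dominance gate.* Entropy thresholding has a known failure mode when
the stained class is tiny or absent: the criterion then prefers to split
the high-entropy unstained tissue hump, turning the whole tissue into
"foreground". Wall pixels must therefore also satisfy
`R − max(G, B) ≥ min_red_dominance` (default 40). Counterstained tissue
has a red margin of ~20, stained endothelium ≥ 100, so the gate is inert
on ordinary slides and only suppresses the degenerate regime (it is what
makes a vessel-free slide yield zero vessels rather than one giant one).

**Moment-preserving tissue threshold (Tsai).** Applied to the blue
channel after 8× block-mean decimation. The first three grey-level
moments determine two representative levels `z0 < z1` and a background
fraction `p0`; the threshold is the smallest level whose cumulative
histogram fraction reaches `p0`. Tissue is the darker-blue class
(`tissue_polarity` config inverts this for unusual stains). Degenerate
moment systems (single level, zero variance, no real root pair) raise a
dedicated error rather than returning an arbitrary level.

**Lumens.** Candidates are pixels inside the tissue mask with luminance
`(R+G+B)/3` above `lumen_bg_fraction` (default 0.90) of the mean
luminance *outside* the tissue mask — the threshold adapts to the
slide's glass brightness, which is the behavior one wants from "lightest
structures relative to the background". Components are kept only when
their 1-px 8-connected dilation touches a wall, so bright holes and
blood-vessel lumens far from stained walls are rejected. A collapsed
vessel (no bright interior) is still counted from its wall alone.

**Assembly.** Vessel objects are the hole-filled union of walls and kept
lumens, labeled with 8-connectivity. Hole-filling makes each vessel one
solid object even where the lumen threshold missed interior pixels. An
exclusion mask (raster or GeoJSON polygons) removes whole objects it
touches — the programmatic stand-in for an annotator circling
podoplanin-positive tumor cells or epidermis; removed labels are
reported, never silently dropped.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `pixel_size_um` | 0.65 | µm/px | physical scale; only defaulted when neither argument nor file metadata provides it (warning logged) |
| `min_wall_area_px` | 20 | px | speck removal; ≈ 8.5 µm² at 0.65 µm/px, below any vessel section. Raising it can only reduce the vessel count (monotone) |
| `min_red_dominance` | 40 | grey levels | chromaticity gate on wall pixels (see above) |
| `lumen_bg_fraction` | 0.90 | — | lumen luminance threshold as a fraction of mean background luminance |
| `tissue_decimation_factor` | 8 | — | block-mean decimation of the blue channel before tissue thresholding |
| quantification decimation | 4 | — | block-OR decimation of masks for region geometry (distance map, stroma, band); 1 = full-resolution reference. At 4 the demo LVD differs from full resolution by ~0.2% |
| `band_mm` | 2.0 | mm | peritumoral band width from the tumor invasion edge |
| sector window | (0, 2] | mm | radial window of the directional profile; the region of interest around the tumor is ~2–3 mm, so the upper bound is configurable |

## Geometry conventions

Raster coordinates are (row, col), 0-based, row 0 at the top. Angles
seen from the tumor mass centre are `atan2(−Δrow, Δcol)` mapped to
[0, 360): 0° points right, 90° up on the displayed image,
counter-clockwise positive. The tumor mass centre is the unweighted
centroid of all tumor pixels, even for disconnected bundles. The eight
directional sectors are 45°-wide wedges centred on 0°, 45°, …, 315°,
half-open at the lower edge (22.5° belongs to the 45° sector). The
radial window is open at its lower bound and closed at the upper. Linear
density is sector count divided by window length (vessels/mm) — this
concretizes "density per unit length" with interpretable units, rather
than a normalized-frequency area.

Distances use the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`) of the tumor-mask complement,
scaled by the pixel size; a vessel's distance is the map value at the
nearest integer pixel to its centre of mass. The peritumoral band uses
straight-line distance; a geodesic-through-tissue reading ("within 2 mm
*of tissue*") is defensible but not implemented. Region membership is by
centroid, so a vessel straddling the band boundary counts exactly once.
Binary masks decimate by block-OR (presence-preserving — no vessel may
vanish), grey channels by block mean; edge blocks pool over the pixels
they actually contain; a k-decimated mask carries k× the pixel size.

The stroma is operationalized as tissue minus tumor. In the pipeline the
full-resolution tissue mask is first completed with the detected vessel
objects: lumens are glass-bright and would otherwise punch holes in the
thresholded tissue exactly where vessel centroids lie.

## Synthetic slides

The generator renders what the segmentation chain assumes: near-white
glass (245,245,248), a pink tissue ellipse whose blue channel is a
smooth blotch field spanning 150–190 (a *flat* tissue color is
unrealistic and makes any percentile-type threshold knife-edge through
the single tissue grey level), tumor blobs in a distinct purple
(150,120,160) whose blue sits inside the tissue range, vessels as
permanent-red annuli (210,60,100) of 3 µm wall thickness (endothelium is
a thin cell layer; thick near-black-blue walls would leave pure-wall
decimated blocks that skew the third grey-level moment and displace the
tissue threshold) around near-white lumens, and optional red confounder
clumps inside the tumor margin mimicking podoplanin-positive tumor
cells. Gaussian pixel noise (σ = 8 by default, a mild sensor level) is
added last; a single seeded generator drives all placement and noise, so
a config + seed is bit-reproducible.

Placement is rejection sampling with a 5 µm minimum clear gap between
structures: two vessels closer than the staining resolution would be one
object to any observer, so the ground truth guarantees separability.
Constraint-violating configurations fail loudly after 10⁴ rejections.
The default validation slide is 2000×2000 px (1.3×1.3 mm at 0.65 µm/px)
with 50 vessels of 15–45 µm lumen radius and one central tumor blob —
sizes chosen so twenty slides run through the full pipeline in about a
minute on one CPU. The anisotropic case confines all vessels to the
90°–270° half-plane within 2 mm of the tumor, the scenario in which the
polar profile must show empty right-facing sectors.

What the synthetic slides do **not** emulate: staining texture and
gradients within walls, partial/weak staining, overlapping or collapsed
vessel morphologies beyond the no-lumen case, tissue folds, edge
artifacts, and out-of-focus blur. Passing the synthetic validation
therefore demonstrates the correctness of the *computational* chain
under the stated color model, not staining-quality robustness on
clinical material — the same caveat the underlying staining-dependent
method carries.

## Numerical choices and degenerate inputs

- Histogram thresholds return integer grey values; both thresholders
  raise `DegenerateHistogramError` on single-level histograms (e.g. an
  all-glass image).
- Tsai's percentile lookup uses a 1e-9 tolerance on the cumulative
  fraction so an exactly-two-level histogram thresholds at its lower
  level instead of being tipped over it by float rounding.
- Distance histograms bin by `floor(d / width)`, guaranteeing half-open
  bins exactly; the automatic range extends one bin beyond the largest
  distance so no vessel is dropped.
- A vessel centroid falling on a tumor pixel gets distance 0 with a
  logged warning; a centroid coinciding with the tumor mass centre has
  no defined angle and is recorded with angle 0 plus a warning.
- An empty vessel label map yields an empty record list, not an error;
  an empty region mask raises (a density over zero surface is
  meaningless).
- Hard failure paths (`noise_sigma = 30`, faint staining) reduce recall
  monotonically — the suite checks the direction, not a fixed value.

## Known limitations

- Whole-slide streaming is out of scope: inputs are tiles or
  downsampled slides that fit in memory.
- Tumor delineation is an input (manual mask or polygons); no
  cytokeratin-based auto-delineation.
- The exclusion mask replaces interactive removal of non-lymphatic
  detections; nothing discriminates podoplanin-positive tumor cells
  automatically.
- The 2 mm band is straight-line, not geodesic through tissue.
- Whether a minimum-size filter or per-tile thresholding is "canonical"
  for this method family is unstated in the literature it comes from;
  both choices here (global threshold, 20 px filter) are explicit
  config.
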