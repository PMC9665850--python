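# Methods

## Pipeline

`netquant` quantifies NETosis from registered two-channel micrographs: a
total-DNA stain and a NET-reporting antibody stain. Per field of view the
pipeline is threshold → connected components → size gate → count, run once
on the DNA channel for total cells and once on the marker channel for NETs,
followed by %NETs = 100·n_net/n_total. The two regimes differ only in the
marker-channel threshold: the automatic regime applies the same Bernsen
local threshold as the DNA channel; the manual regime applies a fixed
global cutoff chosen by the operator to exclude dim resting nuclei. Totals
are always counted automatically, in both regimes.

## Bernsen thresholding

Each pixel is compared against the midgray of the min/max over a circular
neighborhood (disk of radius `bernsen_radius`, center included). If the
local contrast (max − min) reaches `bernsen_contrast`, the pixel is
foreground iff its intensity strictly exceeds the midgray; otherwise the
whole region is deemed uniform and is foreground iff the midgray reaches
half the full bit-depth scale (128 for 8-bit, 32768 for 16-bit).

Numerical choices, fixed so results are exactly reproducible:

* **Borders.** Neighborhoods are clipped at the image border; no padding
  value ever participates. The implementation uses scipy's min/max filters
  with `mode="nearest"`: an out-of-bounds coordinate is clamped per axis,
  which can only shrink each axis offset, so the clamped pixel is itself
  inside the disk and in bounds — the filter output is therefore exactly the
  clipped-neighborhood min/max. A brute-force per-pixel oracle in the test
  suite verifies this equivalence on random images including radii larger
  than one image dimension.
* **Strict inequalities.** Foreground requires `I > mid` (and `I > t` for
  the global threshold). The low-contrast rule uses `mid >= half-scale`.
* **Defaults.** radius 15 px, contrast 35 — the published operating point of
  the automatic workflow. `contrast = 0` forces every pixel into the
  high-contrast branch.

## Particle analysis

Components are labeled with 8-connectivity by default (4 available),
deterministically numbered by raster-scan order of each component's first
pixel. Size gates are inclusive at both ends, matching ImageJ size-range
semantics: totals at ≥ 25 px² (10×) / 100 px² (20×), NETs at ≥ 75 px²
(10×) / 250 px² (20×). Areas are raw pixel counts, never calibrated µm²:
the published gates are unitless particle sizes from uncalibrated analysis,
and keeping pixels removes any hidden dependence on pixel-size metadata.
The upper gate defaults to infinity and exists to exclude fused structures
that cannot be assigned to individual cells. Objects touching the image
border are retained — excluding them would bias counts against exactly the
large structures being quantified.

Per object we record area, centroid, per-channel cumulative intensities,
and the circumference as an ordered coordinate list: outer-boundary pixels
(object pixels with an 8-neighbor in the background or outside the image)
traced clockwise by Moore-neighbor tracing from the topmost-then-leftmost
pixel, 0-based (row, col), origin top-left.

## Quality score and exclusion

`q` = (DNA-foreground pixels inside accepted objects) / (all DNA-foreground
pixels), computed against the total-cell gate, since that is the object set
assignable to individual cells or NETs. A field with zero DNA foreground
scores 0 and is flagged degenerate. `min_quality` defaults to 0.5 — a field
is kept when at least half its stained area is assignable; no published
cutoff exists, so the value is configurable and always written to the run
report. Exclusion only flags reports; rows are never dropped before
aggregation, which skips flagged fields and warns when a group empties.

## Time-course classification

Per-object mean marker intensity (sum/area) is divided by the maximum
per-object mean over the entire series — all fields and all time points, not
per image — so normalized values are comparable across the time course and
lie in (0, 1] with at least one object at exactly 1. An object is classified
`net` iff area ≥ the NET area gate AND normalized intensity ≥
`intensity_min_net` (default 0.3; no published value, configurable,
recorded). Ties classify as net. One global intensity cutoff is used for
the whole series rather than per-time-point cutoffs, consistent with
series-wide normalization. An all-zero series raises a
degenerate-normalization error rather than silently producing NaNs.

## Overlap coefficient

The Manders overlap R = Σab / √(Σa²·Σb²) over raw intensities, optionally
restricted to an ROI mask. No automatic background subtraction or channel
thresholding is applied — background handling is the caller's explicit
choice via the ROI. R is bounded in [0,1], symmetric, and invariant to
positive rescaling of either channel.

## Synthetic data generator

The generator emulates the three cell states the classifier must separate,
at the analysis scale of a 20× (or 10×) field:

* **resting** nuclei: unions of 2–4 jittered ellipses (lobulated), area
  drawn from [min_area_total, min_area_net) — detected as cells, never as
  NETs;
* **spread** cells: larger lobed footprints (3–5 ellipses), area in
  [min_area_net, 2·min_area_net), with weaker DNA staining — the
  early-time-point confounder: NET-sized, dimly stained;
* **NETs**: super-ellipses with Gaussian-blurred (σ = 2 px) soft edges,
  area in [2.2, 3.2)·min_area_net.

Channels are rendered as background (mean 16) plus per-class mean times the
footprint profile, plus additive Gaussian noise (sd 3), clipped to 8-bit.
Two stain models fix the marker means: `d3d9_like` (resting 18 / spread 20 /
net 200 — only NETs stained above background) and `chromatin_like`
(resting 200 / spread 150 / net 220 — everything stained). DNA means are
180/140/170. These levels were chosen once so that every object clears the
Bernsen contrast threshold in the channel where it should be detected while
the camera-noise range across a radius-15 disk stays well below contrast 35
(sd 3 gives a background min–max range around 19), i.e. the generator
emulates the published operating point where thresholding is
noise-robust. With time courses, the NET marker mean under `d3d9_like`
ramps linearly from background at 120 min to full at 180 min, reflecting an
epitope that appears only once decondensation has begun; the pan-chromatin
model is time-independent.

Objects are placed by rejection sampling with a bounding-circle clearance
of 14 px (covering the 3σ blur tail and 8-connectivity), so footprints are
pairwise disjoint and segmentable exactly; a retry cap turns impossible
densities into an explicit error. A single seeded generator stream drives
shapes, placement and noise, making every field bit-reproducible. NET
interiors carry no additional texture: interior intensity modulation would
create local contrast near the Bernsen cutoff and make interior pixels a
coin flip, adding variance without testing anything the pipeline claims.

What the generator does **not** emulate: optics (PSF, uneven illumination,
vignetting), photon (Poisson) noise, overlapping or touching cells,
out-of-focus planes, or the textures of real chromatin. Passing the
synthetic suite therefore demonstrates the correctness of the measurement
pipeline and the direction of the antibody-dependent bias — not performance
on real micrographs, where segmentation quality dominates.

## Problem sizes

The test suite and the acceptance script use 512×512 fields (20 per
recovery experiment, 6 per stain-comparison), 200 random ≤ 48×48 images for
the thresholding oracle, and ≤ 48×48 masks for the labeling oracle; these
sizes give exact expected counts and stable means while keeping a full run
in the one-minute range on a single CPU.

## Known limitations

* Touching cells are not split (no watershed); the workflow relies on the
  upper size gate to exclude fusions, as published.
* The manual regime models the operator's threshold as a given constant;
  choosing it is outside the package.
* %NETs can exceed 100 when the marker channel fragments differently from
  the DNA channel; it is reported unclamped with a warning.
* 8- and 16-bit integer TIFFs only; float and RGB inputs are rejected
  rather than coerced.
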