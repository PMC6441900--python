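# Methods

`dyadscape` quantifies cardiomyocyte t-tubule architecture, dyadic protein
organization, Ca²⁺-release synchrony, t-tubule electrical activation, and
surface topography from 2D fluorescence micrographs, time-lapse stacks, and
Z-spine annotation tables. This note documents the models and procedures, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not emulate.

## Image preprocessing (`image_core`)

All pipelines share a calibrated-image layer (`Image2D`, `VideoStack`: pixel
size in µm, frame interval in ms) and the following operators.

**Rolling-ball background subtraction** is implemented as grey-scale
morphological opening with a disk structuring element of the stated radius
(15 px for membrane stains, 20 px for immunolabels), subtracted from the image
and clipped at zero. The opening is the deterministic analogue of the
paraboloid rolling ball: a flat background is removed exactly, structures
smaller than the ball survive, and no pixel ever increases.

**Rotation to horizontal.** The cell footprint is found by Otsu thresholding,
closing with a ~1 µm disk (bridging the gaps of a striated stain), keeping the
largest connected component, filling holes, and taking the convex hull —
appropriate because rod-shaped myocytes are close to convex, and robust when a
sparse tubule network does not enclose the interior. The long-axis angle comes
from the footprint's second central moments (ties for circular cells resolve
to 0°); the image is rotated by its negative with bilinear interpolation and
zero padding. When the operand image has already been background-subtracted
(which flattens a featureless cell body entirely), the footprint is estimated
from the raw micrograph and the same rotation applied to both.

**Interior ROI.** The rotated footprint eroded inward by 1 µm (configurable
`roi_margin_um`) approximates a region traced just inside the surface
sarcolemma. The 1 µm default is this package's documented choice.

**Contrast enhancement** clips 0.8% of pixels in total, split evenly between
the two tails (0.4% per tail, matching common macro-platform semantics), and
maps the remaining range linearly onto [0, 255]. The mapping is monotone;
constant images pass through unchanged.

**Mexican hat** is an inverted Laplacian of Gaussian with the named radius
interpreted as the kernel half-width; the Gaussian scale defaults to
σ = 0.55·radius. The scale was calibrated on synthetic ridge grids so that
Otsu segmentation of the response reproduces the underlying ridge width
without systematic thinning or fattening (a naive σ = radius inflates apparent
tubule width several-fold). The truncated kernel's DC gain is removed exactly,
so a constant image maps to zero response; negative responses are clipped.

**Otsu thresholding** maximizes between-class variance over 256 equal-width
bins spanning the observed intensity range, with class means computed from
per-bin intensity sums (not bin centres), so the selected threshold is exactly
the bin edge that the exhaustive pixel-partition search would select. Values
lying exactly on a bin edge count to the lower class, consistent with the
returned mask being `pixels > threshold`. Constant images raise a
`DegenerateImageError`.

## T-tubule morphometry (`tubule_morphometry`)

Segmentation applies, in order: background subtraction (15 px), rotation to
horizontal, contrast enhancement (0.8%), Mexican hat (r = 3), median filter
(disk, r = 1), Otsu; the mask is clipped to the cell footprint. **Density** is
the percentage of interior-ROI area covered by the mask. A featureless
interior yields an empty mask rather than a failure.

**Skeletonization and branch labels.** The mask is thinned to one-pixel width
(topology-preserving). Junctions are pixels whose Rutovitz crossing number
(0→1 transitions around the 8-neighbour ring) is ≥ 3 — unlike a raw neighbour
count this does not flag the pixels flanking a T-junction, so junctions stay
single-pixel and branch lengths are not eroded. Branches are traced from each
junction outward along non-junction pixels, terminating at the next junction;
junction pixels belong to no branch (their count is reported separately).
Branch orientation is the principal (PCA) direction of the pixel path, in
(−90°, 90°] versus the image horizontal. A branch is **transverse** when its
direction lies within 45° of the image vertical (i.e. it runs across the
horizontally oriented cell) and **longitudinal** otherwise; the symmetric 45°
cut is this package's reconstruction — the angular criterion of the original
macro is not published. Branches shorter than 3 px inherit the label of their
longest neighbouring branch (tie or no neighbour → transverse). Lengths use
the 8-connected step metric (1 or √2 pixel units, scaled to µm), unbiased for
diagonal branches; orientation fractions are length-weighted.

## Dyadic colocalization (`dyad_colocalization`)

Channels are background-subtracted (20 px) and cleared outside the cell ROI.

**Automatic thresholds.** The Costes procedure fits an orthogonal regression
LTCC = m·RyR + c over the ROI and walks the candidate threshold down from the
RyR maximum until the Pearson correlation of pixels below both thresholds
reaches zero. Costes has no meaningful solution when the channels are not
positively correlated or when the zero-correlation point sits at the noise
floor (featureless backgrounds) or the intensity maximum (uncorrelated
subregions); the implementation therefore falls back to per-channel Otsu
thresholds unless the overall correlation exceeds 0.2, both thresholds clear
the background distribution (median + 3 robust SD), and each channel retains
at least 25 above-threshold pixels.

**Manders coefficients.** M1 = Σ LTCC over pixels above both thresholds ÷
Σ LTCC over its above-threshold support ("fraction of LTCC containing RyR");
M2 symmetric. Restricting the numerator to the joint support keeps both
coefficients in [0, 1] with the above-threshold denominator (with a
total-signal denominator the restriction would be unnecessary; the
above-threshold convention is fixed here and used consistently in tests).

**Orientation territories.** The RyR channel is binarized (median + Otsu),
lightly closed to bridge punctate labelling along Z-lines, skeletonized, and
split by the 45° rule. Each split skeleton is dilated by all-ones square
kernels of 17×17 then 13×13 px (the published sizes at Airyscan sampling,
configurable; contents of the original kernels are unpublished, so a
controlled dilation is used) and clipped to the ROI. The two territories
partition the cell: contested pixels go to the nearer skeleton (tie →
transverse), so transverse signal is never counted against the longitudinal
territory and vice versa. Per-orientation MCCs re-run the Manders computation
on the masked channels; empty territories are skipped with a warning.

**Densities and dyadic density.** Protein density is the percentage of
nucleus-excluded cell area above the channel threshold (the MCC threshold by
default, so density and overlap share one segmentation). Dyadic density =
LTCC density (% area) × M1, exactly.

**Nearest-LTCC distances.** The Euclidean distance transform of the LTCC mask
evaluated at every above-threshold RyR pixel (per-pixel, not per cluster
centroid), scaled to µm; the orphaned fraction is the share of distances above
a 0.5 µm cutoff (configurable; the original identification of orphaned sites
was visual, without a numeric cutoff).

## Ca²⁺ kinetics (`calcium_kinetics`)

The **global transient** is the ROI-mean trace; F₀ is the mean of pre-stimulus
frames, F₅₀ the level halfway between F₀ and the post-stimulus peak, and TF₅₀
the time from the stimulus to the F₅₀ crossing (linear interpolation between
frames). The global rise onset is the last frame before the trace sustainably
(≥ 2 consecutive frames) exceeds F₀ + 2 SD of the baseline.

The **dyssynchrony index (DI)** is the standard deviation (configurable: IQR)
of the per-pixel time to half-maximum across the ROI, after 3×3 spatial
smoothing of the frames to tame shot noise at ms sampling. Pixels without a
valid crossing are excluded and counted; a map with over half its pixels
lacking a crossing is flagged unreliable. The SD definition and the
2 SD / 2-frame onset rule are documented configurables — neither formula is
published for the original macro.

**Local sites** are 1×1 µm boxes (rounded to odd pixel counts) centred on
transverse or longitudinal skeleton pixels, or — for orphaned sites — on local
maxima of the distance-to-skeleton field exceeding the orphan cutoff. Boxes
must lie fully inside the ROI and not overlap within a category. **Local
TTF₅₀** is the time from the start of the Ca²⁺ rise to the crossing of the
*global* F₅₀ level by the site's mean trace. By default the start of rise is
the global (cell-wide) onset, a common timing reference under which a site
whose release is delayed by d ms measures d ms longer — the behaviour of
orphaned sites awaiting propagated Ca²⁺. A purely local onset (detected on the
site's own trace with the same 2 SD rule) is available via
`reference="local"`; note that for a pure time-shift of the trace that variant
is shift-invariant and quantifies only the local rise shape.

## Voltage activation (`voltage_activation`)

The three frames preceding cell contraction are restricted to the skeleton
pixels and normalized per pixel to the recording's first frame (F/F₀; pixels
with zero F₀ are excluded and counted, > 20% exclusions flags the result).
The pooled normalized values over all three frames are Otsu-thresholded, and a
skeleton pixel counts as depolarized when above threshold in ≥ 1 of the three
frames (configurable to all three). When the pooled distribution is not
genuinely bimodal (class-mean separation < 4× the larger within-class SD),
Otsu cannot distinguish "everything up" from "nothing up"; the result is then
resolved against the early-recording baseline: a uniformly elevated network is
reported as fully depolarized, a quiescent one as zero with a `no-signal`
flag. Contraction is auto-detected as the first frame whose mean absolute
frame-to-frame difference (normalized by mean intensity, hence scale
invariant) exceeds its early-recording mean + 3 SD; a user-supplied index
overrides.

## Surface topography (`surface_topography`)

From per-cell Z-spine annotation CSVs: the **Z-groove index** is the summed
length of elevated membrane crests divided by the summed Z-spine length — a
ratio of sums at the cell level, not a mean of per-spine ratios — and the
**t-tubule opening fraction** is the count of spines with a visible t-tubule
lumen over the number of spines. Records violating crest ≤ spine or spine > 0
fail with the offending spine named.

## Synthetic data (`synthetic_data`)

The generators exist so that every measurement above can be verified against
construction-time ground truth; all are bit-reproducible given (spec, seed).

**Tubule networks.** Transverse elements are vertical chords of an elliptical
footprint at Z-line positions (pitch 1.8 µm, ≤ 5% jitter); the occupied count
is fixed at its expectation (positions random), keeping per-cell density at
the programmed level. Longitudinal connectors are horizontal segments spanning
1–3 sarcomeres at a programmed areal density, kept ≥ 1 µm apart within a
corridor (real longitudinal tubules do not stack into slabs — and a stacked
slab would be legitimately nulled by the band-pass ridge filter). The network
is dilated to the tubule width (default 0.35 µm), blurred with a Gaussian PSF
(σ 0.15 µm), and carried on a background of 20 with signal 100; noise is
Poisson-like (variance ∝ mean / `photon_scale`, default 20 photons per unit —
SNR ≈ 45, typical of confocal — `inf` disables) plus Gaussian read noise.
Defaults emulate an adult rat ventricular myocyte (40×18 µm, 0.16 µm pixels).

**Dyad pairs** place RyR puncta along Z-lines and along the mid-segments of
2-pitch connectors at 0.2 µm pitch (dense enough to merge into ridges at the
PSF, as in confocal images of RyR rows; clusters stay ≥ 0.7 µm from every
Z-line a connector crosses because the junction zone is ambiguous territory).
Each non-orphaned RyR punctum receives an LTCC partner: coincident with
probability equal to the per-orientation colocalized fraction, otherwise
displaced perpendicular to the parent element by 0.35–0.45 µm — far enough to
be resolvable as non-dyadic, near enough to stay inside the parent territory.
`orphan_gap_count` Z-lines keep RyR but lose their tubule and all LTCC.
Rendering is at 0.04 µm pixels over a 14×7 µm cell (Airyscan-like sampling so
the 17×17/13×13 kernels have their published physical scale).

**Ca²⁺ videos.** Each pixel follows baseline + A·(1−e^(−u/τ_rise))·e^(−u/τ_decay)
for u = t − t₀ > 0. Within 0.4 µm of the skeleton, t₀ is the stimulus plus a
site-wise delay drawn per ~2 µm skeleton block and then standardized so the
per-pixel delay field has exactly the programmed mean and SD (clipped at
zero — choose mean ≥ ~2.5 SD to keep the clip negligible); beyond the halo t₀
gains (distance − halo)/propagation speed, so pixels in tubule-free gaps
release late, in proportion to their distance. Gaussian noise is added; a
co-registered membrane-dye frame is provided for site classification. Frames
default to 160 at 1.5 ms.

**Voltage videos.** A random subset of branches totalling the programmed
fraction of skeleton length steps up by 12% at the onset frame; rigid
translation begins at the contraction frame (> onset + 3); Gaussian noise is
added. The realized fraction (within one branch's length of the target) is the
ground truth.

**Phenotype presets** bundle illustrative parameter values for three cell
states: `developing` (30% Z-line occupancy, longitudinal-dominant, slow rise
τ = 25 ms, delay SD 12 ms, slow propagation), `adult` (95% occupancy,
transverse-dominant, high transverse colocalization 0.9, fast synchronous
release), and `hf` (55% occupancy, orphaned Z-lines, reduced colocalization
0.6, slow dyssynchronous release). They caricature the qualitative contrasts
between those states and are not fitted to any measured dataset.

**What the generators do not emulate.** Real micrographs have curved and
branching tubules, spatially varying background and gain, chromatic offsets
between channels, RyR cluster-size distributions, motion during Ca²⁺
recordings before contraction, photobleaching, and detector-specific noise.
Passing the recovery suites therefore demonstrates that the measurement
pipeline is correct and unbiased under controlled geometry and noise — not
that it is robust to every artefact of real data.

## Problem sizes and verification protocol

The test and acceptance suites use cell rasters of roughly 140×280 px
(morphometry), 225×400 px (dyads), 73×74 px × 160 frames (Ca²⁺), and
188×213 px × 18 frames (voltage); recovery is assessed over 20 cells spanning
transverse fractions {0.2, 0.5, 0.8}, 10 seeds for colocalization and orphan
timing (8 sites per category, medians), 4×5 runs for voltage fractions, and 10
seeded replicates for the phenotype orderings. These sizes were chosen so the
whole verification runs in a few minutes on one CPU while keeping every
recovery band statistically meaningful.

## Known limitations

* The branch-label scheme (45° cut, runt-branch inheritance) reconstructs an
  unpublished macro; absolute transverse/longitudinal fractions are
  convention-dependent even though they recover the generator's truth.
* Costes thresholds degrade to Otsu on data whose background is featureless or
  whose channels are weakly correlated; the `threshold_method` field records
  which path was taken.
* Density measured through the band-pass filter chain retains a small
  negative bias (typically within 3 percentage points, occasionally ~4 on
  junction-dense meshes) dominated by ridge pinching where transverse and
  longitudinal elements cross — the perpendicular arm's negative filter lobe
  suppresses the response around each junction — plus a weaker
  foreground-fraction dependence of the Otsu threshold.
* DI and local TTF₅₀ depend on documented configurables (SD vs IQR; global vs
  local onset); comparisons across datasets must hold these fixed.
* No drift or motion correction: Ca²⁺ and voltage analyses assume the cell is
  stationary until contraction.
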