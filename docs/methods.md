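# Methods

## Overview

`gliaquant` implements the quantitative image- and molecular-analysis
procedures used to characterize microglial behavior in acute brain slices:
spontaneous surveillance (pixel-turnover motility), directed process extension
toward a chemoattractant-filled pipette, cell density and skeleton
morphometry in fixed-tissue fields, engulfment of a fluorescent Aβ-42 deposit,
receptor-staining intensity partitioning, and ΔΔCt qPCR quantification.
Because such studies rarely deposit raw microscope stacks, validation is
simulation-based: every analysis stage has a paired synthetic generator that
renders a calibrated image stack *and* records its exact programmed truth, so
the pipeline is tested by round-trip recovery rather than against reference
images.

## Motility index

A single-cell ROI of a time-lapse is binarized and consecutive frame pairs are
compared pixel-wise: *extending* pixels are present only at t+1, *retracting*
pixels only at t, *stable* pixels in both. The motility index of a pair is

    MI(t) = (extending + retracting) / stable

and the time-lapse summary is the arithmetic mean over its defined pairs (a
20-min lapse at 20-s intervals gives 60 pairs). Pairs with zero stable pixels
are undefined under this formula; they are excluded from the mean and counted
in `excluded_pairs` rather than propagated as infinities. Two conservation
identities hold for every pair and are asserted in tests: extending + stable
equals the later frame's foreground area, retracting + stable the earlier
frame's.

Thresholding defaults to Otsu computed on the temporal mean image and applied
fixed to all frames. Per-frame thresholds are available but off by default:
threshold flicker between frames masquerades as turnover and inflates the
index.

### Registration

Time-lapses are stabilized by translation-only phase correlation before
binarization. Two modes exist. `reference` aligns every frame to a chosen
reference frame; `pairwise` (the motility pipeline default) estimates the
shift between consecutive frames and applies the accumulated correction.
The pairwise mode matters for motility: a remodeling cell slowly shifts its
own center of mass, and aligning each frame to frame 0 would "correct" that
biology, corrupting the turnover counts. Frame-to-frame offsets of the
biology are sub-threshold (< 0.5 px/frame, quantized to zero), while genuine
stage or slice drift appears as abrupt whole-field jumps that the pairwise
mode removes exactly. Shifted-in border pixels are filled with the modal
background intensity so the field edge cannot register as extension.

## Chemotaxis velocity

Process velocity follows manual-tracking semantics: total path length (sum of
consecutive Euclidean steps, converted via the pixel pitch) divided by elapsed
time in minutes — not net displacement. If a track carries a pipette
position, it is truncated at the first point within the capture radius
(default 2 µm; arrival is described only qualitatively in slice experiments,
so the radius is configurable) and the elapsed time ends there; post-arrival
points contribute neither distance nor time. Per-cell velocity is the mean of
its per-process velocities (typically 3–5 tracked processes per cell);
processes with undefined velocity are excluded from the mean with the count
reported, and a cell with no defined process is excluded entirely.

The automated tip tracker used on synthetic stacks seeds the n foreground
objects nearest the pipette at t0 and links each tip to the centroid of
foreground pixels within a per-frame search radius (default 6 px); a tip with
no candidate in range terminates its track. It is a stand-in for manual
clicking, adequate for well-separated synthetic tips, and is not a general
multi-object tracker (no gap closing, no crossing resolution).

## Density and skeleton morphometry

Cell density is counted from bright somas in a maximum-intensity projection of
a calibrated field (default geometry 284 × 284 µm × 20 µm deep) and expressed
both per field and per mm³. Morphology reduces each binarized cell (soma
included) to its topological skeleton. Endpoints are skeleton pixels with
exactly one 8-neighbor — the standard skeleton-analysis definition — with an
isolated pixel counting as one endpoint; components below a minimum area
(default 50 px) are dropped as debris before per-cell statistics. Total
branch length sums steps along skeleton adjacency, 1 px for orthogonal and √2
for diagonal neighbors, with diagonal steps skipped when they shortcut an
existing orthogonal path (otherwise corners double-count). This measure is
deliberately the plain chain-code length: it reproduces the cited ImageJ-style
workflow, at the cost of a known orientation bias — a digital straight line at
22.5° measures up to ~8% longer than its Euclidean length. Length-corrected
estimators exist but would break the 1-px-per-step convention the rest of the
ecosystem reports.

## Aβ coverage

The two acquisition channels are binarized independently (they are acquired
separately to avoid bleed-through; no spectral unmixing is attempted).
Per time point, yellow = microglia ∩ Aβ and red = Aβ \ microglia, and

    percent coverage = 100 · yellow / (yellow + red)

so yellow + red always equals the deposit's area. The deposit mask is
re-binarized per time point by default (deposits can diffuse or compact); a
frozen-at-t0 option supports monotonicity analyses. Coverage is invariant to
microglial signal outside the deposit by construction.

## Intensity partition and ΔΔCt

Receptor-staining images are summarized as total field intensity (raw
arbitrary units by default; optional constant background subtraction clamps
at zero) and as a soma/process partition: the soma masks are cropped out and
the remainder attributed to processes, with percent-in-processes =
100 · process / (process + soma). Soma masks are inputs; automatic soma
segmentation is out of scope here.

qPCR fold change uses the Livak double-delta-Ct formulation: replicate Cq
values are averaged per (sample, gene); ΔCt = Cq_target − Cq_reference per
sample; ΔΔCt = group-mean ΔCt minus reference-group-mean ΔCt; fold change =
2^(−ΔΔCt). The reference group is exactly 1.0 by construction, a uniform Cq
shift cancels, and swapping the reference group inverts the fold change.
ΔCt values are aggregated as group means of per-sample ΔCt, not as averaged
per-sample fold changes. Primer-efficiency (Pfaffl) correction is not
implemented.

## Statistics

Group comparisons support the unpaired two-tailed t-test (pooled variance),
one-way ANOVA, and two-way ANOVA with interaction (statsmodels OLS, type-II
sums of squares), with Sidak-adjusted pairwise t contrasts
(p_adj = 1 − (1 − p)^m) or Tukey HSD after a significant omnibus test — both
families appear in practice and are selectable per comparison. Summaries are
mean ± SEM over the unit of analysis (animal for density/morphology/
intensity, cell for motility/velocity). Data with zero variance everywhere
return statistic 0 and p = 1 flagged degenerate; two distinct constants
return an infinite t, also flagged rather than raised.

## Synthetic data generator

The generator's defaults mirror the acquisition geometries of the imaging
protocols it emulates: 1024 × 1024 px fields every 20 s (61 frames ≙ 20 min)
for motility/chemotaxis, 2048 × 2048 px every 15 min for 2 h (9 frames) for
engulfment, and single 284 µm-wide fields for density/morphology. The pixel
pitch is derived from the 284 µm field width at the stated pixel counts
(≈ 0.277 µm/px at 1024, ≈ 0.139 at 2048) and is configurable, since
microscope pitch is rarely reported explicitly. Rendering is two-level
(background 10, foreground 200 a.u. on an 8-bit-like scale) with optional
additive Gaussian noise; photon-noise realism is a non-goal. A single 2-D
plane stands in for the z-stack: the analyses operate on maximum-intensity
projections, so a z-dimension adds nothing to ground-truth validation. One
seeded numpy Generator per config governs every stochastic draw; identical
(config, seed) reproduces stacks and truth bit-for-bit.

Mode-specific choices:

- **Baseline turnover** flips ≈ rate·area pixels per frame pair, half added on
  the cell's outer margin and half removed from it, recording the exact
  extend/retract/stable counts. Additions are drawn uniformly on the margin
  rather than exclusively at branch tips — the margin is where extension
  happens, and a uniform draw keeps the flip budget achievable for any cell
  shape.
- **Chemotaxis** advances each tip toward the pipette at the programmed
  µm/min (converted to px/frame via pitch and interval), with optional
  isotropic jitter, freezing a tip once it enters the capture radius. Truth
  tracks are float-precision, so truth-side velocity is exact; rendered disks
  are rounded to pixels, so image-side recovery carries ≲ 1% rounding error.
- **Engulfment** sweeps a covered front across a fixed disk deposit
  (pixels ordered by column), so covered sets are nested and a monotone
  schedule renders a monotone series; the truth stores the exactly rendered
  percent at each frame (integer pixel counts quantize the requested percent
  by < 0.5 of a point at the default deposit size).
- **Density/morphology fields** place non-overlapping stylized cells: a soma
  disk (default 3 px radius, rendered brighter than processes so soma
  counting can threshold them apart) with 4–6 straight branches of 3 px
  thickness. Branch directions are quantized to the 8 canonical 45°
  directions by default so the chain-code skeleton length is commensurate
  with the planted geometric length — at arbitrary angles the digital-length
  bias (above) would contaminate the round-trip with up to ~8% rasterization
  error that says nothing about the analysis code. Branch centerlines are
  drawn 0.5 px past the planted tip to offset the ~1 px end-retraction of the
  medial-axis transform. Arbitrary-angle cells remain available via
  `angle_quantize_deg=None`.
- **Intensity fields** scale soma-disk and process-polyline amplitudes so the
  soma masks contain exactly the programmed fraction of total integrated
  intensity (zero background by default, so the partition is exact).

### What passing tests do and do not show

The generator produces clean two-level scenes with well-separated cells,
translation-only drift, and Gaussian noise. Recovery at zero noise therefore
validates the *bookkeeping* of each analysis — set algebra, calibration
arithmetic, truncation and exclusion rules, threshold plumbing — not
robustness to the pathologies of real slices: uneven illumination, depth
attenuation, overlapping or dim cells, z-motion, bleaching, or rotational
drift. Thresholds that separate a bimodal synthetic histogram perfectly will
behave differently on real intensity distributions; the tracker assumes
separated tips; watershed splitting of touching cells is only invoked with
soma markers.

## Problem sizes

Tests and the acceptance script run the generators at reduced field sizes
(128–512 px) and lapse lengths (6–31 frames) with the same calibrations as the
full-scale defaults; every measured quantity is resolution-independent at
these sizes (counts are exact, geometry errors are bounded by the same
rasterization limits), so the reduced scale changes nothing but runtime.

## Known limitations

- Translation-only registration; rotation/shear drift is out of scope.
- 2-D analysis throughout; z-motion is invisible after projection.
- The tip tracker requires separated tips and closes no gaps.
- Chain-code branch length carries the orientation bias discussed above.
- No mixed-effects modeling: nesting of cells within animals is summarized,
  not modeled.
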