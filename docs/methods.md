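# Methods

This note documents the models, conventions, and numerical choices behind
`zdiscquant`, and what the synthetic-data tests do and do not establish
about real micrographs.

## Units and conventions

All physical quantities are µm or µm²; all pixel coordinates are 0-based
with half-open bounding boxes `(x, y, w, h)`. A `CalibratedImage` couples
a raster to its µm-per-pixel scale; TIFFs written by the package carry the
scale exactly in a JSON description tag and approximately in the standard
resolution tags. A file without calibration and without an explicit
override is an error — the pixel size is never silently defaulted. The
default pixel size of the generators is 0.0703 µm/px, so a 512-px field
spans ~36 µm, the field size assumed by the tiled aggregate scoring.

## Auto-thresholding ("Default dark")

The segmentation threshold is the iterative-intermeans (isodata-variant)
fixed point computed on a 256-bin histogram: starting from the lowest
occupied bin, the candidate cut advances while the mean of the two class
means still lies above it; the returned threshold is that mean rounded
half-up to bin resolution. The extreme bins (0 and 255) are zeroed before
iterating, since they typically hold saturated or erased pixels — except
when zeroing would leave fewer than two occupied bins, in which case the
original histogram is used (so a two-valued image `{a, b}` always
thresholds at `(a+b)/2` to within one bin, even when `a` or `b` sits at
the histogram edge; reference implementations instead return the
mid-histogram fallback there). Integer images fitting 0–255 use unit
bins; other ranges are mapped to bins 1–254 so the extreme-bin rule never
swallows the data itself. Masks keep pixels *strictly above* the
threshold (bright objects, dark background). Constant images raise: no
threshold exists.

## Particle analysis and disc diameter

Connected components are 8-connected (diagonal contact merges), matching
the default of the reference particle analyzer. Components below the
minimum area (default 0.2 µm²) and, by default, components touching any
border are dropped. The disc *diameter* is the bounding-box extent
perpendicular to the myofibril axis (for horizontal myofibrils, the bbox
height × pixel size); the axis angle is an explicit parameter rather than
an estimate, because the convention must be stated to be testable.
Whether such measurements historically use bbox height or a Feret
diameter varies between labs; bbox height is the measure-tool default
and is adopted.

Two deliberate non-features: touching discs that merge into one particle
are *not* split or filtered (consistency across genotypes matters more
than the rare merge, which at worst understates group differences — the
test suite reproduces this failure mode), and size-category bin edges
(default 0.5/1.0/1.5/2.0 µm) are package defaults, not validated values,
since no canonical edge set exists for this categorization.

A consequence worth knowing: with the default 0.2 µm² filter and a
0.35 µm band thickness, discs below ≈0.7 µm diameter fall under the area
cutoff and silently vanish from the measured population. The
`analysis/02` driver demonstrates this size-exclusion bias on the mutant
group.

## Tile-based aggregate scoring

Fields are partitioned into `rows × cols` tiles (default 16×16) of
`(floor(W/cols), floor(H/rows))` px; remainder margins are dropped and
logged. For the canonical 36×36 µm field this yields 256 tiles of
~2.25×2.25 µm (sometimes loosely described as "2×2 µm"; the grid count is
what the procedure fixes). Above-threshold area per tile uses either one
global threshold from the full image (default, matching the prose
description of the procedure) or a per-tile threshold (the stack-macro
variant). A tile is aggregate-positive when its area exceeds an explicit
cutoff. No canonical cutoff exists, so it is a configuration value with a
calibration helper that scans the midpoints between observed tile areas
and returns the cutoff maximizing agreement with ground-truth labels;
when aggregates exceed band per-tile areas by ≥2× this achieves perfect
recall and precision on synthetic fields. Absolute aggregate frequencies
on real data therefore depend on a cutoff the user must choose and
report.

## Rotational averaging and localization calls

Cross-section discs are denoised by averaging the image over rotations of
`k·step_deg` (k = 1..n, defaults 2° × 180, the last copy being the
identity) about the disc centre, bilinear interpolation throughout.
Sampling uses normalized convolution — the interpolated value is
`interp(value·valid)/interp(valid)` — so NaN-masked pixels and
out-of-circle territory never bias the mean (no rim darkening); output
pixels outside the selection circle are NaN. On noise-free rotationally
symmetric discs the operation is the identity to within bilinear error
(≤1% of peak at the default geometry); it is idempotent and linear to the
same tolerance.

Discs are admitted only when the Z-disc signal covers ≥90% (configurable)
of the actin-mask area. The underlying idea — a properly oriented disc
shows Z-disc signal over the entire sarcomere cross-section — carries no
number; 90% operationalizes it while tolerating boundary pixels.

Diameter profiles are sampled bilinearly along a diameter at a given
angle (odd sample count so the centre is sampled) and normalized to max
1; per-profile normalization before any cross-disc averaging is the
default (averaging before normalization is also available, since either
order is defensible). Classification smooths with a 5-sample moving
average and finds peaks with prominence ≥0.1 (relative units): one
qualifying peak within the central 25% of the diameter → `center_peaked`;
exactly two opposite-signed peaks flanking a central minimum → `bimodal`;
anything else → `ambiguous` with diagnostics. The thresholds are
configuration values; the two localization patterns are defined
qualitatively, so the thresholds must be explicit to be testable.

## Statistics

Fisher's exact test for count data: 2×2 via the hypergeometric
distribution; R×C tables with total N ≤ 200 by full enumeration over
tables with the observed margins (probability `∏r_i!∏c_j!/(N!∏n_ij!)`);
larger tables by seeded Monte-Carlo permutation of column labels, with
`p = (hits+1)/(reps+1)` and its binomial standard error reported.
Two-sided p-values sum the probabilities of tables no more probable than
the observed one, with a 1+1e-7 relative slack absorbing float round-off
(the convention of mainstream statistics environments). Welch's t-test
uses the unequal-variance statistic with Welch–Satterthwaite degrees of
freedom. Flagging p > 0.001 as not significant, as is common in this
literature, is a reporting convention rather than a correction and is
left to callers.

Intensity normalization divides by the control-group mean (control maps
to mean exactly 1; scale-equivariant). BiFC signal is the per-sample
ratio of Z-disc profile peak to mean off-disc background; ratios near 1
mean no complementation.

## Synthetic-data generator

The generator exists to give every downstream stage inputs with known
truth, at the geometry the pipeline targets:

- **Longitudinal fields** — 36×36 µm at 0.0703 µm/px, 6 myofibrils,
  3.4 µm sarcomere spacing (canonical for IFM), rectangular Z-disc bands
  of 0.35 µm thickness whose extent perpendicular to the axis *is* the
  ground-truth diameter, rendered on the pixel-centre grid with half-open
  membership so grid-aligned diameters are exact in pixels; a continuous
  actin stripe per myofibril; optional bright elliptical aggregates
  larger than any band (aggregates are identified by size and brightness;
  no shape model is assumed). Background 10, signal 100
  (arbitrary units).
- **Cross-section discs** — rotationally symmetric radial profiles:
  Gaussian in radius centred at 0 (centre-peaked, SD = `profile_scale_um`)
  or centred at `profile_scale_um` (ring, SD = ring width, default a
  third of the radius). Two-parameter families are the simplest that
  produce one vs two peaks on a diameter transect.
- **Noise** — `Poisson(I·gain)/gain` photon noise plus additive Gaussian
  read noise, both disableable for exact tests. The standard "moderate"
  regime in tests is gain 50 with SD 2 (2% of signal).
- **Expression** — logistic onsets `plateau/(1+exp(−(t−onset)/s))` with
  class onsets 24 h (growing) and 60 h APF (blocking), sharpness 4 h,
  equal plateaus of 100 TPM, multiplicative log-normal noise (SD 0.25 on
  the log), sampled at 16/24/30/48/72/90 h APF — the sampling design of
  the public IFM development dataset the expression analysis consumes.

Everything is a pure function of (parameters, seed); ground-truth tables
carry exactly one row per generated object.

What the generator does **not** emulate: optics beyond a Gaussian PSF,
3-D structure, sarcomere-length or intensity values measured from real
IFM (the defaults are realistic for the tissue, not calibrated to any
measured image set), aggregate morphology, isoform-specific expression
heterogeneity within a class, or the oligomerization kinetics that
produce disc growth. Passing tests therefore establish that the
*procedures* are implemented correctly and recover known truth under
controlled degradation — not that any particular biological effect size
in real flies is reproduced.

## Display conventions

Class time courses report both the raw mean TPM and log10(mean TPM + 1);
the pseudocount bounds the display at 0 and is standard for TPM scales
(log display of TPM needs an explicit base and pseudocount, so both are
recorded in output metadata). The
half-plateau onset time is the linear-interpolated first crossing of 50%
of the class-mean plateau; flat courses have no onset and report as
undefined.

## Problem sizes

The test suite and acceptance script use one to six 512×512-px fields per
check (≈66 bands each), 20 discs per cross-section condition, 10,000
Welch simulations, and all ~10⁴ 2×2 tables with N ≤ 20 for the Fisher
oracle — sizes chosen so the full suite runs in well under a minute per
module on a single CPU while keeping ≥50 objects behind every error
statistic.

## Known limitations

- No watershed splitting of touching discs; no 3-D segmentation; no
  learned segmentation.
- Cross-section disc centres are supplied (or taken from synthetic
  truth); there is no automatic disc detector for cross sections.
- Transcript quantification from reads is out of scope; TPM tables are
  validated inputs.
- The R×C Fisher enumeration is exponential in table size; beyond the
  configured total-count limit the Monte-Carlo path must be used.
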