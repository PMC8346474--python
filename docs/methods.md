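# Methods

This note documents the models and procedures implemented in
`organoidquant`, the parameters that matter, what the synthetic
fixtures do and do not emulate, and the numerical choices made where
the published recipes left the design open.

## Sphere potency

Day-2 spheres carry three channels: a nuclear stain, SOX2 (neural) and
TBXT/Brachyury (mesodermal).  Spheres are detected on the nuclear
channel by Otsu thresholding, hole filling, and a minimum-area filter
(default 500 px², configurable) that rejects debris.  Marker positivity
is defined per well by Otsu thresholds on each marker channel,
overridable by fixed values when a plate-wide gate is preferred — the
masking rule itself is a configuration choice, as the upstream
acquisition software's rule is not published.  Per sphere,

    potency = %SOX2 − %TBXT        (percentages of nuclear area)

lies in [−100, +100]; spheres with ≥25% of their nuclear area in
neither marker mask are flagged `excluded`.  Lineage classification
uses a symmetric cutoff (default 25 potency units): below −cutoff
myogenic, above +cutoff neurogenic, the closed interval in between
neuromesodermal.  The cutoff is exposed in configuration and echoed in
outputs; no published numeric boundary exists.  Touching spheres are
not split — sphere plating is sparse by design, and a watershed step
would add a parameter with no ground truth to validate against.

## Contraction analysis

The frame-subtraction signal is the per-frame-pair mean absolute
intensity difference.  Events are frames where the signal exceeds
`median + k·MAD`, with the MAD scaled by 1.4826 so that `k` counts
robust standard deviations of a quiescent baseline; the default k = 5
makes false alarms on a pure-noise 5-minute recording essentially
impossible, which replaces the study's manual blinded verification with
an explicit, reproducible rule.  Candidate frames closer than
`merge_gap` (default 2) merge into one event.  Spatial extent is the
fraction of pixels whose |ΔI| at the event's peak frame pair exceeds an
Otsu threshold on that raw difference map — a deterministic surrogate
for the observer's judgement of how much of the field a contraction
"encompasses"; events are `large` when the extent strictly exceeds
half the field.  Whether extent should be judged on raw or bandpassed
frames is not published; the raw map is used and documented here.

Optic flow follows the Gaussian-window MSE formulation: per pixel, the
displacement is the integer vector of Euclidean norm ≤ `max_distance`
(default 7 px) minimizing the Gaussian-weighted (σ = 4 px) mean squared
error between consecutive frames, with ties broken toward smaller
magnitude and then lexicographically for determinism; the per-frame
statistic is the mean displacement magnitude divided by
`max_distance`.  Videos are first min–max converted to the 8-bit range
and bandpass filtered at 5–40 px.  Boundaries are periodic (np.roll),
which is exact for the rigid-shift validation fixtures and a
negligible-edge-effect approximation otherwise.

Drug time-courses divide each well's series by its own pre-compound
baseline mean and report across-well means with two-sided t-based 95%
confidence intervals (with n = 2 wells the interval uses t with 1 df).
Calcium traces are expressed as ΔF/F against the mean of the first
120 s (the pre-application recording; sampling interval 0.5 s), and a
cell is a responder when peak ΔF/F within the 30 s application window
exceeds 0.2 — a configurable default, as no numeric criterion is
published.

## Imaging primitives

* Automatic thresholds operate on a 256-bin histogram spanning the
  image min–max, mirroring 8-bit thresholding behaviour.  Otsu
  maximizes between-class variance; triangle uses the
  peak-to-farthest-end chord construction; minimum-error minimizes the
  Kittler–Illingworth criterion by exhaustive scan.  Class variances in
  the minimum-error criterion are floored at one bin width squared:
  without the floor, a histogram spike with sub-bin variance (the
  exact-zero background left by background subtraction) forms a
  degenerate class that captures the global minimum at the histogram
  boundary, and the scan returns a noise-level threshold instead of the
  between-class one that iterative implementations converge to.
* Rolling-ball background subtraction is implemented as grayscale
  opening with a flat disk footprint of the given radius, subtracted
  and clipped at zero.  This removes structures wider than roughly the
  disk diameter and preserves narrower ridges.  It is not bit-identical
  to implementations that model intensity as a third spatial dimension;
  the discrepancy is accepted and the opening formulation is the
  documented contract.
* The Fourier bandpass multiplies the spectrum by
  `exp(−(f·small)²)·(1 − exp(−(f·large)²))` on radial frequency `f`
  (cycles/px): gain 1/e at the band edges, DC removed, no stripe
  suppression.  Output is min–max rescaled to the 8-bit range
  ("autoscale"); a spectrally flat result returns zeros with a warning.
* Connected components are 8-connected; circularity is
  `4π·area/perimeter²` capped at 1 (single-pixel objects, whose
  rasterized perimeter is 0, cap to 1); object maximal dimension is the
  maximal Feret diameter; physical areas are `px² · scale²`.
* Object filters use strict inequalities (`area > 100 px²`,
  `circularity < 0.5`), following the wording of the published
  recipes; an object exactly at a bound is removed.  Border-touching
  objects are retained.

## Neurite segmentation

The five-step recipe is fixed and order-sensitive: (1) maximum
projection of the 5 × 1 µm stack; (2) neurite candidates: 2σ Gaussian
blur, 5 px rolling-ball subtraction, minimum-error threshold, keep
area > 100 px² and circularity < 0.5; (3) cell bodies: 2σ blur, Otsu,
keep area > 100 px² and circularity > 0.3; (4) sphere autofluorescence:
10σ blur, triangle threshold; (5) final mask = candidates − (bodies ∪
autofluorescence), keep area > 1000 px² and circularity < 0.2; the
neurite area is the total retained mask area.

One robustness guard is added: if the candidate threshold in step 2
selects more than 25% of the field, the stage reports an empty result.
Neurites are thin, sparse structures that occupy a few percent of a
field; a candidate fraction that large means the threshold collapsed
onto background noise (on a content-free field every automatic
threshold still splits *something*, and the percolating noise mask
defeats the area/circularity filters).  The guard stands in for the
human quality control a manual pipeline gets for free.

Two behavioural properties of the recipe, measured on synthetic
fixtures, are worth knowing.  First, absolute recovered area depends on
where the minimum-error threshold lands on the blurred ridge profile;
on filament-only fields the measured error is within a few percent.
Second, fields containing bright somata carry a systematic ≈ −20%
absolute-area bias (soma edge rings survive background subtraction and
pull the threshold up).  The longitudinal readout is the fold change of
per-well total area against the first time point, which cancels any
multiplicative bias; growth-curve conclusions are therefore insensitive
to this, but absolute areas should not be compared across fields with
very different soma content.

## NMJ scoring

Candidate clusters are segmented on the max-projected α-bungarotoxin
channel with a triangle auto-threshold (a generic detector is needed
because the published gates filter already-detected clusters; the
method is configurable).  Retained clusters have maximal Feret diameter
in [10, 50] µm inclusive — "dimension" is interpreted as the Feret
length, and inclusivity is a documented choice — and BTX mean footprint
intensity strictly above 1000.  "Intensity" is the mean pixel intensity
over the cluster footprint, the usual high-content-software object
statistic; the published thresholds (1000 BTX, 5000 EGFP) come without
a named statistic.  A retained cluster is innervated when its EGFP mean
exceeds 5000.  Per culture: innervation percentage and mean areas of
innervated and uninnervated clusters separately; display normalization
divides each culture's value by the mean of its batch-matched isogenic
control cultures.

## Statistics

Fold-change normalization divides each well by its differentiation
batch's average — across all lines ("among" mode) or within the well's
own line ("within" mode).  Among-line variance is the sample variance
(n−1) of per-line means of among-normalized values, compared between
line groups by a two-sided variance-ratio F-test (two-sided p = twice
the smaller tail, capped at 1).  Within-line variance is the per-line
sample variance of within-normalized values — the n−1 estimator is
used, and the raw sum of squared deviations is also emitted — compared
between groups by one-way ANOVA.  A caveat measured here: with 5–6
lines of 6 wells, per-line variance estimates carry few degrees of
freedom, and the ANOVA's power to detect even a 9× within-line variance
inflation is only ≈ 75%; group differences of that size can fail to
reach α = 0.05 in a substantial fraction of replications.

The exact Mann–Whitney test enumerates the full permutation
distribution of U (classical counting recurrence, exact integer
arithmetic) whenever the data are tie-free and C(n1+n2, n1) ≤ 2×10⁵;
the two-sided p is `2·min(P(U≤u), P(U≥u))` capped at 1.  With ties the
test falls back to midranks and the tie-corrected normal approximation
and is flagged approximate — exactness claims are never made on tied
data.  Kruskal–Wallis uses the tie-corrected H with a χ² reference
(k−1 df); at 3 groups of 6 the χ² approximation is slightly
conservative (true type-I ≈ 0.041 at α = 0.05).  The normality gate
runs Shapiro–Wilk per group and routes to the parametric path only if
every group passes; groups with n < 3 or constant values are untestable
and force the nonparametric route with a warning.

ANOVA from summary statistics reconstructs `SD = SEM·√n`, takes
SS_between about the size-weighted grand mean and
`SS_within = Σ(nᵢ−1)·SDᵢ²`; on exact summaries this reproduces the
raw-data ANOVA to machine precision (round-trip tested at 1e-8).

Longitudinal growth is assessed by OLS: the time effect is the F for
the slope in `area ~ time`, and the time × line interaction is the
partial F comparing `area ~ time + line` against `area ~ time * line`.
Wells are treated as independent observations at each time point; the
published analysis does not state its error structure, and this choice
is documented rather than inferred.  All simulations are seeded
(default 20210806).

## Synthetic fixtures

Generators are pure functions of their spec (seed included): identical
specs give bit-identical outputs, and ground truth is emitted alongside
every fixture so recovery tests never re-derive truth from pixels.
Noise is additive Gaussian clipped to the valid range; the default
field is 512×512 px, 16-bit, 1.33 µm/px (comparable to 4×
acquisition).

* **Sphere fields**: non-overlapping discs on a jittered grid; within
  each disc, marker masks are contiguous angular sectors arranged to
  realize the requested SOX2/TBXT/unstained fractions exactly (after
  rasterization), overlap included.  Ground truth records the realized
  per-sphere percentages and potency.
* **Contraction videos**: a static smoothed texture; at each event
  frame, a contiguous region of exactly the requested pixel fraction
  brightens by the event amplitude for one frame — the minimal
  perturbation a frame-subtraction detector responds to.  No physical
  deformation or motion blur is modelled.
* **Neurite stacks**: rectangular filaments (default 10 px wide,
  intensity 1000 over background), compact bright somata, one large
  diffuse autofluorescent sphere, a smooth background haze (Gaussian,
  sd 250 at 50 px correlation length over a level of 500) and shot
  noise (sd 80), rendered as 5 slices with a focus profile.  The haze
  and the bright sphere are not decoration: the triangle-threshold
  autofluorescence step keys on the shape of the blurred-image
  histogram, and on an implausibly flat background it would mask any
  filament's own diffuse glow.  Filaments are placed clear of somata
  and spheres so the painted area is recoverable ground truth.
* **NMJ fields**: hard-edged elliptical puncta of specified maximal
  dimension and mean intensities on a grid; EGFP overlays the same
  footprint.  Rasterization inflates the measured Feret diameter by a
  few percent, so fixtures keep configured diameters a little inside
  the [10, 50] µm gates; boundary behaviour is tested with explicit
  diameters.
* **Grouped tables**: `value = line_mean + batch_offset +
  N(0, within_line_sd)` with batch offsets drawn once per batch; true
  variance components are attached to the table.

What passing these suites shows — and does not.  The fixtures exercise
thresholding, shape filtering, event detection, gating logic and the
statistical layer against exact ground truth under controlled noise.
They do not emulate optics (PSF, depth attenuation), real staining
variability, overlapping or touching structures, motion blur, or
photobleaching; recovery at the tolerances reported here is evidence
the code implements the stated procedures, not that the procedures
themselves are unbiased on real microscopy.

## Problem sizes

Test and acceptance runs use desk-scale fixtures chosen to keep the
full suite in tens of seconds while preserving the regimes of
interest: 384–512 px fields, 120-frame videos at 64×64 px, 8 filament
fields per recovery suite, 100 seeded videos for detector calibration,
and 10⁴ replicates for type-I calibration of the rank tests.
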