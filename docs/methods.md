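# Methods

This note documents the models, parameter defaults and numerical
choices behind `focipair`, and what the synthetic worlds used by the
test suite do and do not establish.

## Coordinates and units

All positions are continuous nanometers in image orientation (origin at
the region bounding-box top-left, *y* down). Every distance anywhere in
the package is the Euclidean distance on `(x_nm, y_nm)`; thresholds
stated in µm in the field's conventions (1 µm complex linkage, 1 µm
sparseness horizon) are carried as nm internally to avoid scale bugs.

## The paired-end focus model

A DSB produces two resected ssDNA ends that separate spatially while
remaining tethered; each end may carry Rad51 and/or Dmc1 signal. The
generator (`simulate_dsb_pattern`) draws, per DSB:

- a midpoint uniform in the nuclear region (disc of the stated area by
  default; polygon regions are supported for traced masks — which
  outline the original spreads used is not recorded, so the disc is the
  simulation default);
- an end-to-end separation from `pair_sep_sampler`, default uniform on
  [150, 400] nm. Pair enrichment is observed up to 400 nm with a
  ~150 nm detection floor; no separation distribution is reported, so
  uniform is the least-committal stand-in and is fully configurable;
- both ends placed at ±sep/2 along a uniform orientation, rejection
  sampling until both fall inside the region (10,000 consecutive
  failures raise "nucleus too small");
- per end, an occupancy category (both channels / RAD51 only / DMC1
  only / empty), default 0.7/0.1/0.1/0.1 — chosen so that ~85% of foci
  of either channel have a cross-channel partner, echoing the measured
  84–85% cross-channel colocalization fractions. This is a testing
  stand-in, not an inference about biology;
- channel records offset from the end by `cofocus_offset_sampler`
  (default uniform [0, 150] nm) at a uniform angle — the side-by-side
  co-focus geometry;
- log-normal intensities (median 100 a.u., σ=0.5): focus brightness in
  real spreads spans orders of magnitude.

Records carry truth tags (`dsb_id`, `end_id`, `is_background`) so that
pair-detection accuracy is measurable.

## Resolution censoring

Widefield imaging cannot separate foci closer than ~150 nm. The censor
(`apply_resolution_censor`) repeatedly replaces the closest same-channel
pair below the floor with one focus at the intensity-weighted centroid
carrying the summed intensity, until all pairwise distances clear the
floor. The merge rule is a package choice (only the floor itself is an
observed property of the assay); closest-pair-first with lexicographic
tie-breaking makes it deterministic. Total intensity is conserved and
the minimum pairwise distance never decreases. The matched null uses a
unit-weight (plain midpoint) merge, since null placements have no
meaningful intensities; this does not measurably affect distance
distributions.

## Nearest-neighbor statistics and the matched null

`nn_distances` pools per-focus NN distances across nuclei (same-channel
mode excludes self; nuclei with fewer than two foci, or an empty
cross-channel target, contribute nothing). Histograms use right-open
50 nm bins on [0, 2000) nm plus an overflow bin; 50 nm resolves both
the ~100 nm super-resolution peak and the 200–400 nm widefield pairing
band, and the width is configurable.

The null (`simulate_matched_null`, default 100 reps) re-places the
observed per-nucleus focus counts uniformly in each nucleus's own
region, so nucleus-to-nucleus density variation is matched exactly, and
pooling weights nuclei by focus count exactly as the observed pooling
does. Censoring is ON by default so the null embeds the same
observation floor as widefield data, and OFF for super-resolution data;
whether the original simulations enforced the floor is not recorded, so
both modes exist. Per-rep bin fractions give Monte-Carlo standard
errors. Points are placed strictly inside the bounded region with no
toroidal wrap — spread nuclei are bounded objects, and the closed-form
calibration test runs at a density where edge bias is far below the
Monte-Carlo noise.

`pairing_enrichment` reports per-bin excess fractions and
`p̂ = Σ max(0, excess)` over bins with upper edge ≤ 400 nm. On synthetic
worlds with 200 nuclei × 30 foci this recovers generated paired
fractions of 0.2/0.5/0.8 within ±0.1 (see the acceptance suite).

## Filters and the detectability bound

- Low-density nuclei: strictly fewer than 0.8 foci per µm² of nuclear
  area in at least one of the stated channels.
- Locally sparse foci: exactly one same-channel neighbor within a
  closed 1 µm ball (self excluded).

`detectability_bound` asks how large a hidden subpopulation of
fixed-distance pairs could be while escaping detection. For each
candidate fraction it simulates spiked versus pure-CSR cohorts and
tests the pooled NN histograms with a Pearson χ² statistic whose
significance comes from a **nucleus-level permutation null**. A plain
two-sample χ² on pooled NN counts is anti-conservative because NN
distances are correlated within a nucleus (mutual pairs share a
distance): its measured type-I error at α=0.05 was 0.72. Permuting
whole nuclei preserves the dependence and is exactly calibrated
(measured 0.05). Adjacent bins are pooled to a minimum combined count
of 10 before testing; the pooling is computed from permutation-invariant
totals.

## Co-focus merging, pairs and categories

Composites are mutual cross-channel nearest neighbors strictly closer
than 200 nm, merged at the intensity-weighted centroid; the 200 nm
radius follows the cross-channel colocalization convention (no separate
merging radius is reported for classification) and is configurable.
Pairs are mutual nearest neighbors among composites within 400 nm —
mutual-NN prevents chains and guarantees each composite joins at most
one pair. Pair composition is reported as the full table over
{co-focus, RAD51-only, DMC1-only} member pairs.

Intensity shares express each member's brightness as the percentage of
the pair's total per-channel signal; the least-squares slope of DMC1
share on RAD51 share tests coordinate loading (independent assembly
predicts slope ≈ 0). Pairs missing a channel on either member are
excluded and logged.

Category rules (per nucleus): NEGATIVE if no RAD51/DMC1 foci; one
complex → I (1 composite), II (2 composites), III (>2 foci in either
channel); multiple complexes (single-linkage at 1 µm) → IV (≤2 per
channel) or V (>2). Single linkage is chosen over max-diameter for
determinism; channel-count rules take precedence where both could
apply, because category III/V are defined by channel counts. The
classifier is total: every configuration maps to exactly one category,
cross-checked against an independent rule-table implementation on
randomized instances.

Landmark selection: nuclei need 1–2 spots of each array kind; the
anchor is the midpoint of the closest (tetO, lacO) pair; exactly one
DMC1 focus within 300 nm of the anchor and 0–2 additional DMC1 foci
within 1 µm of that focus. The "pair" call is ≥1 additional focus in
that neighborhood — "resolvable pair" has no recorded operational
definition, so this declared rule stands in. The tetO split distance is
reported whenever two tetO spots exist.

## dSTORM simulation and localization

`simulate_blink_stack` renders two-state blinking emitters: per frame
each emitter is on independently with `p_on`, photons are Poisson, the
PSF is an isotropic Gaussian sampled at 100 nm pixel centers, and
Poisson background is added. No bleaching kinetics, chromatic
aberration or camera gain modeling — the artifact under study needs
only co-blinking.

The localizer is a deliberately minimal centroid/second-moment method
(the conclusions depend on SNR thresholding plus the width cutoff, not
on parity with any particular fitting plugin): per frame, background is
the median and noise 1.4826×MAD; candidates are local maxima of a
Gaussian-smoothed residual (σ 2.5 px) that clear `snr_min` (default 5)
in the raw 3×3 amplitude **and** a matched threshold in the smoothed
domain. The second test exists because, over millions of pixel draws,
single-pixel Poisson spikes fluke past the raw bar and produce wide
false localizations; smoothing suppresses them while real and merged
spots pass by large margins. Position is the intensity-weighted
centroid in a 7×7 window with sub-noise pixels zeroed; width is
2.355 × the RMS second-moment radius; localizations wider than
`fwhm_cutoff_px` (default 2 px = 200 nm) are rejected.

A consistency caveat: the 2 px width cutoff presumes spots whose
measured FWHM is below 200 nm. The generic emitter default of
σ = 130 nm (FWHM ≈ 306 nm) is kept for rendering, but simulations meant
to pass the cutoff use σ = 70 nm (measured FWHM ≈ 180 nm after
pixelation and window truncation). Localization precision on bright
noiseless emitters is <10 nm; with noise the RMS error tracks
σ_PSF/√photons within a factor of two at high photon counts (a
thresholded centroid is not efficient at low counts).

Two emitters several hundred nm apart that blink in the same frame
yield a single smoothed maximum and hence one event near their
photon-weighted midpoint with a strongly inflated width — the
mis-localization artifact. `artifact_decay_curve` localizes once with
the filter disabled and applies each cutoff as a post-filter
(equivalent, since the width cut is the localizer's last step),
reporting the midpoint-disc fraction (50 nm radius at the true
midpoint, a declared region) and the A/B cluster count ratio
(75 nm-radius discs). Real clusters hold their ratio while the
midpoint fraction collapses; with a clean two-emitter world the merged
widths are narrowly distributed, so adjacent loose cutoffs can tie —
the decay is monotone non-strictly, with a >5-fold overall drop.

## Reconstruction, sr foci and blur congruence

Reconstructions are 2D histograms at 20 nm pixels with a 0.75 px
Gaussian blur (total intensity = number of localizations, conserved to
<0.1%). sr foci are connected components of the ≤50 nm neighbor graph
(density-reachability with a minimum of 5 members; smaller components
count as noise). Ellipse axes are 4×√eigenvalue of the member
covariance (±2σ, covering ~95% of a Gaussian cluster footprint; the
multiplier is exposed since no axis convention is recorded for manual
ellipse tools), with orientation from the principal eigenvector;
near-singular covariance is flagged degenerate.

`blur_congruence` blurs the reconstruction by 6 px (σ = 120 nm at
20 nm/px), detects foci in the blurred image (relative-threshold local
maxima with centroid refinement) and compares NN distributions across
(i) sr-focus centroids, (ii) blurred-image foci, (iii) widefield foci
by Kolmogorov–Smirnov distance. On synthetic paired sr foci the blurred
distribution peaks with the widefield one (~300 nm) while the
super-resolution distribution peaks near 100 nm.

## Filament geometry

Pure arithmetic: `core = apparent − 60 nm` (antibody decoration plus
finite resolution broaden structures ~60 nm per dimension; a 10 nm-wide
filament images 70 nm wide), `nt = 2 × core` (2 nt/nm), `protomers =
⌊nt/3⌋` (3 nt footprint), `turns = protomers/6.6`. The 6.6
protomers-per-turn default is back-derived from the 33-protomer ↔
5-turn correspondence; the canonical RecA value (~6.2) is selectable.
`tract_fraction_pct` expresses the filament against a typical 800 nt
resected tract. Inputs at or below the broadening floor are rejected.

## What the synthetic worlds do not establish

The generators state a world — uniform separations, independent
occupancy, disc nuclei, isotropic Gaussian PSFs, two-state blinking —
and the green tests establish that the estimators recover that world's
parameters and reproduce the mechanisms (censoring, the midpoint
artifact, blur congruence) within stated tolerances. They do not
reproduce measurements that depend on the original micrographs
(cross-channel fractions of 84–85%, sr-focus lengths of 114 ± 30 nm,
aspect ratios, sr-foci-per-focus counts, tetO split distances): those
require the real data, which is not deposited. Printed worked-example
percentages and the filament arithmetic chain are exact and are
reproduced exactly.

## Reproducibility

Every stochastic routine takes a seed or `numpy.random.Generator`; the
pipeline splits one master seed per stage with `SeedSequence` so stages
re-run independently yet reproducibly, and identical (config, seed)
runs produce byte-identical outputs (tested).
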