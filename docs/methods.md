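# Methods

This note documents the models implemented in `paleotrail`, their
assumptions, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the design was open.

## ZooMS taxon screening

A spectrum is a peak list (m/z, optional intensity). Each taxon in the
reference library carries up to seven named collagen peptide markers
(A–G) with monoisotopic [M+H]⁺ masses. Marker *m* matches iff some peak
lies within ±`tol` of its reference mass (closest peak reported); the
spectrum is assigned to the taxon with the most matched markers, provided
it reaches `min_markers`, else it is `unidentified`.

Parameters and defaults:

- `tol = 0.2` Da. A calibrated linear MALDI-TOF instrument resolves
  collagen peptides well within this window; with it, the observed
  hominin peak list matches exactly the six Hominidae markers it should
  (A–D, F, G) and rejects a peak 0.21 Da off.
- `min_markers = 4`. Below four shared peptides an assignment to family
  level is not credible; four keeps single-marker coincidences from
  producing identifications while letting degraded spectra (one or two
  markers lost) through.

Design choices: ties between taxa are reported as the composite label
joining the tied names (`Cervidae/Bovidae`), mirroring how shared-peptide
ambiguity is reported in practice; one peak may satisfy markers of
several taxa, because collagen peptides genuinely are shared across
clades — no exclusivity is enforced. Deamidation and oxidation mass
shifts are not modelled; matching is against the reference masses only.
Raw-spectrum processing (baseline subtraction, peak picking) is out of
scope — inputs are peak lists.

The bundled reference library holds observed masses only for the six
printed Hominidae markers (marker E is absent: it is rarely recovered
from degraded human collagen, and no mass is available for it, so the
6-of-7 match does not depend on it). The faunal rows (Equus, Bovidae,
Cervidae, Rhinocerotidae, Canis lupus, Saiga) are synthetic: plausible
masses with realistic spacing, unique per taxon at ±0.2 Da, with a few
deliberately shared peptides between related clades.

## Radiocarbon calibration

Model: measurement error and curve error are independent Gaussians, so
for determination *a* ± σ and curve μ(t), σ_c(t),

p(t) ∝ exp(−(a − μ(t))² / 2(σ² + σ_c(t)²)),

normalized over a 1-cal-yr grid spanning the curve support. The 1-yr grid
removes discretization as a source of interval mismatch. The prior over
calendar time is uniform; no reservoir or ΔR corrections, no Bayesian
sequence/phase modelling, no outlier models.

HPD intervals: grid years are admitted in order of decreasing posterior
mass until the level is reached (ties included), contiguous runs become
intervals. Endpoints are rounded *outward* to the nearest 10 cal yr by
default — the convention used when reporting multi-decade uncertainties —
so enclosed mass is always ≥ the level and a 68.3% region is nested
inside the 95.4% one by construction. Rounding can be disabled
(`round_to=0`), as the closed-form tests do.

Curves are read in the IntCal text dialect (`#` comments; first three
columns cal BP, ¹⁴C age, error; comma- or whitespace-separated; an
oldest-first file is reversed on load), and the synthetic curve writer
round-trips bit-exactly (17-significant-digit output). The published
IntCal20 file parses directly, but is not redistributable here; the two
tests that compare calibrated endpoints for the determinations on the
hominin bone against their published calendar ranges require a
user-supplied copy under `data/` and fail with instructions otherwise.
Calibration correctness is instead established by closed-form limits: on
the identity curve the posterior equals the sampling Gaussian to ≤ 1e-6
total variation, central ±1σ mass is 0.683 ± 0.005, and HPD half-widths
are 1σ/2σ at the two standard levels; curve errors add in quadrature; and
translating curve and measurement together translates the posterior
exactly.

## mtDNA pairwise differences

Comparable sites for a pair are positions where both rows carry an
unambiguous base (A/C/G/T). Gaps and ambiguity codes are missing data,
excluded from numerator and denominator — the conservative convention
for low-coverage ancient consensus sequences, where much of the D-loop
may be uncalled. The statistic is symmetric; masking additional sites
can only decrease both counts. Ranking from most to least dissimilar
breaks ties lexicographically by name so output is deterministic.
Coordinates are 1-based on the alignment; no projection to reference
coordinates. Read mapping, damage rescaling, contamination estimation
and tree inference are out of scope.

Diagnostic-site support: for a table of (position, derived allele,
observed read bases), covered = reads with a called base ≠ N at a
diagnostic position; matching = those equal to the derived allele.

## Habitat suitability model

Assumptions: the taxon's realized niche is a single bivariate Gaussian
envelope in (annual-mean temperature, annual precipitation); occurrences
sample that envelope; climate at an occurrence is the nearest grid cell
and nearest 1,000-y slice (no interpolation, matching the coarse ~5.75° ×
3.75° source grid); suitability decays exponentially with the Mahalanobis
quadratic form. s = 1 iff climate equals the envelope mean; with Σ⁻¹ = I
the distance is exactly squared Euclidean (tested against that oracle),
and d_M is invariant under invertible affine transforms applied to both
sample and grid (tested to 1e-10).

Monte Carlo design: member *m* draws k records per region box uniformly
without replacement (balanced spatial representation; a box holding
exactly k records — the Crimea box holds two — always contributes all of
them) and a Uniform[younger, older] age per record. k = 2 for the primary
model (six samples per member), k = 10 for the validation configuration
(thirty per member); 5,000 members. Each member's stream seed is derived
as `default_rng([master_seed, m])`, so members are reproducible
independently of scheduling order. Members whose envelope cannot be
fitted are skipped with a warning; a run with > 10% failures aborts.
The ensemble-average grid is a running arithmetic mean (5,000 member
grids at the study size would not fit in memory; per-member grids can be
retained for small runs with `store_members=True`, and per-member box
time series are always recorded for the sampling boxes).

Numerical choices: covariance uses the unbiased (n−1) estimator;
condition numbers above 1e12 trigger Tikhonov regularization
Σ + εI with ε = 1e-6 · tr(Σ)/2 (absolute floor 1e-12 when the trace
vanishes), with a warning. The quadratic form is the default distance —
the exponential-decay definition is stated on the quadratic form — and
`distance_mode="root"` provides the conventional square-root Mahalanobis
distance, since usage varies. Region membership is by cell center,
longitude-wrap aware; ages outside the field's span clamp to the nearest
slice with a warning. Occurrence tables are normalized on load: the
printed age columns carry the older bound first, so bounds are stored
explicitly as (older, younger), with a warning where a swap relative to
min ≤ max semantics occurred. The source table prints 12 dated records
(the accompanying text mentions 13 samples; the 12 printed rows are what
ships, and the discrepancy is noted rather than resolved).

## Synthetic-data generators

All generators are fully seeded (same seed ⇒ byte-identical output).

**Climate.** T(lon, lat, t) = base + linear latitudinal gradient +
sinusoidal glacial cycle + Gaussian noise; precipitation analogous and in
phase (interglacials warm and wet), floored at zero. Defaults: 5.75° ×
3.75° global grid, 150→30 ka BP at 1,000-y steps (121 slices, 63 × 49
cells), base 10 °C, gradient −0.6 °C/°lat, cycle half-amplitude 8 °C /
150 mm yr⁻¹ with 100 ky period peaking at 125 ka BP (the Last
Interglacial), noise 0.5 °C and 20 mm yr⁻¹. The single sinusoid is a
deliberate stand-in for orbital-scale variability: it creates warm
"interglacial windows" with the right period and phase, which is the
feature the suitability model's qualitative behaviour depends on. It has
no physics — no orbital forcing, no land mask (masking optional, default
off), no spatial teleconnections, and a linear (not |lat|) temperature
gradient — so passing tests demonstrate the *pipeline's* statistical
behaviour, not fidelity to any particular climate reconstruction.

**Occurrences.** For each record a target climate is drawn from a known
truth envelope and the record is placed at the (cell, slice) in its box
whose climate is Mahalanobis-nearest the target; where the box's grid
covers the envelope this reproduces the envelope distribution without
the availability bias a density-weighted cell draw would have. True age
and true climate are stored in extra columns the pipeline never reads;
published bounds bracket the true age by ± half the stated uncertainty.
The recovery experiments use a truth of mean (−19 °C, 455 mm yr⁻¹) with
standard deviations (5 °C, 120 mm yr⁻¹) and correlation 0.45 — a
cold-steppe envelope centred well inside what the synthetic field offers
at the boxes' latitudes (so mean recovery is unbiased, verified to within
3 standard errors at n = 1500) and wide enough that its 99% ellipse
covers ~26% of grid cells, leaving clear margin over the top-decile
criterion. A real occurrence record's climates are constrained to a
quasi-one-dimensional manifold (few latitudes × cycle phase), which is
why envelope *covariance* recovery is necessarily approximate; the
recovery criterion is therefore stated on the suitability map (top-decile
cells inside the truth's 99% ellipse in ≥ 90% of 100 seeded runs, where a
run passes if ≥ 99% of those cells are inside), not on Σ̂ itself.

**Peak lists.** Reference masses + Gaussian jitter (default 0.05 Da) per
non-dropped marker, plus uniform noise peaks over 800–3200 Da at low
intensity. The acceptance assemblage reproduces the published screening
composition (150 spectra over five excavation squares; four
unidentifiable noise-only spectra; Equus 136 of 146 identified; one
Hominidae) and classifies every spectrum from scratch — the 97.3% success
rate is measured, not asserted.

**Calibration curves.** μ(t) = t plus a seeded sum of six smooth
sinusoids (wavelengths 0.5–5 ky) scaled to a requested wiggle amplitude;
constant curve error. Monotone on average (slope 1) but locally wiggly
like a real curve.

**Alignments.** Random reference plus sequences carrying *disjoint*
planted substitutions — so every pair's true difference count is the sum
of the two planted counts — then per-sequence N-masking at a requested
fraction (the reference is never masked). Realized counts are recovered
exactly at zero masking (tested over all pairs at 16.6 kb).

## Problem sizes

The default test and acceptance runs use: the full 63 × 49 × 121
synthetic grid for ensemble work (5,000 members ≈ 1 minute on one core);
100 recovery runs of 100 members each; 10,000 members for the balance
audit (sampling only, no grids); 16.6 kb alignments; 1,000 random cells
for the Euclidean-oracle comparison. These sizes make every statistical
check well-resolved while keeping a complete run in minutes.

## Known limitations

- The suitability model inherits the Gaussian-envelope assumption;
  multimodal or boundary-limited niches are out of scope.
- The synthetic climate's simplicity means box-level suitability curves
  should be read qualitatively (phase and ranking), not as calendar-dated
  reconstructions.
- Calibration against the real IntCal20 curve is supported but not
  self-contained (see above); the published calendar ranges are only
  checkable with a user-supplied curve file.
- Corridor/route identification between regions (e.g. least-cost paths)
  is deliberately not implemented.
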