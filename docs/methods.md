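# Methods

This note documents the models, estimators and design decisions behind
`xomap`: what each stage assumes, which parameters matter, what the
synthetic generators do and do not emulate, and where the numerically
delicate choices lie.

## 1. Map distance from fluorescent seed segregation

### Model

The measured interval is flanked by two seed-expressed fluorescent
reporters (eGFP and dsRed) carried in *cis* on one homolog of an F1
hybrid. Gametes are `RG` or `--` (parental, each with frequency
`(1−r)/2`) or `R-` / `-G` (recombinant, each `r/2`), where `r` is the
recombinant-gamete fraction. An F2 seed unites two independent gametes
and shows the union of their reporters, so each single-colour class has
probability

    p_single(r) = (1 − (1 − r)²) / 4 .

Inverting with observed counts NG (green-only), NR (red-only), NT
(total):

    cM = 100 · (1 − √(1 − 2(NG + NR)/NT)) .

A formula for this quantity is sometimes printed with the closing
square-root rendered as a division by two
(`100 × {1 − [1 − 2(NG+NR)/NT]/2}`); that reading returns 50 cM at zero
recombinants and cannot be the estimator. We implement the square-root
form, which (a) returns 0 at NG = NR = 0, (b) is the exact inverse of
the gamete model above — verified in the tests against brute-force
enumeration of all 16 ordered gamete pairs — and (c) reduces to the
familiar `100·(NG+NR)/NT` for small `r`.

Assumptions: at most one effective crossover per chromatid in the
interval (sensible for sub-cM intervals), no differential seed
viability or scoring bias between classes, independent gamete pairing.
The "other" class (two-colour plus non-fluorescent seeds) is never
subdivided.

Domain: `2(NG+NR)/NT ≤ 1`. Larger values are rejected as impossible
under the model. Bootstrap resamples that cross the boundary (possible
when resampling near it) are clamped to 100 cM rather than rejected, so
the CI procedure never fails.

### Uncertainty and aggregation

Per cross we attach a percentile bootstrap CI from multinomial
resampling of `(NG, NR, other)` at fixed NT (default `n_boot = 2000`,
`level = 0.95`, caller-supplied seed). Across crosses we report both the
unweighted mean of per-cross estimates (matching how such measurements
are usually plotted, one point per cross with a mean line) and a pooled
estimate from summed counts, which weights crosses by seed number. For
the clean multinomial data the generator produces, the two agree to
within sampling error; with real per-plant heterogeneity they can
differ, which is why both are reported.

Group comparisons (`compare_rf`) delegate to Welch's t, the pooled t, or
the Mann-Whitney U test (two-sided, tie-corrected asymptotics; two
identical groups give p = 1). These are plumbing, not contributions.

## 2. Breakpoint calling from allele depths

### Genotype model

A single-colour F2 seed carries one recombinant chromatid over a
non-recombinant Ler homolog, so the expected genotype is homozygous Ler
on one side of the crossover and Col/Ler heterozygous on the other.
Per marker, the Col-supporting read fraction decides the call:

| parameter   | default      | role |
|-------------|--------------|------|
| `min_depth` | 20 reads     | below this the marker is MISSING |
| `hom_max`   | 0.15         | fraction ≤ `hom_max` → HOM_LER; ≥ 1−`hom_max` → HOM_COL |
| `het_band`  | (0.30, 0.70) | inclusive band → HET |

Fractions between the bands are ambiguous and treated as MISSING. At
the ~1500× depths these data are produced at, both misclassification
tails are below 10⁻⁶ (binomial tails asserted in the tests); the loose
defaults keep the caller usable at far lower simulated depth. No
genotype-quality modelling beyond depth is attempted — the inputs are
allele counts, not reads.

### Segmentation and crossover denomination

Informative (non-MISSING) calls are segmented into maximal runs of
identical genotype. Exactly one HOM_LER↔HET boundary flanked by at
least `min_flank = 2` concordant markers per side yields an OK call:
the breakpoint interval is the gap between the two flanking markers,
reported 0-based half-open in BED output, with midpoint
`floor((left+right)/2)` (strictly interior whenever the gap spans ≥ 2
bp). Decisions for the degenerate cases:

- any HOM_COL call → UNEXPECTED_GENOTYPE. Such a chromatid cannot arise
  from one crossover over a Ler homolog; rather than arbitrate we flag
  the recombinant for QC.
- two or more boundaries → MULTIPLE_TRANSITIONS (double-crossover
  chromatids or noise); no arbitration between candidate boundaries is
  attempted.
- zero boundaries, or a single boundary with a flank shorter than
  `min_flank` → NO_TRANSITION. A transition supported by a single
  terminal marker is indistinguishable from a genotyping artefact at
  that marker, so it is treated as unsupported rather than called.
- fewer than two informative markers: `call_crossover` raises; the
  population mapper records NO_TRANSITION for such recombinants instead
  of aborting the run.

Marker filtering (`filter_snp_candidates`) retains biallelic candidates
whose declared parental alleles were confirmed in ≥ `min_support`
(default 0.9) of homozygous control observations; unvalidatable sites
(no observations) are dropped. This stands in for a curated
high-fidelity marker list; the criteria are ours, since list curation
is upstream of this package.

## 3. Landscapes

Crossovers enter all statistics at their interval midpoint. Rationale:
breakpoints are only localized between markers, and profiles are read
per inter-marker interval anyway; spreading each call uniformly over
its interval is available (`smear=True`) but off by default. Default
binning is the inter-marker intervals (the mapping resolution);
fixed-width bins can be passed instead.

`build_distribution` normalizes bin counts by the total number of OK
calls, so tracks from populations of different sizes are comparable;
the values sum to 1 by construction and the class invariant asserts it.
`differential_track` subtracts two normalized tracks on identical bins
and therefore sums to 0.

### Sliding-window cM/Mb track and mass conservation

`moving_average_cm_per_mb` apportions the interval's total genetic
length (cM) to windows by the fraction of OK midpoints each contains,
divided by the window length in Mb (defaults: 1-kb window, 100-bp
step). Window placement is the one numerically delicate choice. With
windows strictly inside the interval, positions near the edges are
covered by fewer than `window/step` windows and the track's integral
depends on how much crossover mass sits near the edges. We instead
align the grid to the interval start but let it overhang the start by
`window − step`, keeping the full window length in the denominator.
Every position in the interval is then covered by exactly
`window/step` windows (when `window` is a multiple of `step`), and the
discrete integral

    ∫ track ≈ Σ value_w · step / 10⁶  (Mb)

equals the supplied interval cM exactly, up to floating point
(`track_integral_cm`; asserted at 10⁻⁶ relative in the tests, observed
at machine precision). If `window` is not a multiple of `step`,
coverage varies by ±1 window and conservation is only approximate.
For bedGraph output, overlapping windows are resampled to their central
step-long segment, clipped to the interval, so rows tile the interval
without overlap.

With the window set to the whole interval the track is flat at
`interval_cm / interval_length_Mb`, which is the conventional
genome-average rate — a useful sanity anchor.

### Hotspot usage and reduction

`hotspot_usage` is the share of OK midpoints inside each annotated span
(1-based half-open; spans must not overlap), the remainder being
background. `hotspot_reduction` is share-based:

    reduction% = 100 · (1 − sample_share / control_share) ,

negative values meaning enhancement. A summed-frequency definition
within the span gives the same number on normalized tracks with
span-aligned bins; the share-based definition is the one implemented
and documented because it is well-defined regardless of binning.
Hotspot coordinates are always user-supplied annotations — none are
hard-coded.

## 4. Synthetic data: what it emulates, what it does not

The generators reproduce the statistical skeleton of the experiment:

- **Seed counts**: multinomial draws from the exact gamete model at a
  true `r` — no scoring error, no viability differences.
- **Marker maps**: uniform (markers at the declared extremes) or
  random spacing, random distinct parental alleles.
- **Breakpoints**: one per recombinant (matching single-colour seed
  selection), drawn from a hotspot mixture — named spans with weights
  plus an interval-wide uniform background. Orientation is a fair
  coin. An option injects a second, independently drawn breakpoint
  into a chosen fraction of recombinants to exercise the
  MULTIPLE_TRANSITIONS path.
- **Allele depths**: per marker, depth ~ Poisson(mean) — so MISSING
  handling is exercised at low means — and Col-supporting reads ~
  Binomial(depth, p(1−e) + (1−p)e) with true Col fraction p ∈ {0, 0.5}
  and symmetric flip error e (default 0.002). No indels, no mapping or
  reference bias, no PCR duplicates, no amplicon-boundary coverage
  structure: the pipeline consumes allele depths, so error enters only
  as fraction distortion.

Consequently, passing tests demonstrate correctness of the estimators
and the calling/normalization logic under the declared noise model —
they do not certify robustness to alignment artefacts, segregating
structural variation, or allele-specific amplification bias in real
amplicon data. Those failure modes arrive through the allele-depth
table and should be handled upstream or via the marker filter.

### Default study conditions

The default synthetic interval is 40 kb with 101 uniformly spaced
markers (~400-bp resolution, the scale of an amplicon-sequenced
reporter interval) carrying three hotspots, the central one strongest:
weights 0.20 / 0.45 / 0.25 with 0.10 background (`chp_like_model`).
Genetic length defaults to 0.33 cM for cM/Mb tracks; populations of
243 control and 164 sample recombinants at 1500× mean depth with 0.2%
error mirror the design such data sets are produced under. The
seed-scoring demo in `analysis/01` uses 8 crosses × 6000 seeds per
genotype, a realistic scoring effort that gives ~20–30 recombinant
seeds per cross — enough for the rank test across crosses to resolve a
0.33 vs 0.52 cM contrast, while a smaller design typically would not.

Two constructional details make parameter recovery exact in
expectation rather than merely approximate:

- **Hotspot spans are snapped to marker positions.** Crossovers enter
  statistics at inter-marker midpoints. If a hotspot edge cut through
  a gap, all breakpoints in that gap would be attributed to whichever
  side holds the gap midpoint — up to half a gap of the hotspot's
  (high) edge density, several share points at these marker densities.
  With span edges on markers, a span contains a midpoint exactly when
  it contains the true breakpoint, so usage shares are unbiased at
  marker resolution.
- **Suppression is built in share space.** `suppress_hotspot` returns
  a mixture whose *normalized* span probability at the target hotspot
  is exactly `(1 − reduction/100)` times the original, with all other
  weights scaled up to keep the total at 1 (suppressed crossovers
  reappear elsewhere, as normalization dictates). Naively scaling the
  raw component weight would not reproduce the nominal reduction after
  normalization. The recovery study pools shares across replicates
  before forming the ratio, avoiding the O(CV²) small-sample bias of
  averaging per-replicate ratios.

## 5. Verification surface and problem sizes

`xomap.evaluation` packages the recovery studies; the test suite
asserts on them and `scripts/acceptance.py` re-runs and reports them.
Sizes were chosen so the full suite runs in well under a minute on one
core: 1000 datasets × 2000 bootstrap resamples for estimator recovery
and CI coverage (target band 93–97% for the 95% CI); 500 recombinants
at study depth for breakpoint recovery (≥ 99% OK, truth containment in
every OK interval); 200 paired replicates of 243 + 164 recombinants
for the 47.2% reduction recovery (within 2 pooled binomial SE,
observed SE ≈ 0.6 points).

## 6. Pipeline determinism

Every stochastic call takes an explicit seed. The pipeline derives one
seed per stage as `SHA-256(master_seed ":" stage_name) mod 2³¹`, so
stages are decoupled (inserting a stage never shifts another stage's
stream) and a config fully determines all outputs; the manifest records
resolved parameters, stage seeds and SHA-256 checksums of every output,
and re-running a config reproduces the checksums byte-for-byte. Config
validation is schema-based via pydantic: referenced files must exist
and a master seed is required before any stage runs.

## 7. Known limitations

- One crossover per recombinant is assumed biologically and enforced
  computationally; true double crossovers are rejected, not recovered.
- The caller presumes the Ler-homolog cross design; other cross
  geometries (e.g. Col homolog, hence HOM_COL blocks) would need the
  expected-genotype pair generalized.
- Bootstrap CIs are percentile CIs; at very low counts (a handful of
  recombinant seeds) they are conservative near zero and coverage is
  discreteness-limited.
- Midpoint placement concentrates each crossover's mass at one point;
  at very uneven marker spacing the smear mode is the better choice
  for landscape shape, at the cost of the crisp per-gap resolution.
- No statistical test is attached to per-bin landscape differences;
  the differential track is descriptive.
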