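# Methods

## The curation model

The pipeline treats a trait record as one measurement of one quantitative
trait on one species, carried with provenance (source dataset, optional
location and date) and metadata (maturity, health, growth conditions, light
exposure). Its central statistical assumption is that quantitative plant
traits are approximately log-normal: all screening and aggregation happen on
log₁₀-transformed values. Base 10 is a deliberate choice — the two dominant
error modes in compiled trait data, wrong units and misplaced decimal
points, are integer shifts on log₁₀ scale, which makes them maximally
separable from biological variation.

### Hierarchical z-scores

Taxonomy is informative about trait values: congeners resemble each other
more than confamilials, and so on. Outlier screening therefore computes, per
record, `z = (log₁₀x − μ̂)/σ̂` within each of four nested groups — species,
genus, family, all records of the trait — and takes the maximum |z|. Under
normality a true value lies within ±3 SD of its group mean with probability
99.73% and within ±4 SD with 99.99%, so the decision rule is:

* max |z| > 4 → exclude (almost certainly a wrong unit, a decimal error, a
  wrong species attribution, or a trait-definition problem);
* 3 < max |z| ≤ 4 → flag for review (retained by default; the `strict`
  policy excludes instead — in production use this band goes to experts);
* otherwise retain.

Sample SDs from small samples are unreliable, so a taxon with fewer than
`n_min` records (default 5; SD estimates at n < 5 are noisy enough to both
mask errors and create false alarms), or with a degenerate SD of zero,
borrows the unweighted average of the reliable SDs at its level — the spread
one would expect for a typical taxon of that rank. A level with no reliable
taxon at all borrows from the next-higher level (species → genus → family →
all).

Statistics are estimated in a single pass over the post-imputation record
set, matching standard practice. A single pass has a known weakness under
contamination: a decade-scale error inside a small species sample drags that
species' estimated mean by up to a full log unit, so the error's clean
group-mates can cross the exclusion threshold themselves. The detector
therefore offers a `second_pass` option that re-estimates all statistics on
the survivors of the first pass and rescores every record. On the
error-injection benchmark (1% decade errors) the single pass excludes about
0.25% of clean records; the second pass cuts that to ~0.01% while still
excluding 100% of the injected errors. The default remains single-pass; the
benchmark uses the two-pass variant and this is the reason.

### Imputation rules

* **SSD from LDMC** (herbaceous species only): stem dry matter content is
  close to a 1:1 proxy of stem specific density in herbs, and StDMC is
  linearly predictable from the far-better-covered leaf dry matter content.
  Slopes differ among groups, so three equations are used —
  monocots 0.888·LDMC + 0.027, Fabaceae 0.692·LDMC + 0.048, other dicots
  0.524·LDMC + 0.096 — with a pooled all-species line 0.698·LDMC + 0.058 as
  fallback for species whose dicot status is unknown. With both ratios in
  g g⁻¹ the prediction reads directly as SSD in mg mm⁻³. The rule is applied
  per species (one imputed record from the geometric mean of the species'
  LDMC records), never to woody species, and never when a measured SSD
  exists. Species of unknown or semi-woody woodiness are treated as woody
  (no imputation) — erring toward missingness rather than a wrong estimate.
  Note the monocot and other-dicot lines cross near LDMC ≈ 0.19; the
  monocot prediction is the larger one only above the crossing, which is
  where essentially all real LDMC values lie.
* **LMA = 1/SLA**, a unit-consistent reciprocal applied per record.
* **N_mass = 1000·N_area/LMA** (mg g⁻¹ from g m⁻² twice), only when both
  values come from the same observation (same leaf); species-level pairing
  would conflate within-species variation and is skipped.
* **Spore mass** for pteridophytes: spheres of radius r (mm) and density
  0.5 mg mm⁻³, mass = 0.5·(4/3)πr³. Typical spore radii (5–50 µm) give
  masses of order 10⁻⁸–10⁻⁴ mg, several orders below typical seed masses.

Every imputed value carries the `imputed` flag through to the species table,
where each trait's `imputed_fraction` is reported.

### Duplicates and aggregation

Two records are duplicates when they agree on species and trait, their
values differ by at most `rel_tol` (default 10⁻³ — three significant figures
is typical legacy reporting precision), and neither differing locations nor
differing dates give positive evidence that they are distinct measurements.
Clusters are the transitive closure of this relation; the representative is
the record with the most non-missing metadata, ties broken by input order.
Species means are geometric (10^mean of log₁₀ values), computed over
retained plus review-band records under the default policy, without
stratification by dataset or site. Missing cells are empty, never 0 or a
sentinel.

## The synthetic generator

The generator is the package's benchmark instrument, not a model of any
particular holding. It draws a taxonomy (families → genera → species, each
family assigned one higher-rank group), then per species and trait
`log₁₀(value) = μ_trait + family + genus + species + within-record` with
independent zero-mean normal effects. Defaults: within-species SD 0.1 and
between-species SD ≈ 0.38 on log₁₀ (family 0.25, genus 0.20, species 0.20),
so a 10³ unit error is a z ≈ 30 event at the species level while a two-fold
biological extreme is z ≈ 1 — the separation the method relies on. Global
log₁₀ means are realistic for vascular plants (height ~1.6 m, SSD
~0.47 mg mm⁻³, leaf area ~1.3×10³ mm², LMA ~72 g m⁻², N ~19 mg g⁻¹, seed
mass ~2.6 mg, LDMC ~0.25 g g⁻¹). LDMC's components are scaled down (total SD
~0.16) because it is a bounded ratio with genuinely low variance — and the
SSD imputation needs it inside (0, 1).

Records-per-species counts are zero-truncated geometric (default mean 6), so
the mean exceeds the median as in real compilations, where a few species are
sampled hundreds of times and most once or twice. Records are spread over
three synthetic datasets with distinct unit dialects and trait-term
dialects; 10% of LMA records are emitted as SLA (the reciprocal) to exercise
the imputation path, and by default non-woody species get no measured SSD at
all, mirroring the real scarcity that motivates the LDMC rule. About 15% of
records use a synonym instead of the accepted name, and metadata fields are
blanked to "unknown" at rate 0.3.

Error injection assigns each record at most one error: wrong-unit and
decimal-shift errors multiply the stored value by 10^k (k ∈ ±{1,2,3}),
species swaps reattribute the value to a random other species,
non-representative errors set juvenile/experimental metadata, and duplicates
append a clone with blanked location/date and an optional ≤0.05% value
perturbation. The injection rates are free parameters of the benchmark, not
calibrated to any real archive (real error rates are unknown); the
benchmarks use 1–2% per kind. Every injection is logged in the ground-truth
table, including each record's true species, true value in standard units,
and its species-level log₁₀ mean.

What the generator does *not* emulate — and hence what passing benchmarks do
not establish about real data: correlated measurement error within a
dataset, non-normal heavy-tailed biological variation (succulents,
aquatics), spatial/climatic structure in sampling, trait–trait correlation
is off by default (a species-level correlation matrix is supported), and
name-resolution ambiguity beyond simple synonymy. Recovery rates on real
archives will be lower than on this clean test bed, particularly for errors
smaller than a decade.

## Numerical and design choices

* Sample SDs use the n−1 denominator; a taxon's own SD is trusted only when
  n ≥ `n_min` **and** SD > 0 (an all-identical sample is almost always a
  duplication artifact, and using SD = 0 would make every deviation
  infinite).
* Offset diagnosis compares group vs. rest-of-trait medians of log₁₀ values
  (medians, to resist the very outliers being hunted); a finding requires
  the offset to be within 0.2 of a non-zero integer and both sides to have
  ≥ 20 records. Findings are report-only by default because tracing a
  dataset-wide offset to its cause is a human step; `auto_correct` applies
  ×10⁻ᵏ and flags the records.
* Shade-leaf exclusion applies only to leaf traits (LA, LMA, N_mass, SLA,
  N_area, LDMC): height, stem density, and seed mass are not leaf
  measurements. Unknown metadata never causes exclusion.
* Name resolution is strictly table-driven (exact > synonym > orthographic
  normalization); fuzzy matching (edit distance 1, unique hit required) is
  an explicit opt-in because silent mis-resolution is worse than rejection.
  Infraspecific names collapse to the binomial by default.
* Tie-breaks are deterministic everywhere (extremes by species name, dedup
  representatives by input order), and all randomness flows from a single
  user seed, so a rerun is byte-identical.
* Degenerate inputs: empty record sets produce empty partitions; a trait
  with no usable SD anywhere in the hierarchy is an error rather than a
  silent pass-through; rates summing above 1, negative SD components, and
  unknown config keys all fail fast before any processing.

## Benchmark problem sizes

The acceptance benchmarks run at sizes chosen to make their statistics
stable while staying desk-scale: error recovery on ~46,000 records (1,200
species, 1% decade errors — recovery and false-positive rates are then
determined to well under a percentage point), parameter recovery on 1,200
species × 25 records per trait (~5,400 measured species×trait cells; at the
±2σ/√n criterion the expected coverage is 95.45%, so observed values
hover just above 95%), oracle agreement on 1,000 records, and the
conservation/determinism checks on a ~4,000-record default run.

## Known limitations

* The imputation coefficients are constants; the package does not refit
  them, and applying them to taxa far outside their calibration range
  (herbaceous temperate species) is unvalidated.
* The review band has no automatic adjudication — only retain-all or
  exclude-all policies; a real deployment would route it to experts.
* Deduplication cannot distinguish true replicate measurements that were
  rounded to the same value at the same unknown site from genuine
  duplicates; the location/date guard is only as good as the provenance
  metadata.
* Dataset-offset detection assumes at least one trait-decade of separation;
  subtler calibration offsets (×2, ×5) pass through by design.
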