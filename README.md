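# traitcurate

Curation pipeline for heterogeneous plant functional trait records.

Species-level trait compilations (the TRY database and the datasets built on
it are the archetype) merge hundreds of independently collected sources. The
same trait arrives under different names ("SLA", "specific leaf area"), in
different units (cm², mm², m²), under inconsistent species names, with
occasional wrong-unit or misplaced-decimal values, with measurements from
juvenile or greenhouse-grown plants, and with the same measurement reported
twice. `traitcurate` implements the standard curation sequence that turns
such raw record streams into a defensible species-mean trait table:

1. **Semantic integration** — free-text trait terms and metadata mapped onto
   controlled vocabularies.
2. **Taxonomic consolidation** — species names resolved against a reference
   table of accepted names and synonyms, attaching genus, family, and
   higher-rank group.
3. **Unit standardization and error exclusion** — conversion to one standard
   unit per trait (height m; stem specific density mg mm⁻³; leaf area mm²;
   leaf mass per area g m⁻²; leaf N mg g⁻¹; diaspore mass mg), diagnosis of
   whole datasets sitting a power of ten off the rest, and exclusion of
   impossible (non-positive) values.
4. **Rule-based imputation** — stem specific density of herbaceous species
   from leaf dry matter content via group-specific linear regressions
   (SSD ≈ StDMC = a·LDMC + b, with separate coefficients for monocots,
   Fabaceae, and other dicots); LMA = 1/SLA; N_mass = N_area/LMA for
   same-leaf pairs; fern spore mass as density × (4/3)πr³. Every imputed
   value is flagged, and a measured value always wins over an imputed one.
5. **Hierarchical outlier screening** — on log₁₀ scale each record gets a
   z-score `(log₁₀x − μ̂)/σ̂` within its species, genus, family, and the
   whole record set. Under log-normality fewer than 0.1% of true values lie
   beyond 4 SD of any taxon mean, so records with max |z| > 4 are excluded
   and 3 < |z| ≤ 4 is flagged for review. Taxa with too few records for a
   reliable SD borrow the average SD of their taxonomic level.
6. **Duplicate exclusion** — same species and trait, values equal to within
   rounding, and no evidence of distinct location or date.
7. **Species means** — geometric means per species and trait (log-normal
   traits), joined with categorical traits (woodiness, growth form, …) and
   summarized in validation reports (per-trait ranges, the ten most extreme
   species in each direction).

Because real holdings cannot ship with a library, the package includes a
first-class synthetic generator (`traitcurate.synth`) that emulates the
relevant structure — log-normal traits with variance partitioned across
family/genus/species/within-species levels, right-skewed records-per-species
counts, multiple dataset "dialects" — and injects errors of every kind above
with full ground truth, so each stage's recovery can be measured.

## Worked example

```python
import traitcurate as tc

tables = tc.generate_dataset(tc.GeneratorConfig(
    seed=42,
    errors=tc.ErrorInjectionSpec(unit_shift=0.005, decimal_shift=0.005,
                                 species_swap=0.005, nonrepresentative=0.01,
                                 duplicate=0.02)))
result = tc.run_pipeline(records=tables["records"],
                         taxonomy=tables["taxonomy"],
                         categorical=tables["categorical"])
for entry in result.log:
    print(entry)
print(result.summary.round(3).to_string(index=False))
```

prints (abridged):

```
{'stage': 'filter_nonrepresentative', 'records_in': 6643, 'records_out': 6577,
 'rejects_by_reason': {'juvenile': 34, 'experimental': 32}}
{'stage': 'impute', 'records_in': 6577, 'records_out': 6680, 'imputed': 201}
{'stage': 'classify_records', 'records_in': 6680, 'records_out': 6615,
 'excluded': 65, 'review': 25}
{'stage': 'deduplicate', 'records_in': 6615, 'records_out': 6453,
 'duplicates_removed': 162}

trait  n_species  geometric_mean     min       max  mean_n  median_n
    H        167           1.710   0.256    21.114   6.641       5.0
  SSD        168           0.316   0.026     4.492   2.982       1.0
   LA        166        1505.381 246.874 10584.178   5.771       4.0
  LMA        166          73.969   6.761   320.735   5.476       4.0
Nmass        168          27.735   2.972   159.172   5.744       4.0
   SM        164           2.340   0.191    13.275   5.744       4.0
```

Reading it: 66 juvenile/greenhouse records were dropped on their metadata;
201 values were imputed (reciprocal SLA→LMA conversions plus one
species-level SSD estimate per herbaceous species with LDMC data); 65
records — dominated by the injected decade-scale errors — were excluded with
max |z| > 4; 162 near-identical same-species records were collapsed. The
summary mirrors the standard per-trait validation table: species counts,
geometric mean of the species means, range, and the mean vs. median number
of records per species (mean ≫ median: a few species are sampled heavily,
most barely). Every input record's fate is in `result.record_fates`, and
per-record z-scores at all four taxonomic levels are in
`result.zscore_report`.

The same flow is available from the shell:

```bash
traitcurate generate --seed 42 --out data/
traitcurate run --records data/records.csv --taxonomy data/taxonomy.csv \
    --categorical data/categorical.csv --out out/
traitcurate report --out out/
```

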