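# mitschema

Nanosafety research produces multidisciplinary data — engineered
nanomaterial (ENM) characterization, biological test systems, exposure and
dosimetry, assay readouts, statistics — that is rarely reported completely
enough to be reused. `mitschema` implements a **minimum information table
(MIT)** for nanosafety as a machine-readable, modular metadata schema, and
the bookkeeping needed to work with it:

- a bundled **reference schema**: six modules (general information,
  material information, biological model information, exposure information,
  endpoint read out information, analysis and statistics) holding 33
  grouping fields and 300 content-bearing labeled fields (333 total), with
  synonyms (e.g. *zeta potential* / *surface charge*) and in vitro / in
  vivo applicability branching;
- **record validation and completeness scoring**: check an experiment's
  metadata record against the schema and measure the fraction of applicable
  fields it fills, per module and overall;
- **crosswalk construction** against external vocabularies ingested as flat
  term tables, following the source-to-target principle: *exact* (one-to-one,
  identical normalized naming), *partial* (deviating or more general names,
  token-subset rule scored by Jaccard similarity), or *none*, with curated
  decisions overriding automatic ones;
- **coverage statistics**: matched/total counts and integer percentages
  (half-up rounding) per module, per field category and overall, in
  one-to-one and partial modes — e.g. a crosswalk with 8 of 33 grouping and
  105 of 300 content-bearing exact matches reports 113/333 = 34% overall;
- **extension profiles** for new approach methodologies (air–liquid
  interface, advanced intestinal, 3D skin models);
- an **ISA-TAB-like exporter** routing record values into the
  Investigation / Study / Assay / Material four-file layout;
- **synthetic fixture generators** with planted ground truth for testing
  matchers and completeness scoring.

## Worked example

```python
from mitschema import (
    build_reference_mit, schema_stats, generate_record, completeness_score,
    PlantSpec, generate_vocabulary, auto_crosswalk, coverage_report,
)

mit = build_reference_mit()
print(schema_stats(mit).as_dict())
# {'modules': 6, 'grouping_fields': 33, 'content_bearing_fields': 300,
#  'total_fields': 333, 'per_module_content_bearing': {
#   'general_information': 22, 'material_information': 32,
#   'biological_model_information': 69, 'exposure_information': 48,
#   'endpoint_readout_information': 98, 'analysis_statistics': 31}}

# completeness of a half-filled record
rec = generate_record(mit, p_present=0.5, seed=3)
report = completeness_score(rec, mit)
print(round(report.overall_fraction, 3))   # 0.467

# crosswalk a planted vocabulary and report coverage
vocab, truth = generate_vocabulary(mit, PlantSpec(0.4, 0.3, 0.3, seed=7))
xw = auto_crosswalk(mit, vocab)
print(xw.decisions == truth)               # True (planted truth recovered)
cov = coverage_report(xw, "one_to_one")
print(cov.by_stratum["overall"].percent)   # 40  (133 exact of 333)
```

The counts mean: of the 333 labeled fields, 133 were planted as exact
copies in the vocabulary (`round(0.4 * 333)`), and the matcher recovered
every planted decision, so one-to-one coverage is 133/333 = 40%.

The same operations are available from the shell:

```bash
mitschema schema stats reference
mitschema schema merge reference --profile ali --format json
mitschema fixtures record --p-present 0.5 --seed 3 -o rec.json
mitschema record score rec.json --schema reference --json
mitschema map auto --schema reference --vocab vocab.tsv -o crosswalk.tsv
mitschema map coverage crosswalk.tsv --schema reference --mode partial
```

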