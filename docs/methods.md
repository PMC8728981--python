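# Methods

## The schema model

A schema is a versioned container of modules; each module groups *labeled
fields* under named subdivisions (depth one: module → subdivision, matching
the table's printed structure).  A labeled field is either a *grouping*
field — a structural header that organises the table and never holds a
record value — or a *content-bearing* field that does.  Fields carry
synonyms, an applicability branch (`always`, `in_vitro_only`,
`in_vivo_only`), a requirement level (`minimum` / `recommended` /
`optional`), a value kind (`free_text`, `quantity_with_unit`,
`controlled_term`, `identifier`, `boolean`), an optional unit hint, and a
provenance tag naming the standard or guideline family the field traces to.

### The bundled reference schema

The reference table has six modules and 333 labeled fields: 33 grouping
fields and 300 content-bearing fields distributed 22 / 32 / 69 / 48 / 98 /
31 over general information, material information, biological model
information, exposure information, endpoint read out information, and
analysis and statistics.  The complete published field inventory is not
reproduced in the source text, so the bundled inventory is a
reconstruction that is exact in structure: fields named in the published
description (experiment name, compound name, major use, zeta potential
with synonym surface charge, dispersion protocol, passage number, seeding
density, plate format, delivered dose, statistic, the flow cytometry /
light microscopy / electron microscopy instrument blocks, ...) appear
verbatim; the remainder are filled in from the module and subdivision
descriptions and tagged `provenance="reconstructed"`.  Grouping fields are
the 33 subdivision headers, distributed 4 / 6 / 8 / 6 / 6 / 3 per module;
the source states only their total, so no per-module grouping invariant is
asserted anywhere.

All 300 reference fields default to `requirement=minimum`: the source
defines the whole table as minimum information and leaves contextual
subsetting to the experiment, so requirement levels are data a user can
edit, not a claim baked into the reference.

Field ids are lowercase snake-case slugs of the primary name (grouping
fields are module-prefixed since subdivision names repeat across modules).
The canonical serialization is CSV — one row per labeled field, schema and
module attributes in `#key=value` header lines — mirroring the
spreadsheet shape of the source artifact; JSON and XML are lossless
projections of the same content.  Writers are deterministic, so
load → save → load is byte-stable, which the suite asserts for all three
dialects.

### Extension profiles

Complex new-approach methodologies need metadata the base table lacks.
Three bundled profiles add fields under profile-named subdivisions of the
existing modules: `ali` (aerosol generation, dilution, volume, flow
alignment and particle deposition; apical culture conditions; epithelial
barrier function), `intestine_advanced` (food matrix and digestion
simulation, mucus verification, specialised cell types, peristalsis and
shear stress), and `skin_3d` (commercial model identity, UV damage state,
irritation / sensitization / corrosion readouts, dermal penetration
depth).  Merging is collision-checked (re-applying a profile raises), tags
added fields with the profile id, and leaves every base field untouched.

## Record validation and completeness

A metadata record maps field ids to value lists and declares a model
context (`in_vitro`, `in_vivo`, `both`).  Validation flags unknown keys,
values on grouping fields, value-kind violations (e.g. a non-numeric
string in a quantity field — numbers accept an optional unit suffix and
the Unicode minus), and applicability violations (an in-vivo-only field in
an in-vitro record).  Emptiness is deliberately not a validity finding: an
empty record is clean but scores zero.  A schema-version mismatch is an
error, not a finding, because no downstream number would be meaningful.

Completeness is `n_present / n_applicable` per module and overall, where a
field is applicable if it is content-bearing, its applicability matches
the record's model context (`both` keeps every branch applicable — the
conservative, largest denominator), and its requirement level is at least
the chosen floor (`minimum` is the most demanding level, so
floor=`minimum` counts only the mandatory core and floor=`optional`
counts everything; the denominator is non-increasing as the floor rises).
Presence means at least one non-empty value; the explicit sentinel
`"not applicable"` (or `"n/a"`) counts as present because the experimenter
addressed the field — a completeness audit must distinguish omission from
stated inapplicability.  Unknown keys never count toward completeness:
the score measures schema coverage, not data volume.

## Matching

The published compatibility analysis was expert work in spreadsheets; this
package implements a deterministic algorithmic proxy plus a curated layer
so published decisions can be loaded as data, with precedence
curated > exact > partial > none.  The proxy makes no claim to replicate
expert judgment — it makes the bookkeeping reproducible.

- **Normalization**: case-fold, strip punctuation, collapse whitespace,
  tokenize.  Idempotent and deterministic.
- **Exact (one-to-one)**: normalized sequence equality between any field
  variant (name or synonym) and any term variant.  Score 1.
- **Partial**: candidate iff one normalized token set is a non-empty
  subset of the other (the "protocol" ⊂ "dispersion protocol" pattern);
  score is the Jaccard similarity of the token sets, maximised over
  variant pairs; pairs that are exact by sequence equality are excluded.
  Default threshold `min_score=0.25` admits a one-token generalisation of
  a two-token label (score 0.5) while rejecting single-token overlap in
  long labels; it is exposed as a parameter and CLI flag.
- **Tie-breaks** are lexicographic on term id everywhere (best score first,
  then lowest id), so identical inputs always yield identical crosswalks.
- A crosswalk is a *total function*: exactly one decision per labeled
  field, grouping fields included (they are matched like any field but
  reported in their own stratum).

## Coverage statistics

`coverage_report` recounts a crosswalk per stratum — each module (over its
content-bearing fields), the grouping category, the content-bearing
category, and overall — in two modes: `one_to_one` counts exact decisions
only; `partial` counts exact ∪ partial, so partial-mode counts dominate
one-to-one counts in every stratum by construction.  Percentages are
integers under **half-up rounding**, computed in exact integer arithmetic
(`(200·m + t) // (2·t)`); half-up is the unique convention consistent with
every published (count, total, percent) pair (e.g. 55/333 = 16.52 → 17 but
11/31 = 35.48 → 35).  Zero-total strata report 0% flagged as empty rather
than erroring, since profiles can create empty strata.

`crosswalk_fixture_from_counts` builds a deterministic crosswalk realizing
requested per-stratum exact/partial counts (fields filled in schema
order).  This is the harness that reproduces published aggregate figures
without their underlying field-by-field decisions, which are not
algorithmically derivable.  Two published inconsistencies are handled by
checking each printed pair individually: the eNanoMapper per-module counts
are treated as one-to-one figures because they sum exactly to the
one-to-one content total (14+29+16+13+22+11 = 105) although the
surrounding text discusses partial mapping; and the ISA-TAB-Nano
per-module partial counts (sum 183) are not cross-checked against the
printed overall partial count (257 of 300), which they contradict.

## Synthetic generators

`generate_vocabulary` plants, per schema field, an exact copy of its
label, a token-perturbed partial label, or an unrelated random label, and
returns the planted decisions alongside, so matcher recovery is asserted
*exactly* rather than probabilistically.  Plant counts are allocated
deterministically (`round(p·n)`), and the seed only shuffles which field
receives which plant.  Construction guarantees recoverability:

- "none" labels draw tokens from an alphabet disjoint from every field
  name, so they can never fire the subset rule;
- fields whose names nest inside one another (token-set subset, synonyms
  included) are grouped and assigned as a block, never split between
  matchable and unmatchable plants;
- partial perturbations (default: drop one token; `add_qualifier_token`
  appends a disjoint-alphabet token, also the fallback for one-token
  names) are placed only where the perturbed label has no subset relation
  with any other field's variants.

The generator emulates the *bookkeeping* conditions of a crosswalk — one
candidate term per field, clean token structure — and none of the
messiness of real ontologies (polysemy, near-synonyms, multi-candidate
competition, multilingual labels).  Passing recovery tests therefore
validates the matcher's contract, not its performance against real
vocabularies, which is out of scope by design.

`generate_record` fills each applicable content-bearing field
independently with probability `p_present` (quantity fields get a random
magnitude with the field's unit hint), deterministic under the seed.  At
`p_present=0.5` over the 300 reference fields the observed completeness is
checked against the two-sided 99% normal band 0.5 ± 2.5758·√(0.25/300) ≈
0.5 ± 0.074.

## ISA-TAB-like export

Records export to the Investigation / Study / Assay / Material four-file
TSV layout (`i_*.txt`, `s_*.txt`, `a_*.txt`, `m_*.txt`).  Module routing
follows the stated correspondence — general information → investigation,
biological model information → study, material information → material,
endpoint read out information → assay — and, because the target format has
no dedicated modules for exposure or statistics, exposure information
rides in the study table and analysis/statistics in the assay table (the
target lists statistics only as an assay-file field).  Values are emitted
as generic `Parameter Value[<field name>]` columns; each value lands in
exactly one table (count conservation is tested) and re-import recovers
the field → values mapping.  This is a convenience exporter, not a
validating ISA-TAB implementation: no Investigation-file ontology-source
section management, no multi-study bundles.

## Problem sizes and determinism

All tests and the acceptance script run on the 333-field reference schema
(vocabularies of 333 terms, records of ≤ 300 values) — the full size of
the artifact, since nothing here scales beyond desk scale.  Every source
of randomness is an explicit integer seed; hypothesis runs derandomised
with a fixed example budget.

## Known limitations

- The reconstructed field inventory is structurally exact but nominally
  approximate outside the fields named in the published text; downstream
  users mapping real vocabularies should treat `provenance=reconstructed`
  fields accordingly.
- Matching is lexical only: no fuzzy edit distance, no embeddings, no
  multilingual normalization, no use of vocabulary hierarchy (parent links
  are stored and validated but not consulted).
- Completeness scoring does no semantic value checking or unit conversion;
  a present-but-wrong value counts as present (validation, not
  completeness, is where kind violations surface).
- Ontologies must be flattened to the term-table TSV by the user; OWL/OBO
  parsing is out of scope.
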