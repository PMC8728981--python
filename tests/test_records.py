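"""Record validation and completeness scoring."""

import math

import pytest

from mitschema import (
    MetadataRecord,
    ModelContext,
    Requirement,
    SchemaVersionError,
    completeness_score,
    generate_record,
    load_record,
    save_record,
    validate_record,
)
from mitschema.records import FindingKind


def _record(reference, values, context=ModelContext.both):
    return MetadataRecord(
        record_id="r1",
        schema_version=reference.version,
        model_context=context,
        values=values,
    )


class TestValidation:
    def test_quantity_with_unicode_minus_is_clean(self, reference):
        rec = _record(reference, {"zeta_potential": ["−30 mV"]})
        assert validate_record(rec, reference) == []

    def test_empty_record_is_valid(self, reference):
        assert validate_record(_record(reference, {}), reference) == []

    def test_in_vivo_field_in_in_vitro_record_flagged(self, reference):
        rec = _record(
            reference,
            {"housing_conditions": ["open cages"]},
            context=ModelContext.in_vitro,
        )
        findings = validate_record(rec, reference)
        assert [f.kind for f in findings] == [FindingKind.applicability]

    def test_both_context_accepts_either_branch(self, reference):
        rec = _record(
            reference,
            {"housing_conditions": ["open cages"], "passage_number": ["12"]},
        )
        assert validate_record(rec, reference) == []

    def test_unknown_key_flagged(self, reference):
        findings = validate_record(
            _record(reference, {"no_such_field": ["x"]}), reference
        )
        assert [f.kind for f in findings] == [FindingKind.unknown_field]

    def test_non_numeric_quantity_flagged(self, reference):
        findings = validate_record(
            _record(reference, {"zeta_potential": ["negative-ish"]}), reference
        )
        assert [f.kind for f in findings] == [FindingKind.value_kind]

    def test_not_applicable_sentinel_passes_any_kind(self, reference):
        rec = _record(reference, {"zeta_potential": ["not applicable"]})
        assert validate_record(rec, reference) == []

    def test_value_on_grouping_field_flagged(self, reference):
        grouping = next(
            f.field_id
            for f in reference.iter_fields()
            if f.category.value == "grouping"
        )
        findings = validate_record(_record(reference, {grouping: ["x"]}), reference)
        assert [f.kind for f in findings] == [FindingKind.grouping_field_value]

    def test_version_mismatch_is_an_error_not_a_finding(self, reference):
        rec = MetadataRecord("r", "9.9", ModelContext.both, {})
        with pytest.raises(SchemaVersionError):
            validate_record(rec, reference)


class TestCompleteness:
    def test_saturated_record_scores_one(self, reference):
        rec = generate_record(reference, 1.0, seed=1)
        report = completeness_score(rec, reference)
        assert report.overall_fraction == 1.0
        assert report.missing_minimum == []

    def test_empty_record_scores_zero_and_lists_all_minimum(self, reference):
        report = completeness_score(_record(reference, {}), reference)
        assert report.overall_fraction == 0.0
        assert len(report.missing_minimum) == report.overall_applicable == 300

    def test_half_presence_within_binomial_99pct_band(self, reference):
        # p=0.5 over the 300 applicable fields; 99% two-sided normal band
        rec = generate_record(reference, 0.5, seed=11)
        report = completeness_score(rec, reference)
        assert report.overall_applicable == 300
        half_width = 2.5758 * math.sqrt(0.25 / 300)
        assert abs(report.overall_fraction - 0.5) < half_width

    def test_sentinel_counts_as_present(self, reference):
        report = completeness_score(
            _record(reference, {"zeta_potential": ["n/a"]}), reference
        )
        assert report.overall_present == 1

    def test_unknown_keys_do_not_count(self, reference):
        report = completeness_score(
            _record(reference, {"bogus": ["x"]}), reference
        )
        assert report.overall_present == 0
        assert report.unknown_fields == ["bogus"]

    def test_in_vitro_context_shrinks_denominator(self, reference):
        both = completeness_score(_record(reference, {}), reference)
        vitro = completeness_score(
            _record(reference, {}, context=ModelContext.in_vitro), reference
        )
        assert vitro.overall_applicable < both.overall_applicable
        # the in-vivo-only fields are exactly what disappears
        n_vivo_only = sum(
            1
            for f in reference.iter_fields()
            if f.category.value == "content_bearing"
            and f.applicability.value == "in_vivo_only"
        )
        assert both.overall_applicable - vitro.overall_applicable == n_vivo_only

    def test_adding_a_value_never_decreases_fractions(self, reference):
        rec = generate_record(reference, 0.3, seed=5)
        base = completeness_score(rec, reference)
        absent = next(
            f.field_id
            for m in reference.modules
            for f in m.content_fields()
            if f.field_id not in rec.values
        )
        rec.values[absent] = ["something"]
        grown = completeness_score(rec, reference)
        for b, g in zip(base.per_module, grown.per_module):
            assert g.fraction >= b.fraction
        assert grown.overall_fraction > base.overall_fraction

    def test_floor_monotonicity_of_denominator(self, reference):
        # demote one field so the floors actually differ
        from dataclasses import replace

        schema = reference
        module = schema.modules[0]
        module_fields = list(module.fields)
        idx = next(
            i
            for i, f in enumerate(module_fields)
            if f.category.value == "content_bearing"
        )
        module_fields[idx] = replace(
            module_fields[idx], requirement=Requirement.optional
        )
        from mitschema import Module, Schema

        patched = Schema(
            schema.schema_id,
            schema.version,
            [Module(module.module_id, module.name, module.subdivisions, module_fields)]
            + schema.modules[1:],
        )
        rec = _record(patched, {})
        n_by_floor = [
            completeness_score(rec, patched, floor).overall_applicable
            for floor in (Requirement.optional, Requirement.recommended, Requirement.minimum)
        ]
        assert n_by_floor[0] >= n_by_floor[1] >= n_by_floor[2]
        assert n_by_floor[0] == 300 and n_by_floor[2] == 299

    def test_per_module_present_sums_to_overall(self, reference):
        rec = generate_record(reference, 0.4, seed=9)
        report = completeness_score(rec, reference)
        assert sum(m.n_present for m in report.per_module) == report.overall_present
        assert (
            sum(m.n_applicable for m in report.per_module)
            == report.overall_applicable
        )


class TestRecordIO:
    @pytest.mark.parametrize("suffix", [".json", ".csv", ".tsv"])
    def test_round_trip(self, reference, tmp_path, suffix):
        rec = generate_record(reference, 0.5, seed=2)
        path = tmp_path / f"rec{suffix}"
        save_record(rec, path)
        loaded = load_record(path)
        assert loaded.values == rec.values
        assert loaded.model_context == rec.model_context
        assert loaded.record_id == rec.record_id
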