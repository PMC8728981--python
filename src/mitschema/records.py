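"""Metadata record validation and completeness scoring.

A :class:`MetadataRecord` holds one experiment's metadata as a mapping from
field id to values, together with the experimental model context (in vitro,
in vivo, or both).  Validation flags unknown keys, values on grouping
fields, value-kind violations and applicability violations; completeness
scoring measures what fraction of the applicable content-bearing fields the
record actually fills — the operational form of "data completeness" that
reuse of experimental datasets depends on.

Presence means at least one non-empty value; the explicit sentinel
``"not applicable"`` (or ``"n/a"``) counts as present, because the
experimenter addressed the field — an omission and a stated inapplicability
are different things in a completeness audit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path

import pandas as pd

from .schema_model import (
    Applicability,
    Category,
    LabeledField,
    Requirement,
    Schema,
    ValueKind,
)


class SchemaVersionError(Exception):
    """Record and schema declare different schema versions."""


class ModelContext(str, Enum):
    in_vitro = "in_vitro"
    in_vivo = "in_vivo"
    both = "both"


NOT_APPLICABLE_SENTINELS = frozenset({"not applicable", "n/a", "na"})


@dataclass
class MetadataRecord:
    record_id: str
    schema_version: str
    model_context: ModelContext = ModelContext.both
    values: dict[str, list[str]] = dc_field(default_factory=dict)


class FindingKind(str, Enum):
    unknown_field = "unknown_field"
    grouping_field_value = "grouping_field_value"
    value_kind = "value_kind"
    applicability = "applicability"
    empty_value = "empty_value"


@dataclass(frozen=True)
class Finding:
    kind: FindingKind
    field_id: str
    message: str


@dataclass(frozen=True)
class ModuleCompleteness:
    module_id: str
    n_applicable: int
    n_present: int

    @property
    def fraction(self) -> float:
        return self.n_present / self.n_applicable if self.n_applicable else 0.0


@dataclass
class CompletenessReport:
    per_module: list[ModuleCompleteness]
    overall_applicable: int
    overall_present: int
    missing_minimum: list[str]
    unknown_fields: list[str]

    @property
    def overall_fraction(self) -> float:
        if self.overall_applicable == 0:
            return 0.0
        return self.overall_present / self.overall_applicable

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "module": m.module_id,
                "applicable": m.n_applicable,
                "present": m.n_present,
                "fraction": m.fraction,
            }
            for m in self.per_module
        ]
        rows.append(
            {
                "module": "overall",
                "applicable": self.overall_applicable,
                "present": self.overall_present,
                "fraction": self.overall_fraction,
            }
        )
        return pd.DataFrame(rows)


# number with optional sign (ascii or unicode minus), optional unit text
_QUANTITY_RE = re.compile(
    r"^[+\-−]?\d+(\.\d+)?([eE][+\-]?\d+)?(\s*\S.*)?$"
)
_BOOLEAN_VALUES = frozenset({"true", "false", "yes", "no", "0", "1"})


def _is_sentinel(value: str) -> bool:
    return value.strip().casefold() in NOT_APPLICABLE_SENTINELS


def _value_kind_ok(kind: ValueKind, value: str) -> bool:
    v = value.strip()
    if _is_sentinel(v):
        return True
    if kind is ValueKind.quantity_with_unit:
        return bool(_QUANTITY_RE.match(v))
    if kind is ValueKind.boolean:
        return v.casefold() in _BOOLEAN_VALUES
    # free_text, controlled_term, identifier: any non-empty string
    return bool(v)


def field_applicable(field: LabeledField, context: ModelContext) -> bool:
    if field.applicability is Applicability.always:
        return True
    if context is ModelContext.both:
        return True
    if field.applicability is Applicability.in_vitro_only:
        return context is ModelContext.in_vitro
    return context is ModelContext.in_vivo


def validate_record(record: MetadataRecord, schema: Schema) -> list[Finding]:
    """Enumerate validity findings; an empty list means the record is clean.

    Emptiness of the record is a completeness matter, not a validity one.
    A schema-version mismatch is an error (raised), not a finding.
    """
    if record.schema_version and record.schema_version != schema.version:
        raise SchemaVersionError(
            f"record declares schema version {record.schema_version!r}, "
            f"schema is {schema.version!r}"
        )
    by_id = schema.fields_by_id
    findings: list[Finding] = []
    for field_id, values in record.values.items():
        field = by_id.get(field_id)
        if field is None:
            findings.append(
                Finding(
                    FindingKind.unknown_field,
                    field_id,
                    f"key {field_id!r} does not resolve to a schema field",
                )
            )
            continue
        if field.category is Category.grouping:
            findings.append(
                Finding(
                    FindingKind.grouping_field_value,
                    field_id,
                    f"{field_id!r} is a grouping field and cannot hold values",
                )
            )
            continue
        if not field_applicable(field, record.model_context):
            findings.append(
                Finding(
                    FindingKind.applicability,
                    field_id,
                    f"{field_id!r} ({field.applicability.value}) is not "
                    f"applicable in a {record.model_context.value} record",
                )
            )
        for value in values:
            if not value.strip():
                findings.append(
                    Finding(
                        FindingKind.empty_value,
                        field_id,
                        f"{field_id!r} carries an empty value",
                    )
                )
            elif not _value_kind_ok(field.value_kind, value):
                findings.append(
                    Finding(
                        FindingKind.value_kind,
                        field_id,
                        f"{field_id!r} expects {field.value_kind.value}, "
                        f"got {value!r}",
                    )
                )
    return findings


_REQ_RANK = {
    Requirement.optional: 0,
    Requirement.recommended: 1,
    Requirement.minimum: 2,
}


def _present(record: MetadataRecord, field_id: str) -> bool:
    values = record.values.get(field_id, [])
    return any(v.strip() for v in values)


def completeness_score(
    record: MetadataRecord,
    schema: Schema,
    requirement_floor: Requirement = Requirement.minimum,
) -> CompletenessReport:
    """Fraction of applicable content-bearing fields the record fills.

    ``requirement_floor`` restricts the denominator to fields at least as
    strongly required as the floor (``minimum`` is the most demanding
    requirement level, ``optional`` the least, so floor=optional counts
    every field and floor=minimum only the mandatory core).  Unknown keys
    never count toward completeness.
    """
    floor_rank = _REQ_RANK[requirement_floor]
    by_id = schema.fields_by_id
    per_module: list[ModuleCompleteness] = []
    missing_minimum: list[str] = []
    total_applicable = total_present = 0
    for module in schema.modules:
        n_app = n_pres = 0
        for field in module.content_fields():
            applicable = field_applicable(field, record.model_context)
            if applicable and field.requirement is Requirement.minimum:
                if not _present(record, field.field_id):
                    missing_minimum.append(field.field_id)
            if not applicable or _REQ_RANK[field.requirement] < floor_rank:
                continue
            n_app += 1
            if _present(record, field.field_id):
                n_pres += 1
        per_module.append(ModuleCompleteness(module.module_id, n_app, n_pres))
        total_applicable += n_app
        total_present += n_pres
    unknown = sorted(k for k in record.values if k not in by_id)
    return CompletenessReport(
        per_module=per_module,
        overall_applicable=total_applicable,
        overall_present=total_present,
        missing_minimum=missing_minimum,
        unknown_fields=unknown,
    )


# ---------------------------------------------------------------------------
# Record I/O
# ---------------------------------------------------------------------------


def record_to_json(record: MetadataRecord) -> str:
    return json.dumps(
        {
            "record_id": record.record_id,
            "schema_version": record.schema_version,
            "model_context": record.model_context.value,
            "values": record.values,
        },
        indent=2,
        ensure_ascii=False,
    ) + "\n"


def record_from_json(text: str) -> MetadataRecord:
    doc = json.loads(text)
    return MetadataRecord(
        record_id=doc.get("record_id", ""),
        schema_version=doc.get("schema_version", ""),
        model_context=ModelContext(doc.get("model_context", "both")),
        values={k: list(v) for k, v in doc.get("values", {}).items()},
    )


def save_record(record: MetadataRecord, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(record_to_json(record), encoding="utf-8")
        return
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    rows = [
        {"field_id": fid, "value": v}
        for fid, values in record.values.items()
        for v in values
    ]
    df = pd.DataFrame(rows, columns=["field_id", "value"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#record_id={record.record_id}\n")
        fh.write(f"#schema_version={record.schema_version}\n")
        fh.write(f"#model_context={record.model_context.value}\n")
        df.to_csv(fh, sep=sep, index=False)


def load_record(path: str | Path) -> MetadataRecord:
    """Load a record from JSON or from flat CSV/TSV (field_id, value rows)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return record_from_json(text)
    meta = {"record_id": "", "schema_version": "", "model_context": "both"}
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key in meta:
                meta[key] = value
        else:
            body.append(line)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    import io as _io

    df = pd.read_csv(
        _io.StringIO("\n".join(body)), sep=sep, dtype=str, keep_default_na=False
    )
    values: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        value = row["value"]
        unit = str(row.get("unit", "")).strip() if "unit" in df.columns else ""
        if unit:
            value = f"{value} {unit}"
        values.setdefault(row["field_id"], []).append(value)
    return MetadataRecord(
        record_id=meta["record_id"],
        schema_version=meta["schema_version"],
        model_context=ModelContext(meta["model_context"]),
        values=values,
    )
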