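"""Core data model for modular minimum-information metadata schemas.

A schema is a versioned container of modules; each module groups *labeled
fields* under named subdivisions.  Fields are either *grouping* fields
(structural headers that organise the table) or *content-bearing* fields
(slots that hold an actual value in a metadata record).  The model follows
the shape of a spreadsheet-based minimum-information table: one row per
labeled field, modules and subdivisions as the grouping hierarchy.

Serialization is supported in three dialects.  The canonical dialect is CSV
(one row per field, schema-level attributes in ``#key=value`` header lines);
JSON and XML are lossless projections of the same content.
"""

from __future__ import annotations

import csv
import io
import json
import re
import unicodedata
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence


class SchemaError(Exception):
    """Base class for schema-related errors."""


class SchemaParseError(SchemaError):
    """A schema file could not be parsed in the requested dialect."""


class SchemaIntegrityError(SchemaError):
    """A structural invariant of the schema is violated (duplicate ids,
    dangling module references, colliding profile fields, ...)."""


class Category(str, Enum):
    grouping = "grouping"
    content_bearing = "content_bearing"


class Applicability(str, Enum):
    always = "always"
    in_vitro_only = "in_vitro_only"
    in_vivo_only = "in_vivo_only"


class Requirement(str, Enum):
    minimum = "minimum"
    recommended = "recommended"
    optional = "optional"


class ValueKind(str, Enum):
    free_text = "free_text"
    quantity_with_unit = "quantity_with_unit"
    controlled_term = "controlled_term"
    identifier = "identifier"
    boolean = "boolean"


_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(name: str) -> str:
    """Lowercase snake-case slug of a field or module name."""
    name = unicodedata.normalize("NFKD", name)
    name = name.encode("ascii", "ignore").decode("ascii")
    return _SLUG_RE.sub("_", name.strip().lower()).strip("_")


@dataclass(frozen=True)
class LabeledField:
    """One named slot of the schema.

    ``field_id`` is a stable slug unique across the schema.  ``synonyms``
    lists alternative labels for the same concept (e.g. *zeta potential* /
    *surface charge*).  ``applicability`` restricts a field to in vitro or
    in vivo experimental contexts; ``provenance`` names the source standard
    or guideline the field was drawn from, or ``reconstructed`` for fields
    filled in from module-level descriptions; ``profile`` names the
    extension profile that contributed the field (empty for the base
    schema).
    """

    field_id: str
    name: str
    category: Category
    module_id: str
    subdivision_path: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()
    applicability: Applicability = Applicability.always
    requirement: Requirement = Requirement.minimum
    value_kind: ValueKind = ValueKind.free_text
    unit_hint: str = ""
    description: str = ""
    provenance: str = ""
    profile: str = ""


@dataclass
class Module:
    module_id: str
    name: str
    subdivisions: tuple[str, ...] = ()
    fields: list[LabeledField] = dc_field(default_factory=list)

    def content_fields(self) -> list[LabeledField]:
        return [f for f in self.fields if f.category is Category.content_bearing]

    def grouping_fields(self) -> list[LabeledField]:
        return [f for f in self.fields if f.category is Category.grouping]


@dataclass
class Schema:
    schema_id: str
    version: str
    modules: list[Module] = dc_field(default_factory=list)
    profile_tags: tuple[str, ...] = ()

    def iter_fields(self) -> Iterator[LabeledField]:
        for module in self.modules:
            yield from module.fields

    @property
    def fields_by_id(self) -> dict[str, LabeledField]:
        return {f.field_id: f for f in self.iter_fields()}

    def module(self, module_id: str) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    def validate(self) -> None:
        """Raise :class:`SchemaIntegrityError` on structural violations."""
        seen: set[str] = set()
        module_ids = [m.module_id for m in self.modules]
        if len(set(module_ids)) != len(module_ids):
            raise SchemaIntegrityError("duplicate module_id in schema")
        for module in self.modules:
            for f in module.fields:
                if f.field_id in seen:
                    raise SchemaIntegrityError(
                        f"duplicate field_id {f.field_id!r}"
                    )
                seen.add(f.field_id)
                if f.module_id != module.module_id:
                    raise SchemaIntegrityError(
                        f"field {f.field_id!r} claims module {f.module_id!r} "
                        f"but is listed under {module.module_id!r}"
                    )
                norm_name = slugify(f.name)
                for syn in f.synonyms:
                    if slugify(syn) == norm_name:
                        raise SchemaIntegrityError(
                            f"field {f.field_id!r}: synonym {syn!r} duplicates "
                            "the primary name after normalization"
                        )


@dataclass
class ExtensionProfile:
    """Additional fields (and requirement overrides) for an advanced model.

    Profiles capture the extra minimum information that complex new-approach
    methodologies need beyond the base schema — e.g. aerosol generation
    parameters for air–liquid-interface exposure.
    """

    profile_id: str
    name: str
    added_fields: list[LabeledField] = dc_field(default_factory=list)
    modified_requirements: list[tuple[str, Requirement]] = dc_field(
        default_factory=list
    )


@dataclass(frozen=True)
class SchemaStats:
    n_modules: int
    n_grouping: int
    n_content_bearing: int
    n_total: int
    per_module_content: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "modules": self.n_modules,
            "grouping_fields": self.n_grouping,
            "content_bearing_fields": self.n_content_bearing,
            "total_fields": self.n_total,
            "per_module_content_bearing": dict(self.per_module_content),
        }


def schema_stats(schema: Schema) -> SchemaStats:
    """Count modules, grouping and content-bearing fields, per module and
    overall."""
    per_module = {
        m.module_id: len(m.content_fields()) for m in schema.modules
    }
    n_grouping = sum(len(m.grouping_fields()) for m in schema.modules)
    n_content = sum(per_module.values())
    return SchemaStats(
        n_modules=len(schema.modules),
        n_grouping=n_grouping,
        n_content_bearing=n_content,
        n_total=n_grouping + n_content,
        per_module_content=per_module,
    )


def merge_profile(schema: Schema, profile: ExtensionProfile) -> Schema:
    """Return a new schema extending ``schema`` with a profile's fields.

    Profile fields are tagged with the profile id and appended to the module
    they declare; requirement overrides are applied in place.  Field-id
    collisions with the base schema (including re-applying the same profile)
    raise :class:`SchemaIntegrityError`.
    """
    existing = set(schema.fields_by_id)
    added_ids = [f.field_id for f in profile.added_fields]
    if len(set(added_ids)) != len(added_ids):
        raise SchemaIntegrityError(
            f"profile {profile.profile_id!r} contains duplicate field ids"
        )
    collisions = existing.intersection(added_ids)
    if collisions:
        raise SchemaIntegrityError(
            f"profile {profile.profile_id!r} collides with existing field "
            f"ids: {sorted(collisions)}"
        )
    overrides = dict(profile.modified_requirements)
    unknown = set(overrides) - existing
    if unknown:
        raise SchemaIntegrityError(
            f"profile {profile.profile_id!r} overrides unknown fields: "
            f"{sorted(unknown)}"
        )

    new_modules: list[Module] = []
    for module in schema.modules:
        fields = [
            replace(f, requirement=overrides[f.field_id])
            if f.field_id in overrides
            else f
            for f in module.fields
        ]
        extra = [
            replace(f, profile=profile.profile_id)
            for f in profile.added_fields
            if f.module_id == module.module_id
        ]
        subdivisions = list(module.subdivisions)
        for f in extra:
            for name in f.subdivision_path:
                if name not in subdivisions:
                    subdivisions.append(name)
        new_modules.append(
            Module(
                module_id=module.module_id,
                name=module.name,
                subdivisions=tuple(subdivisions),
                fields=fields + extra,
            )
        )
    known_modules = {m.module_id for m in schema.modules}
    orphans = [
        f.field_id for f in profile.added_fields if f.module_id not in known_modules
    ]
    if orphans:
        raise SchemaIntegrityError(
            f"profile {profile.profile_id!r} targets unknown modules for "
            f"fields {orphans}"
        )
    merged = Schema(
        schema_id=schema.schema_id,
        version=schema.version,
        modules=new_modules,
        profile_tags=schema.profile_tags + (profile.profile_id,),
    )
    merged.validate()
    return merged


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "FieldId",
    "Module",
    "Subdivision",
    "Category",
    "Name",
    "Synonyms",
    "Applicability",
    "Requirement",
    "ValueKind",
    "Unit",
    "Description",
    "Provenance",
    "Profile",
]

_SUBDIV_SEP = " / "


def _field_row(f: LabeledField) -> list[str]:
    return [
        f.field_id,
        f.module_id,
        _SUBDIV_SEP.join(f.subdivision_path),
        f.category.value,
        f.name,
        "|".join(f.synonyms),
        f.applicability.value,
        f.requirement.value,
        f.value_kind.value,
        f.unit_hint,
        f.description,
        f.provenance,
        f.profile,
    ]


def dumps_csv(schema: Schema) -> str:
    buf = io.StringIO()
    buf.write(f"#schema_id={schema.schema_id}\n")
    buf.write(f"#version={schema.version}\n")
    buf.write(f"#profiles={','.join(schema.profile_tags)}\n")
    for module in schema.modules:
        buf.write(
            f"#module={module.module_id}"
            f"\t{module.name}"
            f"\t{'|'.join(module.subdivisions)}\n"
        )
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_COLUMNS)
    for f in schema.iter_fields():
        writer.writerow(_field_row(f))
    return buf.getvalue()


def _field_from_mapping(d: dict) -> LabeledField:
    try:
        return LabeledField(
            field_id=d["FieldId"],
            name=d["Name"],
            category=Category(d["Category"]),
            module_id=d["Module"],
            subdivision_path=tuple(
                s for s in d.get("Subdivision", "").split(_SUBDIV_SEP) if s
            ),
            synonyms=tuple(s for s in d.get("Synonyms", "").split("|") if s),
            applicability=Applicability(d.get("Applicability", "always")),
            requirement=Requirement(d.get("Requirement", "minimum")),
            value_kind=ValueKind(d.get("ValueKind", "free_text")),
            unit_hint=d.get("Unit", ""),
            description=d.get("Description", ""),
            provenance=d.get("Provenance", ""),
            profile=d.get("Profile", ""),
        )
    except (KeyError, ValueError) as exc:
        raise SchemaParseError(f"bad field row {d!r}: {exc}") from exc


def loads_csv(text: str) -> Schema:
    schema_id = ""
    version = ""
    profiles: tuple[str, ...] = ()
    module_meta: list[tuple[str, str, tuple[str, ...]]] = []
    body_lines: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key == "schema_id":
                schema_id = value
            elif key == "version":
                version = value
            elif key == "profiles":
                profiles = tuple(p for p in value.split(",") if p)
            elif key == "module":
                parts = value.split("\t")
                if len(parts) != 3:
                    raise SchemaParseError(
                        f"line {lineno}: malformed module header {line!r}"
                    )
                mid, mname, subs = parts
                module_meta.append(
                    (mid, mname, tuple(s for s in subs.split("|") if s))
                )
            else:
                raise SchemaParseError(
                    f"line {lineno}: unknown header key {key!r}"
                )
        else:
            body_lines.append(line)
    reader = csv.reader(io.StringIO("\n".join(body_lines)))
    rows = list(reader)
    if not rows or rows[0] != _CSV_COLUMNS:
        raise SchemaParseError(
            f"missing or malformed header row (expected {_CSV_COLUMNS})"
        )
    modules = {
        mid: Module(module_id=mid, name=mname, subdivisions=subs)
        for mid, mname, subs in module_meta
    }
    for row in rows[1:]:
        if not row:
            continue
        d = dict(zip(_CSV_COLUMNS, row))
        f = _field_from_mapping(d)
        if f.module_id not in modules:
            raise SchemaIntegrityError(
                f"field {f.field_id!r} references unknown module "
                f"{f.module_id!r}"
            )
        modules[f.module_id].fields.append(f)
    schema = Schema(
        schema_id=schema_id,
        version=version,
        modules=[modules[mid] for mid, _, _ in module_meta],
        profile_tags=profiles,
    )
    schema.validate()
    return schema


def dumps_json(schema: Schema) -> str:
    doc = {
        "schema_id": schema.schema_id,
        "version": schema.version,
        "profiles": list(schema.profile_tags),
        "modules": [
            {
                "module_id": m.module_id,
                "name": m.name,
                "subdivisions": list(m.subdivisions),
                "fields": [
                    dict(zip(_CSV_COLUMNS, _field_row(f))) for f in m.fields
                ],
            }
            for m in schema.modules
        ],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def loads_json(text: str) -> Schema:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaParseError(f"invalid JSON: {exc}") from exc
    modules = []
    for m in doc.get("modules", []):
        module = Module(
            module_id=m["module_id"],
            name=m["name"],
            subdivisions=tuple(m.get("subdivisions", ())),
        )
        for d in m.get("fields", []):
            f = _field_from_mapping(d)
            if f.module_id != module.module_id:
                raise SchemaIntegrityError(
                    f"field {f.field_id!r} references unknown module "
                    f"{f.module_id!r}"
                )
            module.fields.append(f)
        modules.append(module)
    schema = Schema(
        schema_id=doc.get("schema_id", ""),
        version=doc.get("version", ""),
        modules=modules,
        profile_tags=tuple(doc.get("profiles", ())),
    )
    schema.validate()
    return schema


_XML_ATTRS = {
    "FieldId": "id",
    "Subdivision": "subdivision",
    "Category": "category",
    "Name": "name",
    "Synonyms": "synonyms",
    "Applicability": "applicability",
    "Requirement": "requirement",
    "ValueKind": "value_kind",
    "Unit": "unit",
    "Description": "description",
    "Provenance": "provenance",
    "Profile": "profile",
}


def dumps_xml(schema: Schema) -> str:
    root = ET.Element(
        "schema",
        {
            "id": schema.schema_id,
            "version": schema.version,
            "profiles": ",".join(schema.profile_tags),
        },
    )
    for m in schema.modules:
        mod_el = ET.SubElement(
            root,
            "module",
            {
                "id": m.module_id,
                "name": m.name,
                "subdivisions": "|".join(m.subdivisions),
            },
        )
        for f in m.fields:
            row = dict(zip(_CSV_COLUMNS, _field_row(f)))
            attrs = {
                xml_name: row[col]
                for col, xml_name in _XML_ATTRS.items()
            }
            ET.SubElement(mod_el, "field", attrs)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def loads_xml(text: str) -> Schema:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise SchemaParseError(f"invalid XML: {exc}") from exc
    if root.tag != "schema":
        raise SchemaParseError(f"root element is {root.tag!r}, not 'schema'")
    modules = []
    for mod_el in root.findall("module"):
        module = Module(
            module_id=mod_el.get("id", ""),
            name=mod_el.get("name", ""),
            subdivisions=tuple(
                s for s in mod_el.get("subdivisions", "").split("|") if s
            ),
        )
        for f_el in mod_el.findall("field"):
            d = {
                col: f_el.get(xml_name, "")
                for col, xml_name in _XML_ATTRS.items()
            }
            d["Module"] = module.module_id
            module.fields.append(_field_from_mapping(d))
        modules.append(module)
    schema = Schema(
        schema_id=root.get("id", ""),
        version=root.get("version", ""),
        modules=modules,
        profile_tags=tuple(
            p for p in root.get("profiles", "").split(",") if p
        ),
    )
    schema.validate()
    return schema


_DUMPERS = {"csv": dumps_csv, "json": dumps_json, "xml": dumps_xml}
_LOADERS = {"csv": loads_csv, "json": loads_json, "xml": loads_xml}

DIALECTS = tuple(_DUMPERS)


def dumps_schema(schema: Schema, dialect: str = "csv") -> str:
    try:
        return _DUMPERS[dialect](schema)
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None


def loads_schema(text: str, dialect: str = "csv") -> Schema:
    try:
        loader = _LOADERS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None
    return loader(text)


def save_schema(schema: Schema, path: str | Path, dialect: str = "csv") -> None:
    Path(path).write_text(dumps_schema(schema, dialect), encoding="utf-8")


def load_schema(path: str | Path, dialect: str = "csv") -> Schema:
    """Load a schema file, inferring nothing: the dialect is explicit."""
    text = Path(path).read_text(encoding="utf-8")
    return loads_schema(text, dialect)
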