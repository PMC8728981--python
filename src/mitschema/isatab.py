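"""Export metadata records into an ISA-TAB-like four-file tabular layout.

The target layout follows the Investigation / Study / Assay / Material
organisation of ISA-TAB-Nano.  Schema modules route to tables by the
closest conceptual correspondence:

==============================  ==================
module                          table
==============================  ==================
general_information             investigation
biological_model_information    study
exposure_information            study
material_information            material
endpoint_readout_information    assay
analysis_statistics             assay
==============================  ==================

Exposure information rides in the study table and analysis/statistics in
the assay table because the target format has no dedicated modules for
either (statistics appear there only as an assay-file field).  Field values
are emitted as generic ``Parameter Value[<field name>]`` columns, the
convention the target format uses for ontology-annotated parameters.

This is a convenience exporter, not a validating ISA-TAB implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .records import MetadataRecord, validate_record
from .schema_model import Schema

MODULE_TO_TABLE = {
    "general_information": "investigation",
    "biological_model_information": "study",
    "exposure_information": "study",
    "material_information": "material",
    "endpoint_readout_information": "assay",
    "analysis_statistics": "assay",
}

TABLES = ("investigation", "study", "assay", "material")

_FILE_PREFIX = {
    "investigation": "i",
    "study": "s",
    "assay": "a",
    "material": "m",
}

_VALUE_SEP = "|"


class IsaTabError(Exception):
    pass


@dataclass
class IsaTabBundle:
    investigation: pd.DataFrame
    study: pd.DataFrame
    assay: pd.DataFrame
    material: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _table_for(schema: Schema, module_id: str) -> str:
    try:
        return MODULE_TO_TABLE[module_id]
    except KeyError:
        # schemas with extra modules route them to the assay table, the
        # catch-all for measurement-side information
        return "assay"


def record_to_isatab(record: MetadataRecord, schema: Schema) -> IsaTabBundle:
    """Route one record's values into the four-table bundle.

    Every value lands in exactly one table; an invalid record (unknown keys,
    kind violations, ...) raises :class:`IsaTabError`.
    """
    findings = validate_record(record, schema)
    if findings:
        raise IsaTabError(
            f"record {record.record_id!r} does not validate: "
            + "; ".join(f.message for f in findings[:5])
        )
    by_id = schema.fields_by_id
    columns: dict[str, dict[str, str]] = {t: {} for t in TABLES}
    for module in schema.modules:
        table = _table_for(schema, module.module_id)
        for field in module.content_fields():
            values = record.values.get(field.field_id)
            if not values:
                continue
            col = f"Parameter Value[{field.name}]"
            columns[table][col] = _VALUE_SEP.join(values)

    def frame(table: str) -> pd.DataFrame:
        cols = {"Sample Name": record.record_id, **columns[table]}
        return pd.DataFrame([cols])

    return IsaTabBundle(
        investigation=frame("investigation"),
        study=frame("study"),
        assay=frame("assay"),
        material=frame("material"),
    )


def write_isatab(bundle: IsaTabBundle, outdir: str | Path, stem: str = "record") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for table in TABLES:
        path = outdir / f"{_FILE_PREFIX[table]}_{stem}.txt"
        bundle.table(table).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_isatab(outdir: str | Path, stem: str = "record") -> IsaTabBundle:
    outdir = Path(outdir)
    frames = {}
    for table in TABLES:
        path = outdir / f"{_FILE_PREFIX[table]}_{stem}.txt"
        frames[table] = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return IsaTabBundle(**frames)


def isatab_to_values(bundle: IsaTabBundle, schema: Schema) -> dict[str, list[str]]:
    """Recover the field_id -> values mapping from a bundle (round-trip)."""
    name_to_id = {f.name: f.field_id for f in schema.iter_fields()}
    values: dict[str, list[str]] = {}
    for table in TABLES:
        df = bundle.table(table)
        if df.empty:
            continue
        for col in df.columns:
            if not (col.startswith("Parameter Value[") and col.endswith("]")):
                continue
            name = col[len("Parameter Value[") : -1]
            field_id = name_to_id.get(name)
            if field_id is None:
                raise IsaTabError(f"column {col!r} names no schema field")
            cell = str(df[col].iloc[0])
            if cell:
                values[field_id] = cell.split(_VALUE_SEP)
    return values
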