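"""Compatibility statistics over a crosswalk.

A coverage report answers: how many labeled fields of the source schema
found an equivalent in the target vocabulary?  Counts and integer
percentages are computed per module (over content-bearing fields), per
field category (grouping vs content-bearing), and overall, in two modes:

* ``one_to_one`` counts only exact matches (identical naming);
* ``partial`` counts exact and partial matches together.

Percentages are rounded half-up to integers, the convention that reproduces
spreadsheet-style reporting (e.g. 55/333 = 16.52 -> 17, 11/31 = 35.48 -> 35).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .matching import Crosswalk, CrosswalkError, MatchDecision, no_match
from .schema_model import Category, Schema

MODES = ("one_to_one", "partial")

GROUPING_STRATUM = "grouping"
CONTENT_STRATUM = "content_bearing"
OVERALL_STRATUM = "overall"


class CoverageError(Exception):
    pass


def percent_half_up(matched: int, total: int) -> int:
    """Integer percent with exact half-up rounding (no float artifacts)."""
    if total == 0:
        return 0
    return (200 * matched + total) // (2 * total)


@dataclass(frozen=True)
class CoverageRow:
    stratum: str
    matched: int
    total: int
    percent: int
    empty: bool = False


@dataclass
class CoverageReport:
    mode: str
    rows: list[CoverageRow]
    vocab_id: str = ""

    @property
    def by_stratum(self) -> dict[str, CoverageRow]:
        return {r.stratum: r for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": r.stratum,
                    "matched": r.matched,
                    "total": r.total,
                    "percent": r.percent,
                }
                for r in self.rows
            ]
        )


def _matched(decision: MatchDecision, mode: str) -> bool:
    if mode == "one_to_one":
        return decision.match_type == "exact"
    if mode == "partial":
        return decision.match_type in ("exact", "partial")
    raise CoverageError(f"unknown mode {mode!r}")


def coverage_report(crosswalk: Crosswalk, mode: str) -> CoverageReport:
    """Matched/total counts and integer percentages per stratum.

    Strata: one row per module (content-bearing fields only), one row per
    field category, and an overall row.  Module rows sum to the
    content-bearing row; grouping + content-bearing sum to overall.
    Zero-total strata report 0% and are flagged empty.
    """
    if mode not in MODES:
        raise CoverageError(f"unknown mode {mode!r}")
    crosswalk.validate()
    schema = crosswalk.schema
    by_field = crosswalk.by_field

    rows: list[CoverageRow] = []
    content_matched = content_total = 0
    for module in schema.modules:
        fields = module.content_fields()
        m = sum(1 for f in fields if _matched(by_field[f.field_id], mode))
        t = len(fields)
        content_matched += m
        content_total += t
        rows.append(
            CoverageRow(module.module_id, m, t, percent_half_up(m, t), t == 0)
        )
    grouping_fields = [
        f for f in schema.iter_fields() if f.category is Category.grouping
    ]
    gm = sum(1 for f in grouping_fields if _matched(by_field[f.field_id], mode))
    gt = len(grouping_fields)
    rows.append(
        CoverageRow(GROUPING_STRATUM, gm, gt, percent_half_up(gm, gt), gt == 0)
    )
    rows.append(
        CoverageRow(
            CONTENT_STRATUM,
            content_matched,
            content_total,
            percent_half_up(content_matched, content_total),
            content_total == 0,
        )
    )
    om, ot = gm + content_matched, gt + content_total
    rows.append(
        CoverageRow(OVERALL_STRATUM, om, ot, percent_half_up(om, ot), ot == 0)
    )
    return CoverageReport(mode=mode, rows=rows, vocab_id=crosswalk.vocab_id)


def crosswalk_fixture_from_counts(
    schema: Schema,
    counts: Mapping[str, tuple[int, int]],
) -> Crosswalk:
    """Deterministic crosswalk realizing requested per-stratum match counts.

    ``counts`` maps a stratum — a module id (content-bearing fields) or
    ``"grouping"`` — to ``(n_exact, n_partial)``.  Fields are filled in
    schema order: the first ``n_exact`` fields of the stratum get exact
    decisions, the next ``n_partial`` partial ones, the rest none.  Useful
    for reproducing published aggregate counts without the underlying
    field-by-field decisions.
    """
    module_ids = {m.module_id for m in schema.modules}
    for stratum in counts:
        if stratum != GROUPING_STRATUM and stratum not in module_ids:
            raise CoverageError(f"unknown stratum {stratum!r}")

    plan: dict[str, str] = {}
    term_counter = 0

    def assign(field_ids: Sequence[str], n_exact: int, n_partial: int) -> None:
        nonlocal term_counter
        if n_exact < 0 or n_partial < 0 or n_exact + n_partial > len(field_ids):
            raise CoverageError(
                f"requested counts ({n_exact} exact + {n_partial} partial) "
                f"exceed stratum size {len(field_ids)}"
            )
        for i, fid in enumerate(field_ids):
            if i < n_exact:
                plan[fid] = "exact"
            elif i < n_exact + n_partial:
                plan[fid] = "partial"

    for module in schema.modules:
        n_exact, n_partial = counts.get(module.module_id, (0, 0))
        assign([f.field_id for f in module.content_fields()], n_exact, n_partial)
    grouping_ids = [
        f.field_id
        for f in schema.iter_fields()
        if f.category is Category.grouping
    ]
    g_exact, g_partial = counts.get(GROUPING_STRATUM, (0, 0))
    assign(grouping_ids, g_exact, g_partial)

    decisions = []
    for field in schema.iter_fields():
        kind = plan.get(field.field_id)
        if kind is None:
            decisions.append(no_match(field.field_id))
        else:
            term_counter += 1
            decisions.append(
                MatchDecision(
                    field.field_id,
                    f"CT{term_counter:04d}",
                    kind,
                    "curated",
                    1.0 if kind == "exact" else 0.5,
                )
            )
    xw = Crosswalk(schema=schema, vocab_id="count-fixture", decisions=decisions)
    xw.validate()
    return xw


def compare_reports(a: CoverageReport, b: CoverageReport) -> pd.DataFrame:
    """Per-stratum percent difference b - a (e.g. partial gain over one-to-one)."""
    strata_a = [r.stratum for r in a.rows]
    strata_b = [r.stratum for r in b.rows]
    if strata_a != strata_b:
        raise CoverageError(
            f"reports are not comparable: strata {strata_a} vs {strata_b}"
        )
    rows = [
        {
            "stratum": ra.stratum,
            "percent_a": ra.percent,
            "percent_b": rb.percent,
            "delta": rb.percent - ra.percent,
        }
        for ra, rb in zip(a.rows, b.rows)
    ]
    return pd.DataFrame(rows)


def report_to_json(report: CoverageReport) -> dict:
    return {
        "mode": report.mode,
        "vocabulary": report.vocab_id,
        "rows": [
            {
                "stratum": r.stratum,
                "matched": r.matched,
                "total": r.total,
                "percent": r.percent,
                "empty": r.empty,
            }
            for r in report.rows
        ],
    }
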