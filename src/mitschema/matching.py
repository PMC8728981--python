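"""Crosswalk construction from schema fields to external vocabularies.

External standards and ontologies are ingested as flat term tables
(term id, label, synonyms, optional parent).  Matching follows the
source-to-target principle: every labeled field of the source schema
receives exactly one decision against the target vocabulary —

* *exact*: identical naming after normalization (case folding, punctuation
  stripping, whitespace collapse), taking synonyms on both sides into
  account;
* *partial*: a deviating or more general name, operationalised as one
  normalized token set being a non-empty subset of the other (e.g.
  "protocol" vs "dispersion protocol"), scored by Jaccard similarity;
* *none*: no candidate above the score threshold.

Curated decisions — the bookkeeping form of expert judgments — override
automatic ones.  All tie-breaks are lexicographic on term id, so identical
inputs always produce identical crosswalks.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .schema_model import LabeledField, Schema


class VocabularyError(Exception):
    """A term table violates its invariants."""


class CrosswalkError(Exception):
    """A crosswalk or curated decision file is inconsistent."""


_PUNCT_RE = re.compile(r"[^0-9a-z]+")

DEFAULT_MIN_SCORE = 0.25


def normalize_label(label: str) -> tuple[str, ...]:
    """Case-fold, strip punctuation, collapse whitespace, tokenize.

    Deterministic and idempotent: re-normalizing the space-joined result
    yields the same token sequence.
    """
    text = unicodedata.normalize("NFKD", label).casefold()
    text = text.replace("−", "-")  # unicode minus
    return tuple(t for t in _PUNCT_RE.split(text) if t)


@dataclass(frozen=True)
class TargetTerm:
    term_id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parent_id: str = ""

    def variants(self) -> tuple[str, ...]:
        return (self.label,) + self.synonyms


@dataclass
class TargetVocabulary:
    vocab_id: str
    name: str
    terms: list[TargetTerm] = dc_field(default_factory=list)

    def validate(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise VocabularyError(f"duplicate term ids: {dupes}")
        by_id = {t.term_id: t for t in self.terms}
        for t in self.terms:
            if t.parent_id and t.parent_id not in by_id:
                raise VocabularyError(
                    f"term {t.term_id!r} has dangling parent {t.parent_id!r}"
                )
        # parent links must be acyclic
        for t in self.terms:
            seen = {t.term_id}
            cur = t
            while cur.parent_id:
                if cur.parent_id in seen:
                    raise VocabularyError(
                        f"cycle in parent links at {cur.parent_id!r}"
                    )
                seen.add(cur.parent_id)
                cur = by_id[cur.parent_id]


@dataclass(frozen=True)
class MatchDecision:
    field_id: str
    term_id: str
    match_type: str  # "exact" | "partial" | "none"
    method: str = "auto"  # "auto" | "curated"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.match_type not in ("exact", "partial", "none"):
            raise CrosswalkError(f"bad match_type {self.match_type!r}")
        if self.method not in ("auto", "curated"):
            raise CrosswalkError(f"bad method {self.method!r}")
        if self.match_type == "none" and (self.term_id or self.score):
            raise CrosswalkError("match_type=none requires empty term and score 0")
        if self.match_type == "exact" and self.score != 1.0:
            raise CrosswalkError("match_type=exact requires score 1")


NO_MATCH_SCORE = 0.0


def no_match(field_id: str, method: str = "auto") -> MatchDecision:
    return MatchDecision(field_id, "", "none", method, NO_MATCH_SCORE)


@dataclass
class Crosswalk:
    """A total mapping: exactly one decision per labeled field of the schema."""

    schema: Schema
    vocab_id: str
    decisions: list[MatchDecision]

    @property
    def by_field(self) -> dict[str, MatchDecision]:
        return {d.field_id: d for d in self.decisions}

    def validate(self) -> None:
        schema_ids = [f.field_id for f in self.schema.iter_fields()]
        decision_ids = [d.field_id for d in self.decisions]
        if decision_ids != schema_ids:
            raise CrosswalkError(
                "crosswalk is not a total function over schema fields "
                f"({len(decision_ids)} decisions vs {len(schema_ids)} fields)"
            )


def _field_variants(field: LabeledField) -> tuple[str, ...]:
    return (field.name,) + field.synonyms


def match_exact(field: LabeledField, vocab: TargetVocabulary) -> MatchDecision:
    """One-to-one matching: identical naming after normalization.

    The field's name and synonyms are compared against each term's label and
    synonyms; any normalized-sequence equality is an exact match.  Ties are
    broken by lowest term id.
    """
    field_norms = {normalize_label(v) for v in _field_variants(field)}
    field_norms.discard(())
    hits = [
        t.term_id
        for t in vocab.terms
        if any(normalize_label(v) in field_norms for v in t.variants())
    ]
    if not hits:
        return no_match(field.field_id)
    return MatchDecision(field.field_id, min(hits), "exact", "auto", 1.0)


def _token_sets(variants: Iterable[str]) -> list[frozenset[str]]:
    out = []
    for v in variants:
        s = frozenset(normalize_label(v))
        if s:
            out.append(s)
    return out


def match_partial(
    field: LabeledField,
    vocab: TargetVocabulary,
    min_score: float = DEFAULT_MIN_SCORE,
) -> MatchDecision:
    """Partial matching: deviating or more general names.

    A term is a candidate when one normalized token set (field vs term,
    synonyms included) is a non-empty subset of the other; candidates are
    scored by Jaccard similarity of the token sets.  Pairs with identical
    normalized sequences belong to :func:`match_exact` and are skipped here.
    The best score wins, ties broken by lowest term id; below ``min_score``
    the decision is *none*.
    """
    if not 0 < min_score <= 1:
        raise ValueError("min_score must be in (0, 1]")
    field_seqs = {normalize_label(v) for v in _field_variants(field)}
    field_seqs.discard(())
    field_sets = _token_sets(_field_variants(field))
    best: tuple[float, str] | None = None
    for term in vocab.terms:
        term_variants = [
            v for v in term.variants() if normalize_label(v) not in field_seqs
        ]
        score = 0.0
        for fs in field_sets:
            for ts in _token_sets(term_variants):
                if fs <= ts or ts <= fs:
                    jac = len(fs & ts) / len(fs | ts)
                    score = max(score, jac)
        if score > 0:
            key = (score, term.term_id)
            if best is None or score > best[0] or (
                score == best[0] and term.term_id < best[1]
            ):
                best = key
    if best is None or best[0] < min_score:
        return no_match(field.field_id)
    return MatchDecision(field.field_id, best[1], "partial", "auto", best[0])


def auto_crosswalk(
    schema: Schema,
    vocab: TargetVocabulary,
    curated: Sequence[MatchDecision] = (),
    min_score: float = DEFAULT_MIN_SCORE,
) -> Crosswalk:
    """Build a total crosswalk with precedence curated > exact > partial > none."""
    known = set(schema.fields_by_id)
    curated_by_field: dict[str, MatchDecision] = {}
    for d in curated:
        if d.field_id not in known:
            raise CrosswalkError(
                f"curated decision references unknown field {d.field_id!r}"
            )
        curated_by_field[d.field_id] = MatchDecision(
            d.field_id, d.term_id, d.match_type, "curated", d.score
        )
    decisions: list[MatchDecision] = []
    for field in schema.iter_fields():
        if field.field_id in curated_by_field:
            decisions.append(curated_by_field[field.field_id])
            continue
        decision = match_exact(field, vocab)
        if decision.match_type == "none":
            decision = match_partial(field, vocab, min_score)
        decisions.append(decision)
    xw = Crosswalk(schema=schema, vocab_id=vocab.vocab_id, decisions=decisions)
    xw.validate()
    return xw


# ---------------------------------------------------------------------------
# Flat-file I/O
# ---------------------------------------------------------------------------

VOCAB_COLUMNS = ["term_id", "label", "synonyms", "parent_id"]
CROSSWALK_COLUMNS = ["field_id", "term_id", "match_type", "method", "score", "note"]


def vocabulary_to_frame(vocab: TargetVocabulary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": t.term_id,
                "label": t.label,
                "synonyms": "|".join(t.synonyms),
                "parent_id": t.parent_id,
            }
            for t in vocab.terms
        ],
        columns=VOCAB_COLUMNS,
    )


def save_vocabulary(vocab: TargetVocabulary, path: str | Path) -> None:
    vocabulary_to_frame(vocab).to_csv(path, sep="\t", index=False)


def load_vocabulary(
    path: str | Path, vocab_id: str = "", name: str = ""
) -> TargetVocabulary:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(VOCAB_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise VocabularyError(f"vocabulary table misses columns {sorted(missing)}")
    terms = [
        TargetTerm(
            term_id=row["term_id"],
            label=row["label"],
            synonyms=tuple(
                s for s in str(row.get("synonyms", "")).split("|") if s
            ),
            parent_id=str(row.get("parent_id", "")),
        )
        for _, row in df.iterrows()
    ]
    vocab = TargetVocabulary(
        vocab_id=vocab_id or Path(path).stem, name=name or vocab_id, terms=terms
    )
    vocab.validate()
    return vocab


def crosswalk_to_frame(xw: Crosswalk) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "field_id": d.field_id,
                "term_id": d.term_id,
                "match_type": d.match_type,
                "method": d.method,
                "score": d.score,
                "note": "",
            }
            for d in xw.decisions
        ],
        columns=CROSSWALK_COLUMNS,
    )


def save_crosswalk(xw: Crosswalk, path: str | Path) -> None:
    crosswalk_to_frame(xw).to_csv(path, sep="\t", index=False)


def load_decisions(path: str | Path) -> list[MatchDecision]:
    """Read match decisions (e.g. a curated crosswalk layer) from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "field_id" not in df.columns or "match_type" not in df.columns:
        raise CrosswalkError("decision table needs field_id and match_type")
    out = []
    for _, row in df.iterrows():
        mt = row["match_type"]
        score = row.get("score", "")
        if score in ("", None):
            score = 1.0 if mt == "exact" else (0.5 if mt == "partial" else 0.0)
        out.append(
            MatchDecision(
                field_id=row["field_id"],
                term_id=str(row.get("term_id", "")) if mt != "none" else "",
                match_type=mt,
                method=str(row.get("method", "curated") or "curated"),
                score=float(score) if mt != "none" else 0.0,
            )
        )
    return out


def load_crosswalk(path: str | Path, schema: Schema, vocab_id: str = "") -> Crosswalk:
    decisions = load_decisions(path)
    xw = Crosswalk(schema=schema, vocab_id=vocab_id, decisions=decisions)
    xw.validate()
    return xw
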