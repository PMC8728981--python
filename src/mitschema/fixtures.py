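"""Synthetic-data generators and the bundled reference schema builder.

Two generators carry planted ground truth:

* :func:`generate_vocabulary` builds a flat term table in which each schema
  field is planted as an exact copy, a token-perturbed partial, or an
  unrelated random label — and returns the planted decisions alongside, so
  matcher recovery can be asserted exactly rather than probabilistically.
* :func:`generate_record` fills each applicable content-bearing field
  independently with a given probability, for completeness-score tests.

Both are deterministic under an explicit integer seed.

The planting is constructed inside the matcher's guarantees: "none" labels
are drawn from a token alphabet disjoint from every field name, so they can
never fire the subset rule; partial perturbations are only planted where
they cannot collide with another field's name; and fields whose names nest
inside one another (e.g. "protocol" / "dispersion protocol") are assigned
as a block, never split between matchable and unmatchable plants.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from . import _reference_data as _ref
from .matching import (
    MatchDecision,
    TargetTerm,
    TargetVocabulary,
    no_match,
    normalize_label,
)
from .records import MetadataRecord, ModelContext, field_applicable
from .schema_model import (
    Applicability,
    Category,
    LabeledField,
    Module,
    Requirement,
    Schema,
    ValueKind,
    slugify,
)


class FixtureError(Exception):
    pass


# ---------------------------------------------------------------------------
# Reference schema
# ---------------------------------------------------------------------------


def _make_field(module_id: str, subdivision: str, entry: tuple) -> LabeledField:
    name = entry[0]
    kind = _ref._KIND[entry[1]] if len(entry) > 1 else "free_text"
    unit = entry[2] if len(entry) > 2 else ""
    appl = _ref._APPL[entry[3]] if len(entry) > 3 else "always"
    synonyms = tuple(entry[4]) if len(entry) > 4 else ()
    provenance = entry[5] if len(entry) > 5 else _ref.RECONSTRUCTED_TAG
    return LabeledField(
        field_id=slugify(name),
        name=name,
        category=Category.content_bearing,
        module_id=module_id,
        subdivision_path=(subdivision,),
        synonyms=synonyms,
        applicability=Applicability(appl),
        requirement=Requirement.minimum,
        value_kind=ValueKind(kind),
        unit_hint=unit,
        provenance=provenance,
    )


def build_reference_mit() -> Schema:
    """Construct the bundled six-module reference schema.

    33 grouping fields (one per module subdivision) and 300 content-bearing
    fields (22/32/69/48/98/31 per module).
    """
    modules = []
    for module_id, module_name in _ref.MODULES:
        subdivisions = [sub for sub, _ in _ref.FIELDS[module_id]]
        module = Module(
            module_id=module_id,
            name=module_name,
            subdivisions=tuple(subdivisions),
        )
        for subdivision, entries in _ref.FIELDS[module_id]:
            module.fields.append(
                LabeledField(
                    field_id=f"{module_id}__{slugify(subdivision)}",
                    name=subdivision,
                    category=Category.grouping,
                    module_id=module_id,
                    subdivision_path=(),
                    provenance=_ref.RECONSTRUCTED_TAG,
                )
            )
            for entry in entries:
                module.fields.append(_make_field(module_id, subdivision, entry))
        modules.append(module)
    schema = Schema(
        schema_id=_ref.SCHEMA_ID,
        version=_ref.SCHEMA_VERSION,
        modules=modules,
    )
    schema.validate()
    return schema


# ---------------------------------------------------------------------------
# Vocabulary generator with planted ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantSpec:
    """Mix of planted match outcomes for a generated vocabulary."""

    p_exact: float
    p_partial: float
    p_none: float
    seed: int = 0
    perturbation: str = "drop_qualifier_token"  # or "add_qualifier_token"

    def __post_init__(self) -> None:
        probs = (self.p_exact, self.p_partial, self.p_none)
        if any(p < 0 or p > 1 for p in probs):
            raise FixtureError("plant probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise FixtureError("plant probabilities must sum to 1")
        if self.perturbation not in (
            "drop_qualifier_token",
            "add_qualifier_token",
        ):
            raise FixtureError(f"unknown perturbation {self.perturbation!r}")


# token alphabet disjoint from realistic field names: "none" labels can
# never share tokens with any schema field
_NOISE_SYLLABLES = ("zyx", "qwv", "xjq", "vzk", "wqz", "jxv", "kqy", "zvw")


def _noise_token(rng: random.Random) -> str:
    return rng.choice(_NOISE_SYLLABLES) + rng.choice(_NOISE_SYLLABLES)


def _variant_sets(field: LabeledField) -> list[frozenset[str]]:
    out = []
    for v in (field.name,) + field.synonyms:
        s = frozenset(normalize_label(v))
        if s:
            out.append(s)
    return out


def _nested(a: list[frozenset[str]], b: list[frozenset[str]]) -> bool:
    return any(x <= y or y <= x for x in a for y in b)


def _allocate_counts(n: int, plant: PlantSpec) -> tuple[int, int, int]:
    n_exact = round(plant.p_exact * n)
    n_partial = round(plant.p_partial * n)
    if n_exact + n_partial > n:
        n_partial = n - n_exact
    return n_exact, n_partial, n - n_exact - n_partial


def generate_vocabulary(
    schema: Schema, plant: PlantSpec
) -> tuple[TargetVocabulary, list[MatchDecision]]:
    """Generate a term table plus the planted truth for every schema field.

    Plant counts are allocated deterministically (``round(p * n)``), so the
    recovered match-type frequencies equal the plant exactly; which field
    receives which plant is shuffled under the seed.
    """
    rng = random.Random(plant.seed)
    fields = list(schema.iter_fields())
    n = len(fields)
    variant_sets = {f.field_id: _variant_sets(f) for f in fields}
    norm_names = [normalize_label(f.name) for f in fields]
    if len(set(norm_names)) != len(norm_names):
        raise FixtureError("schema field names are not unique after normalization")

    # group fields whose names/synonyms nest into components (union-find)
    parent = {f.field_id: f.field_id for f in fields}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(fields):
        for b in fields[i + 1 :]:
            if _nested(variant_sets[a.field_id], variant_sets[b.field_id]):
                parent[find(a.field_id)] = find(b.field_id)
    components: dict[str, list[str]] = {}
    for f in fields:
        components.setdefault(find(f.field_id), []).append(f.field_id)
    comp_list = sorted(components.values(), key=lambda c: c[0])
    rng.shuffle(comp_list)

    n_exact, n_partial, n_none = _allocate_counts(n, plant)

    # whole components become "none" (safe: none labels share no tokens with
    # anything); greedily pick components until the count is met
    none_fields: set[str] = set()
    remaining = n_none
    rest: list[list[str]] = []
    for comp in comp_list:
        if len(comp) <= remaining:
            none_fields.update(comp)
            remaining -= len(comp)
        else:
            rest.append(comp)
    if remaining:
        raise FixtureError(
            f"cannot allocate {n_none} 'none' plants over nesting components"
        )

    all_variant_sets = [s for f in fields for s in variant_sets[f.field_id]]
    all_norm_seqs = {
        normalize_label(v)
        for f in fields
        for v in (f.name,) + f.synonyms
    }

    def safe_partial_label(field: LabeledField) -> str | None:
        """A perturbed label that partial-matches its field and nothing else."""
        tokens = list(normalize_label(field.name))
        own = variant_sets[field.field_id]
        candidates: list[tuple[str, ...]] = []
        if plant.perturbation == "drop_qualifier_token" and len(tokens) >= 2:
            idx = list(range(len(tokens)))
            rng.shuffle(idx)
            for i in idx:
                candidates.append(tuple(tokens[:i] + tokens[i + 1 :]))
        # fallback (and the add_qualifier_token mode): append a noise token
        candidates.append(tuple(tokens) + (_noise_token(rng),))
        for cand in candidates:
            cand_set = frozenset(cand)
            if not cand_set or cand in all_norm_seqs:
                continue
            clash = any(
                (cand_set <= other or other <= cand_set)
                for other in all_variant_sets
                if other not in own
            )
            if not clash:
                return " ".join(cand)
        return None

    # partial plants go to singleton components only, where a safe
    # perturbation exists; exact plants take the rest
    singleton_pool = [c[0] for c in rest if len(c) == 1]
    multi_pool = [fid for c in rest if len(c) > 1 for fid in c]
    partial_labels: dict[str, str] = {}
    for fid in singleton_pool:
        if len(partial_labels) == n_partial:
            break
        field = schema.fields_by_id[fid]
        label = safe_partial_label(field)
        if label is not None:
            partial_labels[fid] = label
    if len(partial_labels) < n_partial:
        raise FixtureError(
            f"could only place {len(partial_labels)} of {n_partial} partial "
            "plants safely; too many nested field names"
        )
    exact_fields = {
        fid
        for fid in singleton_pool + multi_pool
        if fid not in partial_labels and fid not in none_fields
    }

    used_labels: set[tuple[str, ...]] = set()
    terms: list[TargetTerm] = []
    truth: list[MatchDecision] = []
    for i, field in enumerate(fields):
        term_id = f"T{i:04d}"
        if field.field_id in none_fields:
            while True:
                label = f"{_noise_token(rng)} {_noise_token(rng)}"
                if normalize_label(label) not in used_labels:
                    break
            used_labels.add(normalize_label(label))
            terms.append(TargetTerm(term_id=term_id, label=label))
            truth.append(no_match(field.field_id))
        elif field.field_id in partial_labels:
            label = partial_labels[field.field_id]
            used_labels.add(normalize_label(label))
            fset = frozenset(normalize_label(field.name))
            tset = frozenset(normalize_label(label))
            score = len(fset & tset) / len(fset | tset)
            terms.append(TargetTerm(term_id=term_id, label=label))
            truth.append(
                MatchDecision(field.field_id, term_id, "partial", "auto", score)
            )
        else:
            label = field.name
            used_labels.add(normalize_label(label))
            terms.append(TargetTerm(term_id=term_id, label=label))
            truth.append(
                MatchDecision(field.field_id, term_id, "exact", "auto", 1.0)
            )
    vocab = TargetVocabulary(
        vocab_id=f"planted-seed{plant.seed}",
        name="synthetic planted vocabulary",
        terms=terms,
    )
    vocab.validate()
    return vocab, truth


# ---------------------------------------------------------------------------
# Record generator
# ---------------------------------------------------------------------------

_SAMPLE_VALUES = {
    ValueKind.free_text: "synthetic text value",
    ValueKind.controlled_term: "synthetic-term",
    ValueKind.identifier: "ID-0001",
    ValueKind.boolean: "true",
}


def generate_record(
    schema: Schema,
    p_present: float,
    seed: int,
    model_context: ModelContext = ModelContext.both,
) -> MetadataRecord:
    """Record filling each applicable content-bearing field with prob. ``p_present``."""
    if not 0 <= p_present <= 1:
        raise FixtureError("p_present must lie in [0, 1]")
    rng = random.Random(seed)
    values: dict[str, list[str]] = {}
    for field in schema.iter_fields():
        if field.category is not Category.content_bearing:
            continue
        if not field_applicable(field, model_context):
            continue
        if rng.random() < p_present:
            if field.value_kind is ValueKind.quantity_with_unit:
                magnitude = round(rng.uniform(0.1, 100.0), 2)
                unit = field.unit_hint or "au"
                values[field.field_id] = [f"{magnitude} {unit}"]
            else:
                values[field.field_id] = [_SAMPLE_VALUES[field.value_kind]]
    return MetadataRecord(
        record_id=f"synthetic-{seed}",
        schema_version=schema.version,
        model_context=model_context,
        values=values,
    )
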