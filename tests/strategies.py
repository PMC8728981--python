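"""Hypothesis strategies for small valid schemas."""

from hypothesis import strategies as st

from mitschema import Applicability, Category, LabeledField, Module, Requirement, Schema, ValueKind

_WORDS = ["alpha", "beta", "gamma", "delta", "dose", "size", "rate", "name", "type", "unit"]

_names = st.lists(
    st.sampled_from(_WORDS), min_size=1, max_size=3
).map(" ".join)


@st.composite
def schemas(draw, max_modules=3, max_fields=6):
    n_modules = draw(st.integers(0, max_modules))
    modules = []
    used_ids = set()
    for mi in range(n_modules):
        module_id = f"mod{mi}"
        fields = []
        n_fields = draw(st.integers(0, max_fields))
        for fi in range(n_fields):
            field_id = f"m{mi}f{fi}"
            assert field_id not in used_ids
            used_ids.add(field_id)
            fields.append(
                LabeledField(
                    field_id=field_id,
                    name=draw(_names) + f" {mi}{fi}",
                    category=draw(st.sampled_from(list(Category))),
                    module_id=module_id,
                    subdivision_path=tuple(draw(st.lists(st.sampled_from(_WORDS), max_size=2))),
                    applicability=draw(st.sampled_from(list(Applicability))),
                    requirement=draw(st.sampled_from(list(Requirement))),
                    value_kind=draw(st.sampled_from(list(ValueKind))),
                    unit_hint=draw(st.sampled_from(["", "nm", "mV"])),
                    description=draw(st.sampled_from(["", "a field"])),
                    provenance=draw(st.sampled_from(["", "reconstructed"])),
                )
            )
        modules.append(
            Module(
                module_id=module_id,
                name=f"Module {mi}",
                subdivisions=tuple(draw(st.lists(st.sampled_from(_WORDS), max_size=2, unique=True))),
                fields=fields,
            )
        )
    return Schema(schema_id="gen", version="0", modules=modules)
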