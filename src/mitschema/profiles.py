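"""Extension profiles for new approach methodologies (NAMs).

Advanced non-animal test systems need minimum information beyond the base
schema.  Three profiles are bundled, one per major exposure route:

* ``ali`` — air–liquid interface models of the respiratory tract: aerosol
  generation and delivery parameters, apical culture conditions, epithelial
  barrier readouts.
* ``intestine_advanced`` — advanced intestinal models: food-matrix and
  digestion simulation, mucus and specialised cell types, peristalsis and
  shear stress.
* ``skin_3d`` — reconstructed 3D skin models: commercial model identity,
  UV damage state, irritation/sensitization/corrosion readouts, dermal
  penetration depth.

Profile fields slot into the existing six modules under a profile-named
subdivision and are tagged with the profile id on merge.
"""

from __future__ import annotations

from .schema_model import (
    Applicability,
    Category,
    ExtensionProfile,
    LabeledField,
    ValueKind,
    slugify,
)

_BIO = "biological_model_information"
_EXP = "exposure_information"
_END = "endpoint_readout_information"

# (module_id, subdivision, name, value_kind, unit)
_PROFILE_FIELDS: dict[str, tuple[str, list[tuple[str, str, str, str, str]]]] = {
    "ali": (
        "Air–Liquid Interface",
        [
            (_EXP, "ALI Exposure", "aerosol generation method", "t", ""),
            (_EXP, "ALI Exposure", "aerosol dilution factor", "q", ""),
            (_EXP, "ALI Exposure", "aerosol volume", "q", "mL"),
            (_EXP, "ALI Exposure", "aerosol flow rate", "q", "L/min"),
            (_EXP, "ALI Exposure", "flow alignment", "t", ""),
            (_EXP, "ALI Exposure", "particle deposition efficiency", "q", "%"),
            (_EXP, "ALI Exposure", "exposure chamber conditions", "t", ""),
            (_BIO, "ALI Culture", "apical surface condition", "t", ""),
            (_BIO, "ALI Culture", "surfactant production", "b", ""),
            (_BIO, "ALI Culture", "mucus secretion status", "t", ""),
            (_BIO, "ALI Culture", "tight junction integrity", "t", ""),
            (_BIO, "ALI Culture", "submerged vs ali cultivation", "c", ""),
            (_BIO, "ALI Culture", "co-culture ratio", "t", ""),
            (_END, "ALI Readout", "epithelial barrier function", "q", "ohm*cm2"),
        ],
    ),
    "intestine_advanced": (
        "Advanced Intestinal Model",
        [
            (_EXP, "Intestinal Exposure", "food matrix model", "t", ""),
            (_EXP, "Intestinal Exposure", "digestion simulation protocol", "t", ""),
            (_EXP, "Intestinal Exposure", "digestive fluid composition", "t", ""),
            (_EXP, "Intestinal Exposure", "oil in water emulsion", "t", ""),
            (_BIO, "Intestinal Culture", "mucus production verification", "t", ""),
            (_BIO, "Intestinal Culture", "m cell presence", "b", ""),
            (_BIO, "Intestinal Culture", "goblet cell presence", "b", ""),
            (_BIO, "Intestinal Culture", "peristalsis simulation", "t", ""),
            (_BIO, "Intestinal Culture", "shear stress level", "q", "dyn/cm2"),
            (_BIO, "Intestinal Culture", "intestinal inflammation state", "c", ""),
            (_BIO, "Intestinal Culture", "organoid source", "t", ""),
            (_END, "Intestinal Readout", "cytokine release panel", "t", ""),
        ],
    ),
    "skin_3d": (
        "3D Skin Model",
        [
            (_BIO, "Skin Model", "skin model product", "t", ""),
            (_BIO, "Skin Model", "skin model supplier", "t", ""),
            (_BIO, "Skin Model", "epidermis thickness", "q", "um"),
            (_BIO, "Skin Model", "uv damage state", "c", ""),
            (_EXP, "Dermal Exposure", "uv radiation dose", "q", "J/cm2"),
            (_EXP, "Dermal Exposure", "dispersing agent type", "t", ""),
            (_END, "Skin Readout", "skin irritation score", "q", ""),
            (_END, "Skin Readout", "skin sensitization result", "c", ""),
            (_END, "Skin Readout", "skin corrosion result", "c", ""),
            (_END, "Skin Readout", "dermal penetration depth", "q", "um"),
            (_END, "Skin Readout", "phototoxicity assessment", "t", ""),
        ],
    ),
}

_KIND = {
    "t": ValueKind.free_text,
    "q": ValueKind.quantity_with_unit,
    "c": ValueKind.controlled_term,
    "b": ValueKind.boolean,
}

PROFILE_IDS = tuple(_PROFILE_FIELDS)


def get_profile(profile_id: str) -> ExtensionProfile:
    try:
        display_name, rows = _PROFILE_FIELDS[profile_id]
    except KeyError:
        raise KeyError(
            f"unknown profile {profile_id!r}; available: {PROFILE_IDS}"
        ) from None
    fields = [
        LabeledField(
            field_id=f"{profile_id}__{slugify(name)}",
            name=name,
            category=Category.content_bearing,
            module_id=module_id,
            subdivision_path=(subdivision,),
            applicability=Applicability.in_vitro_only,
            value_kind=_KIND[kind],
            unit_hint=unit,
            provenance="nam-extension",
        )
        for module_id, subdivision, name, kind, unit in rows
    ]
    return ExtensionProfile(
        profile_id=profile_id, name=display_name, added_fields=fields
    )
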