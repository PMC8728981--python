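"""Field inventory of the bundled reference minimum-information table.

The reference schema has six modules with 33 grouping fields (module
subdivision headers) and 300 content-bearing fields, distributed over the
modules as 22 / 32 / 69 / 48 / 98 / 31.  Fields that are explicitly named
in the published description of the table (experiment name, zeta potential
with synonym surface charge, compound name, major use, dispersion protocol,
passage number, seeding density, plate format, delivered dose, statistic,
the three endpoint instruments, ...) are used verbatim and carry a
provenance tag naming the standard or guideline family they trace to; the
remaining fields are reconstructed from the module and subdivision
descriptions and are tagged ``provenance="reconstructed"``.

Entry format: ``(name, kind, unit, applicability, synonyms, provenance)``
with trailing elements optional.  Kind codes: t=free_text,
q=quantity_with_unit, c=controlled_term, i=identifier, b=boolean.
"""

from __future__ import annotations

_KIND = {
    "t": "free_text",
    "q": "quantity_with_unit",
    "c": "controlled_term",
    "i": "identifier",
    "b": "boolean",
}

_APPL = {"a": "always", "vitro": "in_vitro_only", "vivo": "in_vivo_only"}

SCHEMA_ID = "mit-reference"
SCHEMA_VERSION = "1.0"

MODULES = [
    ("general_information", "General Information"),
    ("material_information", "Material Information"),
    ("biological_model_information", "Biological Model Information"),
    ("exposure_information", "Exposure Information"),
    ("endpoint_readout_information", "Endpoint Read Out Information"),
    ("analysis_statistics", "Analysis and Statistics"),
]

# module_id -> list of (subdivision, [entries])
FIELDS: dict[str, list[tuple[str, list[tuple]]]] = {
    "general_information": [
        (
            "Study Identification",
            [
                ("experiment name", "t", "", "a", (), "MIT core"),
                ("study title", "t"),
                ("study identifier", "i"),
                ("project name", "t"),
                ("study type", "c"),
                ("data generation date", "t", "", "a", (), "DataCite"),
                ("funding information", "t", "", "a", ("grant information",)),
            ],
        ),
        (
            "Authorship and Institution",
            [
                ("author name", "t", "", "a", ("creator",), "Dublin Core"),
                ("author identifier", "i", "", "a", ("orcid",), "DataCite"),
                ("contact email", "t"),
                ("data generating institution", "t", "", "a", (), "MIT core"),
                ("institution address", "t"),
                ("contributor role", "c", "", "a", (), "DataCite"),
            ],
        ),
        (
            "Data Management and Access",
            [
                ("data access conditions", "t", "", "a", ("access rights",)),
                ("license", "c", "", "a", (), "Dublin Core"),
                ("persistent identifier", "i", "", "a", ("doi",), "DataCite"),
                ("repository name", "t"),
                ("data format", "c"),
                ("related publication", "i"),
            ],
        ),
        (
            "Documentation",
            [
                ("abbreviations", "t"),
                ("supplemental material", "t"),
                ("study description", "t", "", "a", ("abstract",)),
            ],
        ),
    ],
    "material_information": [
        (
            "Material Identification",
            [
                ("compound name", "t", "", "a", ("material name",), "MIT core"),
                ("material identifier", "i"),
                ("cas number", "i", "", "a", (), "REACH"),
                ("material class", "c", "", "a", ("nanomaterial type",)),
                ("major use", "t", "", "a", ("application",), "MIT core"),
                ("material design rationale", "t"),
            ],
        ),
        (
            "Synthesis and Production",
            [
                ("synthesis method", "t"),
                ("production batch", "i", "", "a", ("batch number",)),
                ("manufacturer", "t"),
                ("synthesis date", "t"),
                ("precursor materials", "t"),
            ],
        ),
        (
            "Sample Preparation",
            [
                ("sample preparation protocol", "t", "", "a", (), "DaNa"),
                ("vehicle", "t"),
                ("stock concentration", "q", "mg/mL"),
                ("sonication settings", "t"),
            ],
        ),
        (
            "Physicochemical Characterization",
            [
                ("particle size", "q", "nm", "a", ("primary particle size",), "ISO/TC 229"),
                ("size distribution", "t", "", "a", (), "ISO/TC 229"),
                ("particle shape", "c", "", "a", ("morphology",), "ISO/TC 229"),
                ("zeta potential", "q", "mV", "a", ("surface charge",), "ISO/TC 229"),
                ("surface area", "q", "m2/g", "a", (), "REACH"),
                ("surface coating", "t"),
                ("surface functionalization", "t", "", "a", (), "REACH"),
                ("crystallinity", "c", "", "a", ("crystal structure",)),
                ("agglomeration state", "c", "", "a", ("aggregation state",), "ISO/TC 229"),
                ("endotoxin content", "q", "EU/mL", "a", (), "MIRIBEL"),
            ],
        ),
        (
            "Stability and Storage",
            [
                ("storage conditions", "t"),
                ("stability period", "q", "d"),
                ("expiry date", "t"),
            ],
        ),
        (
            "Dispersion",
            [
                ("dispersion protocol", "t", "", "a", (), "MIT core"),
                ("dispersion medium", "t"),
                ("dispersant concentration", "q", "mg/mL"),
                ("dispersion stability", "t"),
            ],
        ),
    ],
    "biological_model_information": [
        (
            "Model Overview",
            [
                ("biological model type", "c", "", "a", ("test system",)),
                ("model organism", "c"),
                ("tissue type", "c"),
                ("model description", "t"),
                ("supplier name", "t"),
                ("biological model identifier", "i"),
            ],
        ),
        (
            "Cell Line Information",
            [
                ("cell line name", "t", "", "vitro", (), "LINCS"),
                ("cell line identifier", "i", "", "vitro", ("rrid",), "LINCS"),
                ("cell type", "c", "", "vitro"),
                ("cell origin", "t", "", "vitro", (), "MIT core"),
                ("donor species", "c", "", "vitro"),
                ("donor details", "t", "", "vitro", ("donor ethnicity",), "MIT core"),
                ("genetic background", "t", "", "vitro", (), "MIT core"),
                ("genetic modification", "t", "", "vitro", (), "MIT core"),
                ("phenotype", "t", "", "vitro", (), "MIT core"),
                ("mycoplasma status", "b", "", "vitro", (), "LINCS"),
                ("authentication method", "t", "", "vitro", (), "LINCS"),
                ("passage number", "q", "", "vitro", (), "MIT core"),
            ],
        ),
        (
            "Cell Culture Conditions",
            [
                ("culture medium", "t", "", "vitro", ("cell culture medium",)),
                ("medium supplements", "t", "", "vitro"),
                ("serum presence", "b", "", "vitro", (), "MIT core"),
                ("serum concentration", "q", "%", "vitro"),
                ("antibiotics used", "t", "", "vitro"),
                ("plate format", "c", "", "vitro", ("type of well plate",), "MIT core"),
                ("seeding density", "q", "cells/cm2", "vitro", (), "MIT core"),
                ("culturing time", "q", "h", "vitro"),
                ("incubation temperature", "q", "degC", "vitro"),
                ("co2 concentration", "q", "%", "vitro"),
                ("humidity level", "q", "%", "vitro"),
                ("permeable support", "t", "", "vitro"),
            ],
        ),
        (
            "Differentiation and Status",
            [
                ("differentiation status", "t", "", "vitro", (), "MIT core"),
                ("differentiation protocol", "t", "", "vitro"),
                ("differentiation markers", "t", "", "vitro"),
                ("metabolic capacity", "t", "", "vitro"),
                ("confluency at exposure", "q", "%", "vitro"),
                ("cell viability baseline", "q", "%", "vitro"),
                ("doubling time", "q", "h", "vitro"),
            ],
        ),
        (
            "In Vivo Model",
            [
                ("animal species", "c", "", "vivo", (), "ARRIVE"),
                ("animal strain", "c", "", "vivo", (), "ARRIVE"),
                ("animal sex", "c", "", "vivo", (), "ARRIVE"),
                ("animal age", "q", "wk", "vivo", (), "ARRIVE"),
                ("animal weight", "q", "g", "vivo", (), "ARRIVE"),
                ("genetic line", "t", "", "vivo"),
                ("health status", "t", "", "vivo", (), "MIT core"),
                ("number of animals", "q", "", "vivo", (), "ARRIVE"),
                ("randomization method", "t", "", "vivo", (), "ARRIVE"),
                ("ethical approval", "i", "", "vivo", (), "ARRIVE"),
                ("animal supplier", "t", "", "vivo"),
                ("acclimatization period", "q", "d", "vivo"),
            ],
        ),
        (
            "Animal Housing",
            [
                ("housing conditions", "t", "", "vivo", (), "ARRIVE"),
                ("cage type", "t", "", "vivo"),
                ("environmental enrichment", "t", "", "vivo", (), "MIT core"),
                ("bedding material", "t", "", "vivo"),
                ("light cycle", "t", "", "vivo"),
                ("room temperature", "q", "degC", "vivo"),
                ("diet", "t", "", "vivo", ("feed",), "ARRIVE"),
                ("water access", "t", "", "vivo"),
                ("group size per cage", "q", "", "vivo"),
            ],
        ),
        (
            "Quality and Acceptance Criteria",
            [
                ("acceptance criteria", "t", "", "a", (), "OECD GD 211"),
                ("quality criteria", "t", "", "a", (), "MIT core"),
                ("positive control", "t", "", "a", (), "OECD GD 211"),
                ("negative control", "t", "", "a", (), "OECD GD 211"),
                ("assay interference check", "t", "", "a", ("interference control",), "MIT core"),
                ("reference material", "t"),
            ],
        ),
        (
            "Biological Safety",
            [
                ("biosafety level", "c"),
                ("license information", "t", "", "a", (), "MIT core"),
                ("animal facility license", "i", "", "vivo"),
                ("operator training", "t"),
                ("waste handling", "t"),
            ],
        ),
    ],
    "exposure_information": [
        (
            "Exposure Design",
            [
                ("study design", "t", "", "a", (), "OECD GD 211"),
                ("exposure route", "c", "", "a", ("route of exposure",), "MIT core"),
                ("exposure type", "c"),
                ("exposure duration", "q", "h", "a", (), "OECD TG"),
                ("exposure frequency", "t", "", "a", (), "OECD TG"),
                ("recovery period", "q", "d"),
                ("number of replicates", "q"),
                ("control exposure", "t"),
            ],
        ),
        (
            "Dose Information",
            [
                ("applied dose", "q", "ug/mL", "a", ("administered dose",), "MIT core"),
                ("delivered dose", "q", "ug/cm2", "a", (), "MIT core"),
                ("dose metric", "c", "", "a", (), "MIT core"),
                ("dose units", "c"),
                ("dose rate", "q"),
                ("number of dose groups", "q", "", "a", (), "OECD TG"),
                ("dose selection rationale", "t"),
                ("dosimetry model", "t", "", "a", (), "MIT core"),
                ("internal dose", "q"),
            ],
        ),
        (
            "In Vitro Exposure",
            [
                ("exposure medium", "t", "", "vitro"),
                ("exposure volume", "q", "mL", "vitro"),
                ("medium change schedule", "t", "", "vitro"),
                ("submerged exposure", "b", "", "vitro", (), "MIT core"),
                ("exposure vessel", "t", "", "vitro"),
                ("cell-free control", "b", "", "vitro"),
                ("dispersion before exposure", "t", "", "vitro"),
                ("exposure temperature", "q", "degC", "vitro"),
            ],
        ),
        (
            "In Vivo Exposure",
            [
                ("administration method", "c", "", "vivo", (), "OECD TG"),
                ("anesthesia used", "t", "", "vivo", (), "ARRIVE"),
                ("instillation volume", "q", "uL", "vivo"),
                ("inhalation chamber type", "t", "", "vivo", (), "OECD TG"),
                ("gavage volume", "q", "uL", "vivo"),
                ("injection site", "c", "", "vivo"),
                ("exposure concentration monitoring", "t", "", "vivo", (), "OECD TG"),
                ("observed clinical signs", "t", "", "vivo", (), "ARRIVE"),
                ("body weight monitoring", "t", "", "vivo", (), "OECD TG"),
            ],
        ),
        (
            "Application and Aerosol",
            [
                ("application type", "c", "", "a", (), "MIT core"),
                ("aerosol concentration", "q", "mg/m3", "a", (), "OECD TG"),
                ("droplet size", "q", "um"),
                ("air flow rate", "q", "L/min"),
                ("humidity during exposure", "q", "%"),
                ("temperature during exposure", "q", "degC"),
                ("particle deposition estimate", "q", "ug/cm2"),
            ],
        ),
        (
            "Sampling and Timing",
            [
                ("sampling time points", "t", "", "a", (), "MIT core"),
                ("sample collection method", "t"),
                ("sample storage", "t"),
                ("time between exposure and readout", "q", "h"),
                ("washing procedure", "t"),
                ("fixation method", "t"),
                ("sample identifier", "i"),
            ],
        ),
    ],
    "endpoint_readout_information": [
        (
            "Assay Description",
            [
                ("assay name", "t", "", "a", (), "MIT core"),
                ("endpoint category", "c"),
                ("endpoint measured", "t", "", "a", (), "MIT core"),
                ("assay principle", "t"),
                ("assay protocol reference", "i", "", "a", ("sop reference assay",)),
                ("assay kit", "t"),
                ("kit lot number", "i"),
                ("detection limit", "q"),
                ("dynamic range", "t"),
                ("throughput format", "c"),
            ],
        ),
        (
            "Method Details",
            [
                ("method name", "t", "", "a", (), "MIT core"),
                ("method version", "t"),
                ("known uses", "t", "", "a", (), "MIT core"),
                ("applicability", "t", "", "a", (), "MIT core"),
                ("robustness", "t", "", "a", (), "MIT core"),
                ("method validation status", "t"),
                ("sop reference", "i", "", "a", (), "DaNa"),
                ("calibration procedure", "t"),
                ("measurement replicates", "q"),
                ("blank correction", "t"),
                ("background correction", "t"),
                ("data acquisition time", "q", "s"),
            ],
        ),
        (
            "Instrument General",
            [
                ("instrument name", "t", "", "a", (), "MIT core"),
                ("instrument manufacturer", "t"),
                ("instrument model", "t"),
                ("instrument serial number", "i"),
                ("instrument configuration", "t", "", "a", (), "MIT core"),
                ("software name", "t"),
                ("software version", "t"),
                ("maintenance date", "t", "", "a", (), "microscopy SOP"),
                ("calibration date", "t", "", "a", (), "microscopy SOP"),
                ("measurement temperature", "q", "degC"),
                ("measurement mode", "c"),
                ("detector type", "c"),
                ("light source", "t"),
                ("acquisition settings", "t"),
                ("sample holder", "t"),
                ("instrument settings file", "i"),
            ],
        ),
        (
            "Flow Cytometry",
            [
                ("cytometer type", "t", "", "a", (), "MIFlowCyt"),
                ("laser wavelengths", "t", "", "a", (), "MIFlowCyt"),
                ("laser power", "q", "mW", "a", (), "MIFlowCyt"),
                ("fluorochromes used", "t", "", "a", (), "MIFlowCyt"),
                ("antibody panel", "t", "", "a", (), "MIFlowCyt"),
                ("antibody clone", "t", "", "a", (), "MIFlowCyt"),
                ("antibody concentration", "q", "ug/mL", "a", (), "MIFlowCyt"),
                ("staining protocol", "t", "", "a", (), "MIFlowCyt"),
                ("compensation method", "t", "", "a", (), "MIFlowCyt"),
                ("gating strategy", "t", "", "a", (), "MIFlowCyt"),
                ("number of events", "q", "", "a", (), "MIFlowCyt"),
                ("flow rate setting", "t"),
                ("forward scatter settings", "t", "", "a", (), "MIFlowCyt"),
                ("side scatter settings", "t", "", "a", (), "MIFlowCyt"),
                ("detector voltages", "t", "", "a", (), "MIFlowCyt"),
                ("threshold settings", "t"),
                ("quality control beads", "t", "", "a", (), "MIFlowCyt"),
                ("carryover control", "t"),
                ("doublet discrimination", "t"),
                ("flow data file format", "c", "", "a", ("fcs version",), "MIFlowCyt"),
            ],
        ),
        (
            "Light Microscopy",
            [
                ("microscope type", "c", "", "a", (), "4DN-BINA"),
                ("objective magnification", "q", "x", "a", ("magnification",), "MIT core"),
                ("numerical aperture", "q", "", "a", (), "MIT core"),
                ("immersion medium", "c", "", "a", (), "4DN-BINA"),
                ("filter sets", "t", "", "a", (), "4DN-BINA"),
                ("excitation wavelength", "q", "nm", "a", (), "4DN-BINA"),
                ("emission wavelength", "q", "nm", "a", (), "4DN-BINA"),
                ("exposure time", "q", "ms", "a", (), "4DN-BINA"),
                ("camera model", "t", "", "a", (), "4DN-BINA"),
                ("pixel size", "q", "um", "a", (), "4DN-BINA"),
                ("z-stack settings", "t"),
                ("image bit depth", "q", "bit"),
                ("illumination intensity", "q"),
                ("contrast method", "c"),
                ("staining dye", "t"),
                ("mounting medium", "t"),
                ("live cell imaging", "b"),
                ("image acquisition software", "t"),
                ("deconvolution method", "t"),
                ("scale bar calibration", "t", "", "a", (), "microscopy SOP"),
            ],
        ),
        (
            "Electron Microscopy",
            [
                ("electron microscope type", "c", "", "a", ("em type",), "ISO/TC 229"),
                ("acceleration voltage", "q", "kV"),
                ("beam current", "q", "nA"),
                ("working distance", "q", "mm"),
                ("vacuum level", "q", "Pa"),
                ("grid type", "t"),
                ("grid coating", "t"),
                ("sample coating", "t"),
                ("em fixation protocol", "t"),
                ("dehydration protocol", "t"),
                ("embedding resin", "t"),
                ("section thickness", "q", "nm"),
                ("heavy metal staining", "t"),
                ("em detector", "c"),
                ("magnification range", "t"),
                ("em image resolution", "q", "nm"),
                ("elemental analysis mode", "c", "", "a", ("eds mode",)),
                ("cryo conditions", "t"),
                ("tilt angle", "q", "deg"),
                ("em image software", "t"),
            ],
        ),
    ],
    "analysis_statistics": [
        (
            "Data Analysis",
            [
                ("analysis method", "t", "", "a", (), "MIT core"),
                ("data processing steps", "t"),
                ("normalization method", "t"),
                ("background subtraction", "t"),
                ("outlier handling", "t"),
                ("curve fitting model", "t", "", "a", (), "MIT core"),
                ("fit parameters", "t", "", "a", (), "MIT core"),
                ("dose-response model", "t", "", "a", (), "MIT core"),
                ("ec50 value", "q", "ug/mL"),
                ("goodness of fit", "q"),
                ("data transformation", "t"),
                ("analysis protocol reference", "i"),
            ],
        ),
        (
            "Statistics",
            [
                ("statistic", "t", "", "a", (), "MIT core"),
                ("statistical test", "c", "", "a", (), "DaNa"),
                ("significance level", "q"),
                ("p value adjustment", "c"),
                ("sample size per group", "q"),
                ("statistical power", "q"),
                ("variance measure", "c"),
                ("error bars definition", "t"),
                ("number of independent experiments", "q"),
                ("technical replicates", "q"),
                ("statistical software settings", "t"),
            ],
        ),
        (
            "Software and Limitations",
            [
                ("software used", "t", "", "a", (), "MIT core"),
                ("analysis software version", "t"),
                ("software license", "t"),
                ("custom code availability", "t"),
                ("known limitations", "t", "", "a", (), "MIT core"),
                ("data exclusion criteria", "t"),
                ("raw data availability", "t"),
                ("analysis date", "t"),
            ],
        ),
    ],
}

# fields with a named provenance above were drawn from the cited standard
# family; everything else is reconstructed from module descriptions
RECONSTRUCTED_TAG = "reconstructed"

EXPECTED_CONTENT_COUNTS = {
    "general_information": 22,
    "material_information": 32,
    "biological_model_information": 69,
    "exposure_information": 48,
    "endpoint_readout_information": 98,
    "analysis_statistics": 31,
}
EXPECTED_GROUPING_TOTAL = 33
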