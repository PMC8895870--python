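"""Editable defaults: evidence-code whitelists, compartment and disease bins.

The selection criteria these encode ("binary, experimental determination",
three subcellular compartments, five disease categories) are fixed; the
exact code lists are reconstructions and are user-overridable, either by
passing explicit sets to the functions that consume them or by loading a
YAML file with :func:`load_config`.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = [
    "default_evidence_whitelists",
    "DEFAULT_GO_COMPARTMENTS",
    "DEFAULT_DISEASE_BINS",
    "DEFAULT_MODEL_GRID",
    "load_config",
]

#: PSI-MI detection methods indicating binary, experimental determination.
#: Reconstruction: the criterion excludes co-complex, small-molecule and
#: computationally predicted evidence; edit freely.
BINARY_EXPERIMENTAL_METHODS: set[str] = {
    "MI:0018",  # two hybrid
    "MI:0397",  # two hybrid array
    "MI:0398",  # two hybrid pooling approach
    "MI:0399",  # two hybrid fragment pooling
    "MI:0232",  # transcriptional complementation assay
    "MI:0112",  # ubiquitin reconstruction
    "MI:0809",  # bimolecular fluorescence complementation
    "MI:0055",  # fluorescent resonance energy transfer
    "MI:0107",  # surface plasmon resonance
    "MI:0065",  # isothermal titration calorimetry
    "MI:0077",  # nuclear magnetic resonance
    "MI:0114",  # x-ray crystallography
    "MI:0411",  # enzyme linked immunosorbent assay
    "MI:0047",  # far western blotting
    "MI:0096",  # pull down (pairwise bait-prey)
}

#: PSI-MI interaction types accepted as binary physical interactions.
BINARY_INTERACTION_TYPES: set[str] = {
    "MI:0407",  # direct interaction
    "MI:0915",  # physical association (pairwise records only)
}

#: Codes that the defaults deliberately exclude (documentation aid).
EXCLUDED_TYPE_EXAMPLES: set[str] = {
    "MI:0403",  # colocalization
    "MI:0914",  # association (co-complex)
    "MI:1110",  # predicted interaction
}


def default_evidence_whitelists() -> dict[str, set[str]]:
    return {
        "detection_methods": set(BINARY_EXPERIMENTAL_METHODS),
        "interaction_types": set(BINARY_INTERACTION_TYPES),
    }


#: GO Cellular Component term groups defining the three compartments.
DEFAULT_GO_COMPARTMENTS: dict[str, set[str]] = {
    "Extracellular": {
        "GO:0005576",  # extracellular region
        "GO:0031012",  # extracellular matrix
    },
    "Membrane": {
        "GO:0009986",  # cell surface
        "GO:0016020",  # membrane
        "GO:0030054",  # cell junction
        "GO:0042995",  # cell projection
    },
    "Intracellular": {
        "GO:0005737",  # cytoplasm
        "GO:0044297",  # cell body
        "GO:0009295",  # nucleoid
        "GO:0031974",  # membrane-enclosed lumen
        "GO:0043226",  # organelle
        "GO:0012505",  # endomembrane system
        "GO:0030496",  # midbody
    },
}

#: Disease-term -> category map (reconstruction; the five microbiome-linked
#: categories of interest).  Keys are lower-cased substrings matched against
#: disease names; extend via YAML for a real DisGeNET export.
DEFAULT_DISEASE_BINS: dict[str, str] = {
    "colorectal cancer": "CRC",
    "colorectal carcinoma": "CRC",
    "colonic neoplasm": "CRC",
    "crohn": "IBD",
    "ulcerative colitis": "IBD",
    "inflammatory bowel": "IBD",
    "obesity": "Obesity",
    "type 2 diabetes": "T2D",
    "diabetes mellitus, non-insulin-dependent": "T2D",
    "rheumatoid arthritis": "Autoimmune",
    "systemic lupus": "Autoimmune",
    "multiple sclerosis": "Autoimmune",
    "psoriasis": "Autoimmune",
    "celiac": "Autoimmune",
}

#: Random-forest hyperparameter grid searched once per study.
DEFAULT_MODEL_GRID: dict[str, list] = {
    "n_estimators": [100, 500],
    "max_depth": [None, 10],
    "min_samples_leaf": [1, 5],
}

#: Human Protein Atlas reliability labels retained for tissue annotation.
RELIABLE_ATLAS_LABELS: set[str] = {"enhanced", "supported", "approved"}


def load_config(path: str | Path) -> dict:
    """Load a YAML config; list-valued whitelist keys become sets."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for key in ("detection_methods", "interaction_types"):
        if key in cfg:
            cfg[key] = set(cfg[key])
    return cfg
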