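"""Packaged brain-region configuration.

The 19 regions analyzed in the cichlid visual-learning study, grouped by
brain division. Abbreviations follow the standard teleost nomenclature.
"""

from __future__ import annotations

#: Full names keyed by abbreviation, in anatomical (rostro-caudal) order.
REGION_NAMES: dict[str, str] = {
    # telencephalon
    "OB": "olfactory bulb / granular layer",
    "Dmd": "dorsal subdivision of the medial division of the dorsal telencephalon",
    "Dmv": "ventral subdivision of the medial division of the dorsal telencephalon",
    "Dldm": "dorsal subdivision of the lateral division of the dorsal telencephalon, pars magnocellularis",
    "Dldp": "dorsal subdivision of the lateral division of the dorsal telencephalon, pars parvocellularis",
    "Dlv": "ventral subdivision of the lateral division of the dorsal telencephalon",
    "Dcd": "dorsal subdivision of the central division of the dorsal telencephalon",
    "Dcv": "ventral subdivision of the central division of the dorsal telencephalon",
    "Dp": "posterior division of the dorsal telencephalon",
    "POA": "preoptic area",
    # diencephalon
    "NG": "nucleus glomerulosus",
    "NDI": "nucleus diffusus lobi inferioris",
    "PGc": "commissural preglomerular nucleus",
    # mesencephalon
    "TOp": "periventricular layer of the tectum opticum",
    "TOs": "superficial layer of the tectum opticum",
    "TS": "torus semicircularis",
    "TLat": "torus lateralis",
    # brainstem
    "RF": "reticular formation",
    "VL": "vagal lobe",
}

#: The 19 region abbreviations, in the packaged order.
REGIONS: tuple[str, ...] = tuple(REGION_NAMES)

#: Brain division per region.
REGION_DIVISIONS: dict[str, str] = {
    **{r: "telencephalon" for r in REGIONS[:10]},
    **{r: "diencephalon" for r in REGIONS[10:13]},
    **{r: "mesencephalon" for r in REGIONS[13:17]},
    **{r: "brainstem" for r in REGIONS[17:]},
}

#: The four experimental groups; "control" is the statistical reference.
GROUPS: tuple[str, ...] = ("control", "avoidance", "trained", "novelty")
CONTROL_GROUP: str = "control"
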