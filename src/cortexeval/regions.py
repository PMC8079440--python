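"""Desikan-Killiany-Tourville (DKT) cortical region set.

The DKT protocol defines 31 gyral labels per hemisphere. Regional mean
cortical thickness tables carry one column per (hemisphere, label), 62 in
total, named ``lh_<code>`` / ``rh_<code>``.
"""

from __future__ import annotations

from dataclasses import dataclass

# (code, full name) for the 31 per-hemisphere cortical labels, in protocol order.
_DKT31: list[tuple[str, str]] = [
    ("cACC", "caudal anterior cingulate"),
    ("cMFG", "caudal middle frontal"),
    ("CUN", "cuneus"),
    ("ENT", "entorhinal"),
    ("FUS", "fusiform"),
    ("IPL", "inferior parietal"),
    ("ITG", "inferior temporal"),
    ("iCC", "isthmus cingulate"),
    ("LOG", "lateral occipital"),
    ("LOF", "lateral orbitofrontal"),
    ("LING", "lingual"),
    ("MOF", "medial orbitofrontal"),
    ("MTG", "middle temporal"),
    ("PARH", "parahippocampal"),
    ("paraC", "paracentral"),
    ("pOPER", "pars opercularis"),
    ("pORB", "pars orbitalis"),
    ("pTRI", "pars triangularis"),
    ("periCAL", "pericalcarine"),
    ("postC", "postcentral"),
    ("PCC", "posterior cingulate"),
    ("preC", "precentral"),
    ("PCUN", "precuneus"),
    ("rACC", "rostral anterior cingulate"),
    ("rMFG", "rostral middle frontal"),
    ("SFG", "superior frontal"),
    ("SPL", "superior parietal"),
    ("STG", "superior temporal"),
    ("SMAR", "supramarginal"),
    ("TT", "transverse temporal"),
    ("INS", "insula"),
]


@dataclass(frozen=True)
class Region:
    code: str        # column name, e.g. "lh_ENT"
    abbreviation: str  # protocol abbreviation, e.g. "ENT"
    name: str        # full label
    hemisphere: str  # "left" | "right"


def _build_regions() -> tuple[Region, ...]:
    out = []
    for prefix, hemi in (("lh", "left"), ("rh", "right")):
        for abbr, name in _DKT31:
            out.append(Region(f"{prefix}_{abbr}", abbr, f"{hemi} {name}", hemi))
    return tuple(out)


DKT_REGIONS: tuple[Region, ...] = _build_regions()
REGION_CODES: tuple[str, ...] = tuple(r.code for r in DKT_REGIONS)
N_REGIONS: int = len(DKT_REGIONS)


def hemisphere_of(code: str) -> str:
    """Hemisphere ("left"/"right") of a region column code such as "rh_ENT"."""
    if code.startswith("lh_"):
        return "left"
    if code.startswith("rh_"):
        return "right"
    raise ValueError(f"not a DKT region code: {code!r}")
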