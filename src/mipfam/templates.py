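"""Synthetic annotated subfamily templates.

These are code-generated, deterministic stand-in sequences (not real plant
aquaporins) with the canonical aquaporin architecture: six hydrophobic TM
helices, NPA boxes in loops B and E, a subfamily-specific ar/R tetrad and
Froger pentad at fixed, annotated columns. They anchor position mapping and
seed the synthetic-data generator.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .motif_profile import ReferenceTemplate

# segment lengths: N-term, TM1, loopA, TM2, loopB, TM3, loopC, TM4, loopD,
# TM5, loopE, TM6, C-term
_SEGMENTS = (
    ("nterm", 10), ("TM1", 21), ("loopA", 8), ("TM2", 21), ("loopB", 14),
    ("TM3", 21), ("loopC", 12), ("TM4", 21), ("loopD", 8), ("TM5", 21),
    ("loopE", 16), ("TM6", 21), ("cterm", 12),
)

TEMPLATE_LENGTH = sum(n for _, n in _SEGMENTS)  # 206

# hydrophobic residues for TM cores, hydrophilic for loops/termini
HYDROPHOBIC = "LIVLIVLIVFMA"
HYDROPHILIC = "DEKRNQSTDEKRGS"

_ARR_TETRADS = {
    "PIP": ("F", "H", "T", "R"),
    "TIP": ("H", "I", "A", "V"),   # TIP group I
    "NIP": ("W", "V", "A", "R"),   # NIP group I
    "SIP": ("A", "N", "V", "H"),   # SIP group I
    "XIP": ("I", "T", "V", "R"),
}

_FROGER_PENTADS = {
    "PIP": ("Q", "S", "A", "F", "W"),
    "TIP": ("T", "S", "A", "Y", "W"),
    "NIP": ("F", "S", "A", "Y", "L"),
    "SIP": ("I", "A", "A", "Y", "W"),
    "XIP": ("V", "C", "A", "F", "W"),
}

_SUBFAMILY_SEEDS = {"PIP": 101, "TIP": 102, "NIP": 103, "SIP": 104, "XIP": 105}

# annotated columns relative to segment starts (0-based offsets)
_H2_OFFSET_IN_TM2 = 11
_NPA1_OFFSET_IN_LOOPB = 5
_P1_OFFSET_IN_LOOPC = 5
_H5_OFFSET_IN_TM5 = 15
_NPA2_OFFSET_IN_LOOPE = 3
_LE1_OFFSET_IN_LOOPE = 8
_LE2_OFFSET_IN_LOOPE = 10
_P2_OFFSET_IN_LOOPE = 12
_P3_OFFSET_IN_LOOPE = 13
_P4_OFFSET_IN_CTERM = 2
_P5_OFFSET_IN_CTERM = 4


def _segment_bounds():
    bounds = {}
    pos = 1
    for name, length in _SEGMENTS:
        bounds[name] = (pos, pos + length - 1)
        pos += length
    return bounds


def build_template(subfamily: str, seed: int | None = None) -> ReferenceTemplate:
    if subfamily not in _ARR_TETRADS:
        raise ValueError(f"no template defined for subfamily {subfamily!r}")
    rng = np.random.default_rng(
        _SUBFAMILY_SEEDS[subfamily] if seed is None else seed
    )
    bounds = _segment_bounds()
    seq = []
    for name, length in _SEGMENTS:
        alphabet = HYDROPHOBIC if name.startswith("TM") else HYDROPHILIC
        seq.extend(rng.choice(list(alphabet), size=length))
    seq = list("".join(seq))

    def put(pos: int, ch: str):
        seq[pos - 1] = ch

    h2 = bounds["TM2"][0] + _H2_OFFSET_IN_TM2
    h5 = bounds["TM5"][0] + _H5_OFFSET_IN_TM5
    npa1 = bounds["loopB"][0] + _NPA1_OFFSET_IN_LOOPB
    npa2 = bounds["loopE"][0] + _NPA2_OFFSET_IN_LOOPE
    le1 = bounds["loopE"][0] + _LE1_OFFSET_IN_LOOPE
    le2 = bounds["loopE"][0] + _LE2_OFFSET_IN_LOOPE
    froger_cols = {
        "P1": bounds["loopC"][0] + _P1_OFFSET_IN_LOOPC,
        "P2": bounds["loopE"][0] + _P2_OFFSET_IN_LOOPE,
        "P3": bounds["loopE"][0] + _P3_OFFSET_IN_LOOPE,
        "P4": bounds["cterm"][0] + _P4_OFFSET_IN_CTERM,
        "P5": bounds["cterm"][0] + _P5_OFFSET_IN_CTERM,
    }

    for pos, ch in zip((npa1, npa1 + 1, npa1 + 2), "NPA"):
        put(pos, ch)
    for pos, ch in zip((npa2, npa2 + 1, npa2 + 2), "NPA"):
        put(pos, ch)
    tetrad = _ARR_TETRADS[subfamily]
    for pos, ch in zip((h2, h5, le1, le2), tetrad):
        put(pos, ch)
    for name, ch in zip(("P1", "P2", "P3", "P4", "P5"), _FROGER_PENTADS[subfamily]):
        put(froger_cols[name], ch)

    tm = tuple(bounds[f"TM{i}"] for i in range(1, 7))
    return ReferenceTemplate(
        subfamily=subfamily,
        sequence="".join(seq),
        npa1=npa1,
        npa2=npa2,
        arR={"H2": h2, "H5": h5, "LE1": le1, "LE2": le2},
        froger=froger_cols,
        tm=tm,
    )


@lru_cache(maxsize=1)
def build_default_templates() -> dict:
    """One synthetic template per subfamily (PIP, TIP, NIP, SIP, XIP)."""
    return {sf: build_template(sf) for sf in _ARR_TETRADS}


def annotated_columns(template: ReferenceTemplate) -> set:
    """The point-annotated columns (NPA boxes, ar/R tetrad, Froger pentad)
    that the synthetic generator leaves untouched by background mutation."""
    cols = set()
    for pos in (template.npa1, template.npa2):
        cols.update((pos, pos + 1, pos + 2))
    cols.update(template.arR.values())
    cols.update(template.froger.values())
    return cols
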