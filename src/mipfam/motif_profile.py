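"""Structural profiling of aquaporins.

For each protein this module locates the six transmembrane (TM) helices, the
two NPA boxes of loops B and E, the four ar/R selectivity-filter residues
(positions H2, H5, LE1, LE2) and the five Froger positions (P1-P5), and
assigns an ar/R group by an ordered rule table covering the nine groups seen
in plant aquaporin families.

Positions are resolved by reference-anchored mapping: the query is globally
aligned to an annotated subfamily template and each annotated template column
is read off the aligned query. This keeps the positional semantics of
H2/H5/LE1/LE2 exact and testable without a multiple alignment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import align_strings, make_aligner
from .seqio import SequenceRecord

# Kyte-Doolittle hydropathy scale; X (ambiguous) scored neutral.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

AR_R_POSITIONS = ("H2", "H5", "LE1", "LE2")
FROGER_POSITIONS = ("P1", "P2", "P3", "P4", "P5")


@dataclass(frozen=True)
class NPASlot:
    """One NPA box: query position of its first residue (1-based, or None
    when unmapped), the three aligned residues, and canonicality."""

    position: int | None
    triplet: str
    canonical: bool

    @property
    def present(self) -> bool:
        return self.position is not None


@dataclass(frozen=True)
class MotifProfile:
    query_id: str
    tm_segments: tuple = ()
    npa1: NPASlot = NPASlot(None, "---", False)
    npa2: NPASlot = NPASlot(None, "---", False)
    arR: dict = field(default_factory=dict)
    froger: dict = field(default_factory=dict)
    group: str = "unclassified"
    template_subfamily: str = ""

    def arR_tetrad(self) -> tuple:
        return tuple(self.arR.get(p, "-") for p in AR_R_POSITIONS)


@dataclass(frozen=True)
class ReferenceTemplate:
    """An annotated subfamily reference sequence.

    ``npa1``/``npa2`` are 1-based positions of the first residue of each NPA
    box; ``arR`` and ``froger`` map position names to 1-based columns; ``tm``
    lists the six (start, end) helix ranges. The template must carry N, P, A
    at its own NPA columns.
    """

    subfamily: str
    sequence: str
    npa1: int
    npa2: int
    arR: dict
    froger: dict
    tm: tuple

    def __post_init__(self):
        n = len(self.sequence)
        cols = [self.npa1, self.npa1 + 2, self.npa2, self.npa2 + 2]
        cols += list(self.arR.values()) + list(self.froger.values())
        cols += [c for seg in self.tm for c in seg]
        for c in cols:
            if not 1 <= c <= n:
                raise ValueError(f"{self.subfamily} template: column {c} outside sequence")
        for pos in (self.npa1, self.npa2):
            if self.sequence[pos - 1:pos + 2] != "NPA":
                raise ValueError(
                    f"{self.subfamily} template: no NPA at column {pos}"
                )

    def record(self) -> SequenceRecord:
        return SequenceRecord(f"{self.subfamily}_template", self.sequence)


def default_templates() -> dict:
    """The package's built-in synthetic subfamily templates."""
    from .templates import build_default_templates

    return build_default_templates()


# ---------------------------------------------------------------------------
# Hydropathy / TM prediction


def hydropathy_profile(seq, window: int = 19) -> np.ndarray:
    """Centered moving-average Kyte-Doolittle hydropathy, one value per
    residue; window ends are truncated rather than padded."""
    if isinstance(seq, SequenceRecord):
        seq = seq.sequence
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    values = np.array([KYTE_DOOLITTLE[ch] for ch in seq], dtype=float)
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones(len(values)), kernel, mode="same")
    return sums / counts


def predict_tm_segments(profile, threshold: float = 1.6, min_len: int = 15):
    """Maximal runs of smoothed hydropathy >= threshold, at least ``min_len``
    residues long. Returns 1-based (start, end) ranges, sorted."""
    above = np.asarray(profile) >= threshold
    segments = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                segments.append((start + 1, i))
            start = None
    if start is not None and len(above) - start >= min_len:
        segments.append((start + 1, len(above)))
    return segments


# ---------------------------------------------------------------------------
# Template-anchored position mapping


def _template_self_score(template: ReferenceTemplate, aligner) -> float:
    matrix = aligner.substitution_matrix
    return float(sum(matrix[ch, ch] for ch in template.sequence))


def _column_map(row_query: str, row_template: str) -> dict:
    """template position (1-based) -> (query position or None, query char)."""
    mapping = {}
    qpos = tpos = 0
    for qc, tc in zip(row_query, row_template):
        if qc != "-":
            qpos += 1
        if tc != "-":
            tpos += 1
            mapping[tpos] = (qpos if qc != "-" else None, qc if qc != "-" else "-")
    return mapping


def map_positions(query: SequenceRecord, template: ReferenceTemplate,
                  aligner=None, score_floor: float = 0.2) -> MotifProfile:
    """Resolve a query's motif positions through its subfamily template.

    The query is globally aligned to the template; every annotated template
    column maps to the aligned query residue ('-' at gaps). An alignment
    scoring below ``score_floor`` x the template self-score yields an
    all-'-' profile with a warning instead of unreliable coordinates.
    """
    if aligner is None:
        aligner = make_aligner()
    row_q, row_t, score = align_strings(query.sequence, template.sequence,
                                        aligner=aligner)
    if score < score_floor * _template_self_score(template, aligner):
        warnings.warn(
            f"{query.id}: alignment to {template.subfamily} template below "
            "score floor; motif positions unresolved"
        )
        return MotifProfile(query_id=query.id,
                            arR={p: "-" for p in AR_R_POSITIONS},
                            froger={p: "-" for p in FROGER_POSITIONS},
                            template_subfamily=template.subfamily)
    cmap = _column_map(row_q, row_t)

    def slot(pos0: int) -> NPASlot:
        chars = "".join(cmap[pos0 + k][1] for k in range(3))
        qpos = cmap[pos0][0]
        return NPASlot(position=qpos, triplet=chars, canonical=chars == "NPA")

    arR = {name: cmap[col][1] for name, col in template.arR.items()}
    froger = {name: cmap[col][1] for name, col in template.froger.items()}

    tm_segments = []
    for s, e in template.tm:
        qpositions = [cmap[c][0] for c in range(s, e + 1) if cmap[c][0] is not None]
        if qpositions:
            tm_segments.append((min(qpositions), max(qpositions)))

    return MotifProfile(
        query_id=query.id,
        tm_segments=tuple(tm_segments),
        npa1=slot(template.npa1),
        npa2=slot(template.npa2),
        arR=arR,
        froger=froger,
        group=assign_arR_group(arR, subfamily=template.subfamily),
        template_subfamily=template.subfamily,
    )


def map_positions_best(query: SequenceRecord, templates: dict,
                       aligner=None) -> MotifProfile:
    """Scan a query against all templates; the best-scoring one wins."""
    if aligner is None:
        aligner = make_aligner()
    best = None
    for template in sorted(templates.values(), key=lambda t: t.subfamily):
        _, _, score = align_strings(query.sequence, template.sequence, aligner=aligner)
        if best is None or score > best[0]:
            best = (score, template)
    return map_positions(query, best[1], aligner=aligner)


# ---------------------------------------------------------------------------
# ar/R group rules

# Ordered rule table; None is a wildcard position. The SIP-I/SIP-II split is
# the package's documented reading of the loosely specified SIP tetrads.
AR_R_RULES = (
    ("PIP", "PIP", ({"F", "V"}, {"H"}, {"T"}, {"R"})),
    ("TIP-I", "TIP", ({"H"}, {"I"}, {"A"}, {"V"})),
    ("TIP-IIa", "TIP", ({"H"}, {"I"}, {"G"}, {"R"})),
    ("TIP-IIb", "TIP", ({"H"}, {"I"}, {"A"}, {"R"})),
    ("TIP-III", "TIP", ({"N"}, {"V"}, None, None)),
    ("NIP-I", "NIP", ({"W"}, {"V"}, {"A"}, {"R"})),
    ("NIP-I", "NIP", ({"G"}, {"S"}, {"G"}, {"R"})),
    ("NIP-II", "NIP", ({"A", "T"}, {"I", "V"}, {"G", "A"}, {"R"})),
    ("SIP-I", "SIP", ({"P", "G", "A"}, {"F", "S", "N"}, {"V", "I", "F"}, {"H", "V"})),
    ("SIP-II", "SIP", ({"S"}, {"H", "N"}, {"G", "P"}, {"A", "S"})),
    ("XIP", "XIP", ({"I", "V"}, {"I", "T"}, {"V", "R"}, {"R"})),
)


def _matches(tetrad, pattern) -> bool:
    for letter, allowed in zip(tetrad, pattern):
        if letter == "-" or allowed is None:
            continue
        if letter not in allowed:
            return False
    return True


def assign_arR_group(arR, subfamily: str | None = None) -> str:
    """Assign the ar/R group from the selectivity-filter tetrad.

    ``arR`` is a dict over H2/H5/LE1/LE2 (or a 4-tuple in that order);
    unresolved positions are '-'. At least 3 of 4 positions must be resolved.
    Rules of the stated subfamily are tried first, then the full ordered
    table; no match (or too few resolved positions) gives ``unclassified``.
    """
    if isinstance(arR, dict):
        tetrad = tuple(arR.get(p, "-") for p in AR_R_POSITIONS)
    else:
        tetrad = tuple(arR)
    if sum(1 for x in tetrad if x != "-") < 3:
        return "unclassified"
    passes = []
    if subfamily:
        passes.append([r for r in AR_R_RULES if r[1] == subfamily])
    passes.append(AR_R_RULES)
    for rules in passes:
        for group, _, pattern in rules:
            if _matches(tetrad, pattern):
                return group
    return "unclassified"


# ---------------------------------------------------------------------------
# Regex fallback for template-less NPA detection

_NPA_RE = re.compile(r"NP[A-Z]")


def find_npa_boxes(seq, max_boxes: int = 2):
    """Lower-confidence regex scan for NPA-like boxes (N-P-x), used when no
    template applies. Returns up to ``max_boxes`` NPASlots by position."""
    if isinstance(seq, SequenceRecord):
        seq = seq.sequence
    slots = []
    for m in _NPA_RE.finditer(seq):
        triplet = m.group(0)
        slots.append(NPASlot(position=m.start() + 1, triplet=triplet,
                             canonical=triplet == "NPA"))
        if len(slots) == max_boxes:
            break
    return slots
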