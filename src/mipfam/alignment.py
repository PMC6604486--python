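"""Pairwise global protein alignment shared by the screening, motif-mapping
and duplication stages.

Needleman-Wunsch with BLOSUM62 and affine gap penalties (open 10, extend 0.5,
terminal gaps penalized like internal ones). Identity is computed over the
full alignment length, gap columns included, so it is symmetric and
order-independent; ``X`` never counts as an identical match.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one global pairwise alignment (query vs reference)."""

    query_id: str
    ref_id: str
    identity_pct: float
    query_coverage_pct: float
    aligned_length: int
    score: float


@lru_cache(maxsize=8)
def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def align_strings(a: str, b: str, aligner=None):
    """Globally align two residue strings.

    Returns ``(row_a, row_b, score)`` where the rows are equal-length gapped
    strings. The first optimal alignment reported by the aligner is used,
    which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a, b)[0]
    return aln[0], aln[1], aln.score


def stats_from_rows(row_a: str, row_b: str):
    """(identical columns, both-aligned columns, alignment length)."""
    identical = 0
    both = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            both += 1
            if x == y and x != "X":
                identical += 1
    return identical, both, len(row_a)


def pairwise_global_align(a: SequenceRecord, b: SequenceRecord,
                          aligner=None) -> AlignmentResult:
    """Optimal global alignment of two protein records.

    identity_pct uses the full alignment length (terminal and internal gap
    columns in the denominator); query_coverage_pct is the fraction of query
    residues aligned opposite a reference residue.
    """
    if a.moltype != "protein" or b.moltype != "protein":
        raise ValueError("pairwise_global_align expects protein records")
    row_a, row_b, score = align_strings(a.sequence, b.sequence, aligner=aligner)
    identical, both, columns = stats_from_rows(row_a, row_b)
    return AlignmentResult(
        query_id=a.id,
        ref_id=b.id,
        identity_pct=100.0 * identical / columns,
        query_coverage_pct=100.0 * both / len(a.sequence),
        aligned_length=columns,
        score=score,
    )
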