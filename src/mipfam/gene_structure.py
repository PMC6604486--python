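"""Exon/intron profiling and subfamily-level intron-pattern summaries.

Intron counts are taken from the representative transcript's exon features
(UTR-containing exons included), so a gene with n exons has n-1 introns; the
subfamily table reports the modal intron count per subfamily — in cotton-like
cohorts typically 3 for PIPs, 4 for NIPs and 2 for TIPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import GeneModel


@dataclass(frozen=True)
class StructureSummary:
    gene_id: str
    n_exons: int
    n_introns: int
    intron_lengths: tuple
    subfamily: str = "unassigned"

    def __post_init__(self):
        assert self.n_introns == self.n_exons - 1
        if any(l <= 0 for l in self.intron_lengths):
            raise ValueError(f"{self.gene_id}: non-positive intron length")


def count_introns(model: GeneModel, subfamily: str = "unassigned") -> StructureSummary:
    """Introns are the gaps between consecutive exons of the representative
    transcript; an intron between exons (..,e) and (s,..) has length s-e-1."""
    exons = sorted(model.exons)
    lengths = tuple(
        nxt[0] - prev[1] - 1 for prev, nxt in zip(exons, exons[1:])
    )
    return StructureSummary(
        gene_id=model.gene_id,
        n_exons=len(exons),
        n_introns=len(exons) - 1,
        intron_lengths=lengths,
        subfamily=subfamily,
    )


def intron_pattern_table(summaries, assignments=None) -> pd.DataFrame:
    """Subfamily x intron-count contingency table.

    ``assignments`` (FamilyAssignments or a dict gene_id -> subfamily)
    overrides the summaries' own subfamily labels; genes without an
    assignment are tallied under ``unassigned``. Returns a tidy frame with
    columns subfamily, n_introns, count.
    """
    subfam_of = {}
    if assignments is not None:
        if isinstance(assignments, dict):
            subfam_of = dict(assignments)
        else:
            subfam_of = {a.query_id: a.subfamily for a in assignments}
    rows = []
    for s in summaries:
        rows.append({
            "subfamily": subfam_of.get(s.gene_id, s.subfamily) or "unassigned",
            "n_introns": s.n_introns,
        })
    if not rows:
        return pd.DataFrame(columns=["subfamily", "n_introns", "count"])
    df = (pd.DataFrame(rows)
          .value_counts(["subfamily", "n_introns"])
          .rename("count")
          .reset_index()
          .sort_values(["subfamily", "n_introns"])
          .reset_index(drop=True))
    return df


def modal_intron_counts(table: pd.DataFrame) -> dict:
    """Modal intron count per subfamily (smallest count wins ties)."""
    modal = {}
    for subfam, grp in table.groupby("subfamily"):
        grp = grp.sort_values(["count", "n_introns"], ascending=[False, True])
        modal[subfam] = int(grp.iloc[0]["n_introns"])
    return modal
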