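"""Candidate aquaporin screening, family/subfamily assignment and
standardized nomenclature.

The screen scores every proteome entry against a reference aquaporin set by
exact global alignment and retains entries whose best hit passes the identity
and coverage thresholds (defaults: identity >= 30%, coverage > 50%). Family
membership then follows the classical identity ladder: best identity > 40%
joins the AQP family, > 60% additionally inherits the reference's subfamily,
< 40% is flagged as a candidate new family. Paralogs sharing a best ortholog
are tagged a, b, c, ... by chromosomal order.
"""

from __future__ import annotations

import re
import string
import warnings
from dataclasses import dataclass, replace

from .alignment import AlignmentResult, make_aligner, pairwise_global_align
from .seqio import GeneModel, SequenceRecord

SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP", "HIP", "LIP", "GIP")

#: identity (%) above which a protein belongs to the AQP family
FAMILY_IDENTITY_PCT = 40.0
#: identity (%) above which the reference's subfamily is inherited
SUBFAMILY_IDENTITY_PCT = 60.0

_SUBFAM_RE = re.compile("|".join(SUBFAMILIES))
_ORTHOLOG_RE = re.compile(r"((?:%s)\d+;\d+)" % "|".join(SUBFAMILIES))


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    best_ref_id: str
    best_identity_pct: float
    best_coverage_pct: float
    family_call: str  # AQP | new_family_candidate | non_AQP
    subfamily: str = "unassigned"
    standardized_name: str = ""

    def __post_init__(self):
        if self.subfamily != "unassigned" and self.best_identity_pct <= SUBFAMILY_IDENTITY_PCT:
            raise ValueError(
                f"{self.query_id}: subfamily assigned at identity "
                f"{self.best_identity_pct:.1f}% <= {SUBFAMILY_IDENTITY_PCT}%"
            )
        if self.family_call == "AQP" and self.best_identity_pct <= FAMILY_IDENTITY_PCT:
            raise ValueError(
                f"{self.query_id}: family_call AQP at identity "
                f"{self.best_identity_pct:.1f}% <= {FAMILY_IDENTITY_PCT}%"
            )


def parse_subfamily(ref_id: str) -> str:
    """Extract the subfamily token from a reference name like ``AtPIP1;2``."""
    m = _SUBFAM_RE.search(ref_id)
    if m is None:
        return "unassigned"
    token = m.group(0)
    return "LIP/GIP" if token in ("LIP", "GIP") else token


def parse_ortholog_base(ref_id: str) -> str:
    """Extract the ortholog group name (``PIP1;4``) from a reference id."""
    m = _ORTHOLOG_RE.search(ref_id)
    return m.group(1) if m else ref_id


def best_hit(query: SequenceRecord, refset, aligner=None) -> AlignmentResult:
    """Best reference for a query: highest identity, ties broken by higher
    alignment score, then lexicographically smallest reference id."""
    if not refset:
        raise ValueError("reference set is empty")
    if aligner is None:
        aligner = make_aligner()
    results = [pairwise_global_align(query, ref, aligner=aligner) for ref in refset]
    results.sort(key=lambda r: (-r.identity_pct, -r.score, r.ref_id))
    return results[0]


def _ladder_call(identity_pct: float):
    if identity_pct > SUBFAMILY_IDENTITY_PCT:
        return "AQP", True
    if identity_pct > FAMILY_IDENTITY_PCT:
        return "AQP", False
    return "new_family_candidate", False


def screen_candidates(proteome, refset, min_identity_pct: float = 30.0,
                      min_coverage_pct: float = 50.0, aligner=None,
                      keep_rejected: bool = False):
    """Screen a proteome against a reference aquaporin set.

    Every proteome entry is scored against every reference; an entry is
    retained iff its best hit has identity >= ``min_identity_pct`` and
    coverage > ``min_coverage_pct``. Retained entries get a family call from
    the 40/60% identity ladder. Deterministic and independent of proteome
    order. With ``keep_rejected`` the non-passing entries are also returned,
    tagged ``non_AQP``.
    """
    if aligner is None:
        aligner = make_aligner()
    assignments = []
    for query in sorted(proteome, key=lambda r: r.id):
        hit = best_hit(query, refset, aligner=aligner)
        passed = (hit.identity_pct >= min_identity_pct
                  and hit.query_coverage_pct > min_coverage_pct)
        if not passed:
            if keep_rejected:
                assignments.append(FamilyAssignment(
                    query_id=query.id, best_ref_id=hit.ref_id,
                    best_identity_pct=hit.identity_pct,
                    best_coverage_pct=hit.query_coverage_pct,
                    family_call="non_AQP"))
            continue
        call, with_subfam = _ladder_call(hit.identity_pct)
        assignments.append(FamilyAssignment(
            query_id=query.id,
            best_ref_id=hit.ref_id,
            best_identity_pct=hit.identity_pct,
            best_coverage_pct=hit.query_coverage_pct,
            family_call=call,
            subfamily=parse_subfamily(hit.ref_id) if with_subfam else "unassigned",
        ))
    return assignments


def assign_nomenclature(assignments, models, prefix: str = ""):
    """Attach standardized names, tagging paralogs a, b, c, ... by position.

    Queries sharing a best-reference ortholog group are suffixed in order of
    (chromosome lexicographic, start ascending); singletons get the bare
    group name (``NIP4;1`` vs ``PIP1;4a``...``j``). More than 10 paralogs
    continue k, l, ... with a warning. ``models`` maps each query to its
    chromosome/position; a query without a gene model is an error.
    """
    by_id = {m.gene_id: m for m in models} if not isinstance(models, dict) else models
    groups: dict[str, list] = {}
    for a in assignments:
        groups.setdefault(parse_ortholog_base(a.best_ref_id), []).append(a)

    named = {}
    for base, members in groups.items():
        for a in members:
            if a.query_id not in by_id:
                raise KeyError(f"no gene model for query {a.query_id!r}")
        if len(members) == 1:
            a = members[0]
            named[a.query_id] = replace(a, standardized_name=prefix + base)
            continue
        members.sort(key=lambda a: (by_id[a.query_id].chrom,
                                    by_id[a.query_id].start, a.query_id))
        if len(members) > 10:
            warnings.warn(
                f"{len(members)} paralogs for {base}: suffixes continue past j"
            )
        for letter, a in zip(string.ascii_lowercase, members):
            named[a.query_id] = replace(a, standardized_name=prefix + base + letter)
    return [named[a.query_id] for a in assignments]
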