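"""Tandem-duplication detection and Nei-Gojobori (1986) Ka/Ks estimation.

Tandem pairs follow the classic windowed rule: two genes on the same
chromosome separated by at most five annotated genes, with nearest-boundary
distance within 100 kb and protein global-alignment identity above 70%.

Ka/Ks uses the NG86 codon-counting method: synonymous site fractions are
averaged over both sequences, observed differences are averaged with equal
weight over all minimal mutation paths per codon (paths through stop codons
excluded, falling back to all paths when none avoids a stop), and the
Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) is applied to the
proportions. Codons containing gaps, ambiguous bases or stops are excluded
from both site and difference counts. An omega (Ka/Ks) below 1 indicates
purifying selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import permutations

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .alignment import align_strings, make_aligner, pairwise_global_align, stats_from_rows
from .seqio import SequenceRecord

_FORWARD = standard_dna_table.forward_table
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_FORWARD))
_BASES = "ACGT"


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    dup_type: str  # tandem | segmental
    protein_identity_pct: float | None = None
    intervening_genes: int | None = None
    span_bp: int | None = None
    ka: float | None = None
    ks: float | None = None
    omega: float | None = None
    selection: str = "NA"

    def __post_init__(self):
        if self.dup_type not in ("tandem", "segmental"):
            raise ValueError(f"bad dup_type {self.dup_type!r}")
        for v in (self.ka, self.ks):
            if v is not None and v < 0:
                raise ValueError("negative substitution rate")


# ---------------------------------------------------------------------------
# NG86 machinery


def _translate(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    return _FORWARD.get(codon)


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three possible point
    mutations that are synonymous; mutations creating stop codons count as
    nonsynonymous.
    """
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon}")
    total = 0.0
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if _translate(alt) == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _codon_path_diffs(c1: str, c2: str) -> tuple:
    """(syn, nonsyn) observed differences between two sense codons, averaged
    with equal weight over all minimal mutation paths."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order, allow_stops):
        cur = c1
        sd = nd = 0
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            aa_cur, aa_nxt = _translate(cur), _translate(nxt)
            if aa_nxt is None and not allow_stops and nxt != c2:
                return None
            if aa_cur is not None and aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return (sd, nd)

    for allow_stops in (False, True):
        results = [r for order in permutations(diff_pos)
                   if (r := walk(order, allow_stops)) is not None]
        if results:
            sd = sum(r[0] for r in results) / len(results)
            nd = sum(r[1] for r in results) / len(results)
            return (sd, nd)
    raise AssertionError("unreachable")


def _jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; undefined (None) at p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


def _usable_codon(codon: str) -> bool:
    return (len(codon) == 3 and all(b in _BASES for b in codon)
            and codon not in STOP_CODONS)


def _codon_align(cds_a: SequenceRecord, cds_b: SequenceRecord, aligner=None):
    """Pair codons of two CDS records.

    Equal-length sequences are paired directly. Otherwise a protein-guided
    codon alignment is built: the translations are globally aligned and the
    alignment is back-threaded onto the codons, dropping columns that are
    gapped in either sequence. Incomplete terminal codons are trimmed first.
    """
    a = cds_a.sequence[:len(cds_a.sequence) - len(cds_a.sequence) % 3]
    b = cds_b.sequence[:len(cds_b.sequence) - len(cds_b.sequence) % 3]
    codons_a = [a[i:i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i:i + 3] for i in range(0, len(b), 3)]
    if len(codons_a) == len(codons_b):
        return list(zip(codons_a, codons_b))

    from Bio.Seq import Seq

    prot_a = str(Seq(a).translate())
    prot_b = str(Seq(b).translate())
    row_a, row_b, _ = align_strings(prot_a, prot_b, aligner=aligner)
    pairs = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            pairs.append((codons_a[ia], codons_b[ib]))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return pairs


def ng86_kaks(cds_a: SequenceRecord, cds_b: SequenceRecord, aligner=None):
    """Nei-Gojobori 1986 (Ka, Ks, omega) for a pair of coding sequences.

    Returns ``None`` for a rate whose Jukes-Cantor correction is undefined
    (proportion >= 3/4) and for omega when Ks is 0 or unavailable.
    """
    pairs = [(ca, cb) for ca, cb in _codon_align(cds_a, cds_b, aligner=aligner)
             if _usable_codon(ca) and _usable_codon(cb)]
    if not pairs:
        raise ValueError(
            f"no comparable codons between {cds_a.id} and {cds_b.id}"
        )
    S = sum((_syn_sites(ca) + _syn_sites(cb)) / 2.0 for ca, cb in pairs)
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for ca, cb in pairs:
        sd, nd = _codon_path_diffs(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return ka, ks, omega


def classify_selection(omega: float | None, neutral_band: float = 0.05) -> str:
    """purifying (omega < 1), positive (omega > 1), neutral~1 within the
    band around 1; NA passes through."""
    if omega is None:
        return "NA"
    if abs(omega - 1.0) <= neutral_band:
        return "neutral~1"
    return "purifying" if omega < 1.0 else "positive"


# ---------------------------------------------------------------------------
# Tandem detection


def find_tandem_pairs(models, proteins, max_intervening: int = 5,
                      max_span_bp: int = 100000, min_identity_pct: float = 70.0,
                      candidate_ids=None, aligner=None):
    """Windowed tandem-duplication scan.

    ``models`` is the full gene annotation (used for counting intervening
    genes, strand-agnostically); ``proteins`` maps gene ids to protein
    records. Candidates default to every gene with a protein; an explicit
    candidate lacking its protein is skipped with a warning. Pairs are
    reported with the upstream gene first.
    """
    if aligner is None:
        aligner = make_aligner()
    if candidate_ids is None:
        candidate_set = set(proteins)
    else:
        candidate_set = set()
        for gid in candidate_ids:
            if gid not in proteins:
                warnings.warn(f"candidate gene {gid} lacks a protein sequence; skipped")
            else:
                candidate_set.add(gid)

    by_chrom: dict[str, list] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)

    identity_cache = {}

    def identity(ga, gb):
        key = (ga, gb) if ga <= gb else (gb, ga)
        if key not in identity_cache:
            res = pairwise_global_align(proteins[key[0]], proteins[key[1]],
                                        aligner=aligner)
            identity_cache[key] = res.identity_pct
        return identity_cache[key]

    out = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda m: (m.start, m.gene_id))
        idx = [i for i, m in enumerate(genes) if m.gene_id in candidate_set]
        for a_pos in range(len(idx)):
            i = idx[a_pos]
            for b_pos in range(a_pos + 1, len(idx)):
                j = idx[b_pos]
                intervening = j - i - 1
                if intervening > max_intervening:
                    break
                span = genes[j].start - genes[i].end
                if span > max_span_bp:
                    continue
                ident = identity(genes[i].gene_id, genes[j].gene_id)
                if ident > min_identity_pct:
                    out.append(DuplicatePair(
                        gene_a=genes[i].gene_id,
                        gene_b=genes[j].gene_id,
                        dup_type="tandem",
                        protein_identity_pct=ident,
                        intervening_genes=intervening,
                        span_bp=span,
                    ))
    return out


def compute_pair_kaks(pairs, cds_map, neutral_band: float = 0.05, aligner=None):
    """Fill Ka/Ks/omega and the selection call for duplicate pairs whose CDS
    are available; pairs lacking a CDS are passed through unchanged."""
    out = []
    for p in pairs:
        if p.gene_a in cds_map and p.gene_b in cds_map:
            ka, ks, omega = ng86_kaks(cds_map[p.gene_a], cds_map[p.gene_b],
                                      aligner=aligner)
            out.append(replace(p, ka=ka, ks=ks, omega=omega,
                               selection=classify_selection(omega, neutral_band)))
        else:
            out.append(p)
    return out


def load_segmental_pairs(path, known_gene_ids=None, cds_map=None, aligner=None):
    """Read a PGDD-style TSV of segmental duplication pairs.

    Requires columns ``gene_a`` and ``gene_b``; optional ``ka``/``ks`` are
    taken from the file unless ``cds_map`` allows recomputation. Rows naming
    genes outside ``known_gene_ids`` (when given) are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty and list(df.columns) == []:
        return []
    missing = {"gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pairs = []
    for _, row in df.iterrows():
        ga, gb = str(row["gene_a"]), str(row["gene_b"])
        if known_gene_ids is not None and (ga not in known_gene_ids
                                           or gb not in known_gene_ids):
            warnings.warn(f"segmental pair {ga}/{gb}: unknown gene id; row skipped")
            continue
        ka = float(row["ka"]) if "ka" in df.columns and pd.notna(row.get("ka")) else None
        ks = float(row["ks"]) if "ks" in df.columns and pd.notna(row.get("ks")) else None
        omega = ka / ks if (ka is not None and ks is not None and ks > 0) else None
        pairs.append(DuplicatePair(
            gene_a=ga, gene_b=gb, dup_type="segmental",
            ka=ka, ks=ks, omega=omega,
            selection=classify_selection(omega),
        ))
    if cds_map is not None:
        pairs = compute_pair_kaks(pairs, cds_map, aligner=aligner)
    return pairs


def pairs_table(pairs) -> pd.DataFrame:
    """Duplicate pairs as a tidy DataFrame (Ka/Ks report)."""
    rows = []
    for p in pairs:
        rows.append({
            "gene_a": p.gene_a, "gene_b": p.gene_b, "dup_type": p.dup_type,
            "identity_pct": p.protein_identity_pct,
            "intervening_genes": p.intervening_genes, "span_bp": p.span_bp,
            "Ka": p.ka, "Ks": p.ks, "omega": p.omega, "selection": p.selection,
        })
    return pd.DataFrame(rows, columns=[
        "gene_a", "gene_b", "dup_type", "identity_pct", "intervening_genes",
        "span_bp", "Ka", "Ks", "omega", "selection"])
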