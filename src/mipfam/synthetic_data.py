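"""Ground-truth generators for every pipeline stage.

Everything is a pure function of its parameters and seed: regenerating with
the same arguments is bit-identical. The generators emulate the statistical
structure the survey assumes — aquaporin-like proteins with six hydrophobic
TM helices, two NPA boxes and subfamily ar/R tetrads; codon pairs evolved
under a planted Ka/Ks ratio; annotated chromosomes carrying tandem arrays
(and near-miss negatives violating exactly one clause of the tandem rule);
FPKM matrices with tissue and salt-time-course patterns; replicated Ct
tables — while remaining far simpler than real genomes (no indel evolution,
no read-level noise, uniform mutation models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .duplication_kaks import SENSE_CODONS, STOP_CODONS, _FORWARD, _syn_sites
from .motif_profile import (MotifProfile, NPASlot, ReferenceTemplate,
                            assign_arR_group)
from .seqio import ExpressionMatrix, GeneModel, SequenceRecord
from .templates import (HYDROPHOBIC, annotated_columns, build_default_templates)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC_SET = sorted(set(HYDROPHOBIC))

_CODONS_FOR_AA: dict = {}
for codon, aa in _FORWARD.items():
    _CODONS_FOR_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[aa].sort()


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a full synthetic survey cohort."""

    seed: int = 0
    n_genes: int = 40
    subfamily_mix: dict = field(default_factory=lambda: {
        "PIP": 0.45, "TIP": 0.22, "NIP": 0.17, "SIP": 0.09, "XIP": 0.07})
    divergence_pct: float = 15.0
    tandem_arrays: tuple = (("Chr01", 3, 5000, 0), ("Chr02", 2, 8000, 1))
    omega_targets: tuple = (0.3,)
    expression_patterns: dict = field(default_factory=lambda: {
        "high_all": 0.25, "tissue_specific": 0.35, "low_all": 0.15,
        "induced": 0.15, "repressed": 0.10})
    noise_cv: float = 0.2

    def __post_init__(self):
        for name, mix in (("subfamily_mix", self.subfamily_mix),
                          ("expression_patterns", self.expression_patterns)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")


# ---------------------------------------------------------------------------
# Proteins


def _mutate(seq: list, positions, rng, tm_mask=None):
    for pos in positions:
        cur = seq[pos]
        if tm_mask is not None and tm_mask[pos] and cur in _HYDROPHOBIC_SET:
            alphabet = [a for a in _HYDROPHOBIC_SET if a != cur]
        else:
            alphabet = [a for a in AA20 if a != cur]
        seq[pos] = alphabet[int(rng.integers(len(alphabet)))]


def _truth_profile(record_id: str, seq: str, template: ReferenceTemplate) -> MotifProfile:
    def slot(pos):
        trip = seq[pos - 1:pos + 2]
        return NPASlot(position=pos, triplet=trip, canonical=trip == "NPA")

    arR = {k: seq[c - 1] for k, c in template.arR.items()}
    froger = {k: seq[c - 1] for k, c in template.froger.items()}
    return MotifProfile(
        query_id=record_id,
        tm_segments=tuple(template.tm),
        npa1=slot(template.npa1),
        npa2=slot(template.npa2),
        arR=arR,
        froger=froger,
        group=assign_arR_group(arR, subfamily=template.subfamily),
        template_subfamily=template.subfamily,
    )


def make_protein(subfamily: str, divergence_pct: float, seed: int,
                 record_id: str | None = None, exact: bool = False,
                 perturb: dict | None = None):
    """An aquaporin-like protein diverged from its subfamily template.

    Background positions mutate at ``divergence_pct`` (Bernoulli per
    position, or exactly that fraction with ``exact=True``); the annotated
    NPA/ar-R/Froger columns stay untouched unless explicitly overridden via
    ``perturb`` (1-based position -> residue). TM positions mutate within the
    hydrophobic alphabet so the planted helices survive. Returns the record
    and its ground-truth motif profile.
    """
    if divergence_pct > 60:
        raise ValueError("divergence above 60% makes the identity ladder meaningless")
    template = build_default_templates()[subfamily]
    rng = np.random.default_rng(seed)
    seq = list(template.sequence)
    protected = annotated_columns(template)
    background = [i for i in range(len(seq)) if (i + 1) not in protected]
    tm_mask = [False] * len(seq)
    for s, e in template.tm:
        for i in range(s - 1, e):
            tm_mask[i] = True
    if exact:
        k = int(round(divergence_pct / 100.0 * len(background)))
        positions = rng.choice(background, size=k, replace=False)
    else:
        mask = rng.random(len(background)) < divergence_pct / 100.0
        positions = [b for b, m in zip(background, mask) if m]
    _mutate(seq, positions, rng, tm_mask=tm_mask)
    if perturb:
        for pos, residue in perturb.items():
            seq[pos - 1] = residue
    rid = record_id or f"{subfamily}_synth_{seed}"
    sequence = "".join(seq)
    return SequenceRecord(rid, sequence), _truth_profile(rid, sequence, template)


def make_diverged_copy(record: SequenceRecord, n_mutations: int, seed: int,
                       record_id: str, protected=()):
    """Copy of a protein with exactly ``n_mutations`` substitutions outside
    the ``protected`` (1-based) positions; identity to the source is exactly
    (L - n) / L when the alignment stays gapless."""
    rng = np.random.default_rng(seed)
    seq = list(record.sequence)
    allowed = [i for i in range(len(seq)) if (i + 1) not in set(protected)]
    if n_mutations > len(allowed):
        raise ValueError("more mutations requested than mutable positions")
    positions = rng.choice(allowed, size=n_mutations, replace=False)
    _mutate(seq, positions, rng)
    return SequenceRecord(record_id, "".join(seq))


_REFSET_NAMES = {
    "PIP": ["PIP1;1", "PIP1;2", "PIP1;3", "PIP1;4", "PIP1;5",
            "PIP2;1", "PIP2;2", "PIP2;3", "PIP2;4", "PIP2;5",
            "PIP2;6", "PIP2;7", "PIP2;8"],
    "TIP": ["TIP1;1", "TIP1;2", "TIP1;3", "TIP2;1", "TIP2;2",
            "TIP2;3", "TIP3;1", "TIP3;2", "TIP4;1", "TIP5;1"],
    "NIP": ["NIP1;1", "NIP1;2", "NIP2;1", "NIP3;1", "NIP4;1",
            "NIP4;2", "NIP5;1", "NIP6;1", "NIP7;1"],
    "SIP": ["SIP1;1", "SIP1;2", "SIP2;1"],
}


def make_refset(seed: int = 2024, divergence_pct: float = 8.0,
                prefix: str = "At", include_xip: bool = False):
    """A synthetic 35-member reference aquaporin set mirroring the canonical
    Arabidopsis family structure (13 PIP / 10 TIP / 9 NIP / 3 SIP), each
    member lightly diverged from its subfamily template.

    Arabidopsis itself lacks XIPs; ``include_xip`` appends three
    poplar-style XIP references so XIP queries can be screened and named.
    """
    refs = []
    i = 0
    for subfamily, names in _REFSET_NAMES.items():
        for name in names:
            rec, _ = make_protein(subfamily, divergence_pct, seed + i,
                                  record_id=prefix + name)
            refs.append(rec)
            i += 1
    if include_xip:
        for name in ("XIP1;1", "XIP2;1", "XIP2;2"):
            rec, _ = make_protein("XIP", divergence_pct, seed + i,
                                  record_id="Pt" + name)
            refs.append(rec)
            i += 1
    return refs


def make_background_protein(length: int, seed: int, record_id: str) -> SequenceRecord:
    """An unrelated random protein (screened out by the identity floor)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AA20), size=length))
    return SequenceRecord(record_id, seq)


def reverse_translate(protein: SequenceRecord, seed: int,
                      record_id: str | None = None) -> SequenceRecord:
    """A CDS for a protein with synonymous codons drawn uniformly."""
    rng = np.random.default_rng(seed)
    codons = [
        _CODONS_FOR_AA[aa][int(rng.integers(len(_CODONS_FOR_AA[aa])))]
        if aa != "X" else "NNN"
        for aa in protein.sequence
    ]
    return SequenceRecord(record_id or protein.id, "".join(codons), moltype="dna")


def derive_cds(source_cds: SequenceRecord, target_protein: SequenceRecord,
               seed: int, syn_rate: float = 0.05,
               record_id: str | None = None) -> SequenceRecord:
    """A CDS for a duplicate copy, inherited codon-by-codon from the source.

    Codons whose amino acid is unchanged are kept (substituted by a random
    synonymous alternative at ``syn_rate``); changed positions draw a random
    codon for the new residue. Keeps synonymous sites correlated between
    duplicates so Ka/Ks is well defined.
    """
    rng = np.random.default_rng(seed)
    src = source_cds.sequence
    codons = []
    for i, aa in enumerate(target_protein.sequence):
        codon = src[3 * i:3 * i + 3]
        if aa == "X":
            codons.append("NNN")
            continue
        choices = _CODONS_FOR_AA[aa]
        if len(codon) == 3 and _FORWARD.get(codon) == aa:
            if len(choices) > 1 and rng.random() < syn_rate:
                alts = [c for c in choices if c != codon]
                codon = alts[int(rng.integers(len(alts)))]
        else:
            codon = choices[int(rng.integers(len(choices)))]
        codons.append(codon)
    return SequenceRecord(record_id or target_protein.id, "".join(codons),
                          moltype="dna")


# ---------------------------------------------------------------------------
# Codon pairs under a planted omega


def make_cds_pair(n_codons: int, omega: float, ks_target: float, seed: int,
                  id_a: str = "cds_a", id_b: str = "cds_b"):
    """A CDS pair evolved from a common ancestor under a planted Ka/Ks.

    One copy keeps the ancestor; the other accrues point substitutions
    (uniform over non-stop single-nucleotide neighbors) with nonsynonymous
    acceptance scaled by ``omega`` relative to synonymous, until the realized
    synonymous substitution count reaches approximately ``ks_target`` x the
    ancestor's synonymous site count. Returns (cds_a, cds_b, truth) with the
    realized substitution counts in ``truth``.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
                for _ in range(n_codons)]
    S = sum(_syn_sites(c) for c in ancestor)
    target_syn = int(round(ks_target * S))
    if target_syn < 1 or ks_target > 2.0:
        raise ValueError(
            f"ks_target {ks_target} unreachable at {n_codons} codons")

    p_syn = min(1.0, 1.0 / omega)
    p_nonsyn = min(1.0, omega)
    derived = list(ancestor)
    syn_subs = nonsyn_subs = 0
    attempts = 0
    max_attempts = 2000 * target_syn + 10000
    while syn_subs < target_syn:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("substitution target unreachable; ks_target too high")
        idx = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        base = "ACGT"[int(rng.integers(4))]
        codon = derived[idx]
        if base == codon[pos]:
            continue
        candidate = codon[:pos] + base + codon[pos + 1:]
        if candidate in STOP_CODONS:
            continue
        synonymous = _FORWARD[candidate] == _FORWARD[codon]
        accept_p = p_syn if synonymous else p_nonsyn
        if rng.random() >= accept_p:
            continue
        derived[idx] = candidate
        if synonymous:
            syn_subs += 1
        else:
            nonsyn_subs += 1
    truth = {
        "omega_planted": omega,
        "ks_target": ks_target,
        "syn_substitutions": syn_subs,
        "nonsyn_substitutions": nonsyn_subs,
        "syn_sites_ancestor": S,
    }
    return (SequenceRecord(id_a, "".join(ancestor), moltype="dna"),
            SequenceRecord(id_b, "".join(derived), moltype="dna"),
            truth)


# ---------------------------------------------------------------------------
# Annotated chromosomes with tandem arrays

_INTRON_COUNTS = {"PIP": 3, "TIP": 2, "NIP": 4, "SIP": 2, "XIP": 2}
_INTRON_LEN = 150


def _gene_model(gene_id: str, chrom: str, start: int, coding_len: int,
                n_introns: int, strand: str = "+") -> GeneModel:
    n_exons = n_introns + 1
    base = coding_len // n_exons
    sizes = [base] * n_exons
    sizes[-1] += coding_len - base * n_exons
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + size - 1))
        pos += size
        if i < n_introns:
            pos += _INTRON_LEN
    return GeneModel(gene_id=gene_id, chrom=chrom, start=start,
                     end=exons[-1][1], strand=strand, exons=tuple(exons),
                     transcript_id=f"{gene_id}.1")


@dataclass
class AnnotationTruth:
    models: list
    proteins: dict           # gene id -> protein SequenceRecord (AQP-like only)
    cds: dict                # gene id -> CDS SequenceRecord
    subfamily: dict          # gene id -> planted subfamily
    tandem_pairs: set        # frozensets {a, b} expected tandem
    negative_pairs: dict     # frozenset {a, b} -> violated clause


def make_annotation(arrays=None, negatives=("span", "intervening", "identity"),
                    n_background: int = 12, seed: int = 0,
                    copy_divergence_pct: float = 5.0) -> AnnotationTruth:
    """Synthetic chromosomes with planted tandem arrays and near-misses.

    ``arrays`` lists (chrom, subfamily, n_copies, spacing_bp,
    intervening_genes) positive arrays whose every within-array pair
    satisfies the tandem rule; each entry of ``negatives`` plants one decoy
    pair violating exactly that clause (span, intervening count, or protein
    identity). Background genes carry unrelated proteins.
    """
    if arrays is None:
        arrays = (("Chr01", "PIP", 3, 5000, 0), ("Chr02", "TIP", 2, 8000, 1))
    rng = np.random.default_rng(seed)
    models, proteins, cds, subfam = [], {}, {}, {}
    tandem_truth, negative_pairs = set(), {}
    counter = {"aqp": 0, "bg": 0}

    def add_background(chrom, cursor):
        counter["bg"] += 1
        gid = f"BG{counter['bg']:04d}"
        model = _gene_model(gid, chrom, cursor, coding_len=rng.integers(600, 1200),
                            n_introns=int(rng.integers(0, 3)))
        models.append(model)
        return model.end + int(rng.integers(2000, 6000))

    def add_aqp(chrom, cursor, subfamily, source=None, divergence=None):
        counter["aqp"] += 1
        gid = f"AQP{counter['aqp']:04d}"
        if source is None:
            prot, _ = make_protein(subfamily, 12.0, seed * 1000 + counter["aqp"],
                                   record_id=gid)
            cds_rec = reverse_translate(prot, seed * 2000 + counter["aqp"], gid)
        else:
            n_mut = int(round((divergence or copy_divergence_pct) / 100.0
                              * len(source.sequence)))
            protected = annotated_columns(build_default_templates()[subfamily])
            prot = make_diverged_copy(source, n_mut, seed * 1000 + counter["aqp"],
                                      gid, protected=protected)
            cds_rec = derive_cds(cds[source.id], prot,
                                 seed * 2000 + counter["aqp"], record_id=gid)
        proteins[gid] = prot
        cds[gid] = cds_rec
        subfam[gid] = subfamily
        model = _gene_model(gid, chrom, cursor, coding_len=3 * len(prot.sequence),
                            n_introns=_INTRON_COUNTS[subfamily])
        models.append(model)
        return model, prot

    def build_array(chrom, cursor, subfamily, n_copies, spacing, intervening,
                    record_truth=True, copy_div=None):
        first, source = add_aqp(chrom, cursor, subfamily)
        member_models = [first]
        cursor = first.end + spacing
        for _ in range(1, n_copies):
            for _k in range(intervening):
                cursor = add_background(chrom, cursor)
            model, _ = add_aqp(chrom, cursor, subfamily, source=source,
                               divergence=copy_div)
            member_models.append(model)
            cursor = model.end + spacing
        if record_truth:
            ids = [m.gene_id for m in member_models]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    tandem_truth.add(frozenset((ids[i], ids[j])))
        return member_models, cursor

    chrom_cursor: dict = {}
    for chrom, subfamily, n_copies, spacing, intervening in arrays:
        cursor = chrom_cursor.get(chrom, 1000)
        _, cursor = build_array(chrom, cursor, subfamily, n_copies, spacing,
                                intervening)
        chrom_cursor[chrom] = cursor + 30000

    # decoy pairs, each violating exactly one clause
    neg_chrom = "Chr09"
    cursor = 1000
    for kind in negatives:
        if kind == "span":
            a, _ = add_aqp(neg_chrom, cursor, "PIP")
            b, _ = add_aqp(neg_chrom, a.end + 150000, "PIP",
                           source=proteins[a.gene_id])
        elif kind == "intervening":
            a, _ = add_aqp(neg_chrom, cursor, "NIP")
            c = a.end + 2000
            for _k in range(6):
                c = add_background(neg_chrom, c) - int(rng.integers(0, 1500))
            b, _ = add_aqp(neg_chrom, c, "NIP", source=proteins[a.gene_id])
        elif kind == "identity":
            a, _ = add_aqp(neg_chrom, cursor, "TIP")
            b, _ = add_aqp(neg_chrom, a.end + 5000, "TIP",
                           source=proteins[a.gene_id], divergence=45.0)
        else:
            raise ValueError(f"unknown negative kind {kind!r}")
        negative_pairs[frozenset((a.gene_id, b.gene_id))] = kind
        cursor = b.end + 120000

    # scattered singleton AQPs and background genes
    for i in range(n_background):
        chrom = f"Chr{3 + i % 4:02d}"
        cursor = chrom_cursor.get(chrom, 1000)
        if i % 3 == 0:
            subfamily = ("NIP", "SIP", "XIP", "TIP")[i % 4]
            model, _ = add_aqp(chrom, cursor, subfamily)
            cursor = model.end + int(rng.integers(40000, 80000))
        else:
            cursor = add_background(chrom, cursor)
        chrom_cursor[chrom] = cursor

    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return AnnotationTruth(models=models, proteins=proteins, cds=cds,
                           subfamily=subfam, tandem_pairs=tandem_truth,
                           negative_pairs=negative_pairs)


def make_random_chromosome(n_genes: int, seed: int, chrom: str = "ChrR",
                           n_families: int = 6):
    """A random annotated chromosome for oracle equivalence testing.

    Genes come from a handful of protein families at varying divergence plus
    unrelated singletons, with random intergenic gaps straddling the span,
    intervening-count and identity clauses of the tandem rule. Every gene
    carries a protein. Returns (models, proteins).
    """
    rng = np.random.default_rng(seed)
    subfams = ("PIP", "TIP", "NIP", "SIP", "XIP")
    founders = []
    for f in range(n_families):
        prot, _ = make_protein(subfams[f % len(subfams)], 10.0,
                               seed * 97 + f, record_id=f"fam{f}")
        founders.append(prot)
    models, proteins = [], {}
    cursor = 1000
    for g in range(n_genes):
        gid = f"R{seed}G{g:03d}"
        choice = rng.random()
        if choice < 0.55:
            source = founders[int(rng.integers(n_families))]
            n_mut = int(rng.integers(0, int(0.5 * len(source.sequence))))
            prot = make_diverged_copy(source, n_mut, seed * 131 + g, gid)
        else:
            prot = make_background_protein(int(rng.integers(180, 260)),
                                           seed * 151 + g, gid)
        proteins[gid] = prot
        model = _gene_model(gid, chrom, cursor, coding_len=3 * len(prot.sequence),
                            n_introns=int(rng.integers(0, 4)))
        models.append(model)
        # gaps spanning well below and above the 100 kb rule
        gap = int(rng.choice([1500, 4000, 12000, 30000, 60000, 120000],
                             p=[0.3, 0.25, 0.2, 0.1, 0.1, 0.05]))
        cursor = model.end + gap
    return models, proteins


# ---------------------------------------------------------------------------
# Expression matrices and Ct tables

_DEFAULT_TISSUES = ("root", "leaf", "ovule0", "ovule3", "ovule10", "ovule20",
                    "ovule30", "ovule40", "fiber10", "fiber20")


def _lognormal_noise(rng, base, cv):
    if cv <= 0:
        return float(base)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(base * rng.lognormal(-0.5 * sigma * sigma, sigma))


def make_tissue_matrix(class_counts: dict | None = None, seed: int = 0,
                       tissues=_DEFAULT_TISSUES, noise_cv: float = 0.2):
    """Raw FPKM tissue panel with planted expression classes.

    ``class_counts`` maps high_all_tissues / tissue_specific / low_all to
    gene counts. Returns (ExpressionMatrix, truth dict gene -> class).
    """
    if class_counts is None:
        class_counts = {"high_all_tissues": 8, "tissue_specific": 12, "low_all": 6}
    rng = np.random.default_rng(seed)
    n_samples = len(tissues)
    breadth_cap = math.ceil(0.3 * n_samples)
    rows, truth = {}, {}
    g = 0
    for cls, count in class_counts.items():
        for _ in range(count):
            g += 1
            gid = f"EXP{g:04d}"
            if cls == "high_all_tissues":
                base = np.full(n_samples, float(rng.uniform(30, 150)))
            elif cls == "low_all":
                base = np.full(n_samples, float(rng.uniform(0.2, 2.0)))
            elif cls == "tissue_specific":
                base = np.full(n_samples, float(rng.uniform(0.1, 1.0)))
                k = int(rng.integers(1, breadth_cap + 1))
                hot = rng.choice(n_samples, size=k, replace=False)
                base[hot] = rng.uniform(40, 120, size=k)
            else:
                raise ValueError(f"unknown expression class {cls!r}")
            rows[gid] = [_lognormal_noise(rng, b, noise_cv) for b in base]
            truth[gid] = cls
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(tissues))
    df.index.name = "gene"
    return ExpressionMatrix(values=df), truth


def make_coexpression_blocks(n_per_block: int = 8, n_samples: int = 8,
                             seed: int = 0, noise_cv: float = 0.1):
    """Two anti-correlated co-expression blocks for clustering recovery."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_samples)
    pattern_a = 20 + 80 * t
    pattern_b = 100 - 80 * t
    rows, truth = {}, {}
    for i in range(n_per_block):
        gid = f"BLKA{i:02d}"
        rows[gid] = [_lognormal_noise(rng, b, noise_cv) for b in pattern_a]
        truth[gid] = "A"
    for i in range(n_per_block):
        gid = f"BLKB{i:02d}"
        rows[gid] = [_lognormal_noise(rng, b, noise_cv) for b in pattern_b]
        truth[gid] = "B"
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"s{j}" for j in range(n_samples)])
    df.index.name = "gene"
    return ExpressionMatrix(values=df), truth


def make_salt_timecourse(patterns: dict | None = None,
                         timepoints=(12.0, 24.0, 48.0), seed: int = 0,
                         fold: float = 8.0, base_fpkm: float = 20.0,
                         noise_cv: float = 0.1):
    """Treated/control FPKM time courses with planted response classes.

    ``patterns`` maps gene id -> ("induced"|"repressed"|"unchanged"|
    "low_expression", peak_time). Returns (treated ExpressionMatrix, control
    ExpressionMatrix, truth DataFrame).
    """
    if patterns is None:
        patterns = {"G_ind": ("induced", 24.0), "G_rep": ("repressed", 24.0),
                    "G_flat": ("unchanged", None), "G_low": ("low_expression", None)}
    rng = np.random.default_rng(seed)
    timepoints = tuple(float(t) for t in timepoints)
    treated_rows, control_rows, truth_rows = {}, {}, []
    for gid, (direction, peak) in patterns.items():
        control = np.full(len(timepoints), base_fpkm)
        treated = control.copy()
        if direction == "induced":
            # triangular ramp peaking at the planted time, so trends toward
            # and away from the peak are monotone
            span = max(timepoints) - min(timepoints)
            w = np.array([max(0.0, 1.0 - abs(t - peak) / span)
                          for t in timepoints])
            treated = control * (1.0 + (fold - 1.0) * w)
        elif direction == "repressed":
            ti = timepoints.index(peak)
            treated = control * 0.9
            treated[ti] = control[ti] / fold
            peak = None  # remaining treated values are ties up to noise
        elif direction == "low_expression":
            control = np.full(len(timepoints), 0.5)
            treated = np.full(len(timepoints), 0.8)
            peak = None
        elif direction == "unchanged":
            peak = None
        else:
            raise ValueError(f"unknown direction {direction!r}")
        treated_rows[gid] = [_lognormal_noise(rng, v, noise_cv) for v in treated]
        control_rows[gid] = [_lognormal_noise(rng, v, noise_cv) for v in control]
        truth_rows.append({"gene": gid, "direction": direction, "peak_time": peak})
    cols = [f"t{t:g}" for t in timepoints]
    treated_df = pd.DataFrame.from_dict(treated_rows, orient="index", columns=cols)
    control_df = pd.DataFrame.from_dict(control_rows, orient="index", columns=cols)
    treated_df.index.name = control_df.index.name = "gene"
    return (ExpressionMatrix(values=treated_df),
            ExpressionMatrix(values=control_df),
            pd.DataFrame(truth_rows))


def make_ct_table(fold_truth: dict | None = None, seed: int = 0,
                  replicates: int = 3, ct_sd: float = 0.15,
                  ref_ct: float = 20.0, base_target_ct: float = 26.0):
    """Replicated Ct records with planted fold changes (treated vs control).

    Returns (records, truth dict gene -> fold). Fold f is planted as a
    -log2(f) shift of the treated target Ct; normal noise (sd ``ct_sd``
    cycles) on every measured Ct.
    """
    if fold_truth is None:
        fold_truth = {"Q1": 4.0, "Q2": 0.5, "Q3": 1.0}
    from .qpcr import QPCRRecord

    rng = np.random.default_rng(seed)
    records = []
    for gene, fold in fold_truth.items():
        for condition, sample in (("control", "control"), ("treated", "treated")):
            shift = 0.0 if condition == "control" else -math.log2(fold)
            for rep in range(1, replicates + 1):
                records.append(QPCRRecord(
                    gene_id=gene, sample_id=sample, condition=condition,
                    replicate=rep,
                    ct_target=base_target_ct + shift + float(rng.normal(0, ct_sd)),
                    ct_reference=ref_ct + float(rng.normal(0, ct_sd)),
                ))
    return records, dict(fold_truth)


# ---------------------------------------------------------------------------
# Phylogeny inputs


def make_random_additive_tree(n_taxa: int, seed: int):
    """A random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix. Returns (tree, DistanceMatrix)."""
    from .phylogeny import TreeNode, tree_path_distances

    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"T{i + 1:02d}") for i in range(n_taxa)]
    for node in nodes:
        node.branch_length = float(rng.uniform(0.05, 0.5))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]],
                          branch_length=float(rng.uniform(0.05, 0.5)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return root, tree_path_distances(root)


def make_clade_msa(clades: dict | None = None, length: int = 300, seed: int = 0,
                   within_divergence: float = 0.05,
                   between_divergence: float = 0.5):
    """An alignment with planted clades (no indels).

    ``clades`` maps clade name -> number of leaves. Each clade ancestor
    diverges from a shared root sequence by ``between_divergence``; leaves
    diverge from their clade ancestor by ``within_divergence``. Returns
    (records, groups dict clade name -> leaf ids).
    """
    if clades is None:
        clades = {"A": 4, "B": 4}
    rng = np.random.default_rng(seed)

    def mutate(seq, rate):
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < rate:
                out[i] = AA20[int(rng.integers(20))]
        return "".join(out)

    root = "".join(rng.choice(list(AA20), size=length))
    records, groups = [], {}
    for name, count in clades.items():
        ancestor = mutate(root, between_divergence)
        ids = []
        for i in range(count):
            lid = f"{name}{i + 1}"
            records.append(SequenceRecord(lid, mutate(ancestor, within_divergence)))
            ids.append(lid)
        groups[name] = ids
    return records, groups
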