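"""Readers and writers for the external formats the survey pipeline touches.

Sequence data (protein and CDS FASTA), gene annotation (GFF3), expression
matrices (TSV, samples as columns), Newick trees with bootstrap supports, and
TSV/JSON report tables. All coordinates are GFF3-style: 1-based, inclusive.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_LETTERS = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named protein or nucleotide sequence.

    Protein sequences may contain the 20 standard residues plus ``X``;
    DNA sequences ``ACGT`` plus ``N``. Sequences are stored uppercased.
    """

    id: str
    sequence: str
    moltype: str = "protein"
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        if self.moltype not in ("protein", "dna"):
            raise FormatError(f"unknown moltype {self.moltype!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        alphabet = PROTEIN_LETTERS if self.moltype == "protein" else DNA_LETTERS
        for i, ch in enumerate(self.sequence):
            if ch not in alphabet:
                raise FormatError(
                    f"illegal {self.moltype} character {ch!r} at position "
                    f"{i + 1} in record {self.id!r}"
                )

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its representative transcript's exon structure.

    Coordinates are 1-based inclusive. Exons are kept sorted by start and must
    be non-overlapping and contained in ``[start, end]``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = ()
    transcript_id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in exons:
            if s > e:
                raise FormatError(f"gene {self.gene_id}: exon {s}-{e} reversed")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon {s}-{e} outside gene bounds"
                )
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def exon_span(self) -> int:
        """Total exonic length in bp."""
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values (FPKM).

    ``normalized`` flags whether values have been log2(FPKM+1) transformed.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in expression matrix")
        if self.values.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        if (self.values.values < 0).any():
            raise FormatError("expression matrix contains negative values")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, moltype: str = "protein") -> list:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; sequences are uppercased. Duplicate ids and illegal
    characters raise :class:`FormatError`.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(rec.id, str(rec.seq), moltype=moltype, description=desc)
        )
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _validate_gff3_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if end < start:
                raise FormatError(
                    f"{path}: line {lineno}: end {end} < start {start}"
                )


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def read_gff3(path) -> list:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    The representative transcript is the one with the longest summed exon
    length (ties broken by lexicographically smallest transcript id). Parsing
    is insensitive to feature-line order. Exons whose Parent cannot be
    resolved raise :class:`FormatError`.
    """
    import gffutils

    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    known_parents = {}
    for ftype in _TRANSCRIPT_TYPES | {"gene"}:
        for feat in db.features_of_type(ftype):
            known_parents[feat.id] = feat

    # exon lists per transcript id
    tx_exons = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent")
        if not parents:
            raise FormatError(f"exon at {exon.seqid}:{exon.start} has no Parent")
        for pid in parents:
            if pid not in known_parents:
                raise FormatError(
                    f"exon at {exon.seqid}:{exon.start}-{exon.end} has "
                    f"unresolvable Parent {pid!r}"
                )
            tx_exons.setdefault(pid, []).append((exon.start, exon.end))

    models = []
    for gene in db.features_of_type("gene"):
        candidates = []
        for tx in db.children(gene, featuretype=tuple(_TRANSCRIPT_TYPES), level=1):
            exons = tx_exons.get(tx.id)
            if exons:
                candidates.append((tx.id, exons))
        if not candidates and gene.id in tx_exons:
            # exons attached directly to the gene feature
            candidates.append((gene.id, tx_exons[gene.id]))
        if not candidates:
            raise FormatError(f"gene {gene.id} has no transcript with exons")
        candidates.sort(
            key=lambda c: (-sum(e - s + 1 for s, e in c[1]), c[0])
        )
        tx_id, exons = candidates[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(sorted(exons)),
                transcript_id=tx_id,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def write_gff3(models, path) -> None:
    """Write GeneModels as a minimal gene -> mRNA -> exon GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.chrom}\tmipfam\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            tid = m.transcript_id or f"{m.gene_id}.1"
            fh.write(
                f"{m.chrom}\tmipfam\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tmipfam\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_matrix(path, normalized: bool = False) -> ExpressionMatrix:
    """Read a TSV with a header row of sample ids and gene ids in column 1."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for lineno, line in enumerate(fh, 2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != ncol:
                raise FormatError(f"{path}: line {lineno}: ragged row")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), normalized=normalized)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree, path=None, include_support: bool = True) -> str:
    """Serialize a :class:`mipfam.phylogeny.TreeNode` to Newick text.

    Branch lengths are always written; integer bootstrap supports become
    internal node labels. Returns the Newick string; writes it if ``path``
    is given.
    """
    text = tree.to_newick(include_support=include_support)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_newick(source):
    """Parse Newick text (or a file path) into a ``TreeNode``."""
    from .phylogeny import TreeNode

    if os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode):
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            node = TreeNode(name=name)
        else:
            node = TreeNode(children=[convert(c) for c in dnode.child_nodes()])
            if dnode.label is not None:
                try:
                    node.support = int(round(float(dnode.label)))
                except ValueError:
                    node.name = dnode.label
        if dnode.edge.length is not None:
            node.branch_length = float(dnode.edge.length)
        return node

    return convert(dtree.seed_node)


# ---------------------------------------------------------------------------
# Reports


def write_report(tables: dict, outdir, basename: str = "report") -> dict:
    """Write a dict of DataFrames as TSV files plus one combined JSON.

    Returns a mapping table-name -> written TSV path. The JSON mirrors every
    table as records, so downstream tools can consume either form.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    combined = {}
    for name, df in tables.items():
        path = os.path.join(outdir, f"{basename}.{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
        combined[name] = json.loads(df.to_json(orient="records"))
    json_path = os.path.join(outdir, f"{basename}.json")
    with open(json_path, "w") as fh:
        json.dump(combined, fh, indent=2, sort_keys=True)
    paths["__json__"] = json_path
    return paths
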