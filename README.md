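# mipfam

A Python toolkit for genome-wide surveys of plant aquaporin (MIP) gene
families: candidate identification and nomenclature, structural motif
profiling, gene-structure and duplication/selection analysis, neighbor-joining
phylogenetics, and expression/stress-response analysis. It is written for
researchers characterizing an aquaporin family in a newly sequenced plant
genome, and for anyone who wants the full analysis chain to be reproducible,
testable code rather than a pile of web-tool screenshots.

## What it computes

Aquaporins are channel proteins with a strongly conserved architecture: six
transmembrane helices, two Asn-Pro-Ala (NPA) boxes in loops B and E, and an
aromatic/arginine (ar/R) selectivity filter read at four positions
(H2, H5, LE1, LE2). Plant families split into the PIP, TIP, NIP, SIP and XIP
subfamilies. `mipfam` implements the standard survey over this biology:

- **Screening & nomenclature** (`family_classify`): every proteome entry is
  globally aligned (BLOSUM62, affine gaps) against a reference aquaporin set.
  An entry is retained when its best hit has identity ≥ 30% and query
  coverage > 50%; best identity > 40% makes it an AQP family member, > 60%
  additionally inherits the reference's subfamily, < 40% flags a candidate
  new family. Paralogs sharing a best ortholog are tagged `a, b, c, …` by
  chromosomal position (`PIP1;4a` … `PIP1;4j`).
- **Motif profiling** (`motif_profile`): Kyte–Doolittle hydropathy TM
  prediction plus template-anchored mapping of NPA boxes, the ar/R tetrad and
  Froger's P1–P5, with a nine-group ar/R classification (PIP; TIP-I/IIa/IIb/III;
  NIP-I/II; SIP-I/II; XIP).
- **Gene structure** (`gene_structure`): intron counts from representative
  transcripts and subfamily × intron-count tables with modal counts.
- **Duplication & selection** (`duplication_kaks`): tandem pairs by the
  windowed rule — same chromosome, ≤ 5 intervening genes, boundary distance
  ≤ 100 kb, protein identity > 70% — plus Nei–Gojobori (1986) Ka/Ks:

  d = −(3/4)·ln(1 − 4p/3) applied to pₛ = Sd/S and pₙ = Nd/N,
  ω = Ka/Ks, with ω < 1 read as purifying selection.

- **Phylogeny** (`phylogeny`): p/Poisson distances with pairwise deletion,
  Saitou–Nei neighbor joining (exact on additive matrices), bootstrap
  supports from column resampling, midpoint rooting, monophyly checks.
- **Expression & qPCR** (`expression_stress`, `qpcr`): log2(FPKM+1)
  normalization, hierarchical clustering, tissue-class flags with the
  FPKM ≥ 5 expression floor, salt-time-course induction/repression/peak-time
  calls, peak-time bias between species, and Livak 2^−ΔΔCt quantification
  with one-way ANOVA.
- **Synthetic cohorts** (`synthetic_data`): deterministic generators planting
  ground truth for every stage — the basis of the test suite.
- **Orchestration** (`pipeline`, `cli`): a `survey` runner chaining all
  stages into per-gene report tables, plus a thin `mipfam` command-line
  wrapper (screen, motifs, structure, tandem, kaks, tree, expr, qpcr,
  simulate, survey).

External search tools (BLAST/HMMER), collinearity detection and read
quantification are out of scope: screening criteria are re-implemented over
exact alignment, segmental-duplication pairs and FPKM matrices are consumed
as inputs.

## Worked example

```bash
python examples/04_tandem_kaks.py
```

```
 gene_a  gene_b dup_type  identity_pct  intervening_genes  span_bp       Ka       Ks    omega selection
AQP0001 AQP0002   tandem     95.145631                  0     5000 0.033020 0.070669 0.467243 purifying
AQP0001 AQP0003   tandem     95.145631                  1    11067 0.040424 0.075612 0.534616 purifying
AQP0002 AQP0003   tandem     90.291262                  0     5000 0.075118 0.155594 0.482780 purifying
AQP0004 AQP0005   tandem     95.145631                  1    12609 0.037078 0.112520 0.329521 purifying

planted pairs recovered: True
decoy pairs (violating one rule clause each) excluded: 3 of 3
```

The generator planted a 3-copy PIP array and a 2-copy TIP array; the scan
recovers exactly those pairwise duplicates and rejects three decoys that each
violate one clause of the tandem rule. Every pair's ω is below 1 — the
duplicates evolved under purifying selection. The other scripts in
`examples/` walk through screening/naming, motif profiling, gene structure,
NJ trees with bootstrap, expression classification and qPCR the same way.

A full survey from files:

```bash
mipfam simulate --out cohort --seed 11
printf 'proteome=cohort/proteome.fasta\nrefs=cohort/refs.fasta\ngff=cohort/annotation.gff3\ncds=cohort/cds.fasta\n' > cohort/survey.cfg
mipfam survey --config cohort/survey.cfg
```

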