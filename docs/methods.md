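# Methods

This note documents the models and procedures implemented in `mipfam`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data generators do and do not emulate.

## Screening and the identity ladder

Candidate aquaporins are identified by exact pairwise global alignment
(Needleman–Wunsch) rather than by heuristic database search. The aligner uses
BLOSUM62 with affine gap penalties (open 10, extend 0.5 — classic `needle`
defaults), and penalizes terminal gaps like internal ones; all parameters are
configurable. Two derived statistics drive every decision:

- **identity** = identical columns / full alignment length (gap columns in
  the denominator; `X` never counts as a match). This definition is
  symmetric, order-independent and strict — a gapped alignment can only lower
  it.
- **query coverage** = query residues aligned opposite a reference residue /
  query length.

Retention requires best-hit identity ≥ 30% *and* coverage > 50%
(`min_identity`, `min_coverage`). The classical family ladder then applies to
the best hit: identity > 40% → AQP family member; > 60% → inherits the
reference's subfamily; below 40% → candidate new family. Both thresholds are
strict inequalities, and tests verify the calls as exact step functions of
measured identity. Ties for the best reference break by higher alignment
score, then lexicographic reference id, so screening is deterministic and
permutation-invariant.

Database-search statistics (E-values) are intentionally not modeled: they
depend on database size and tool internals, whereas identity/coverage are
reproducible from the sequences alone. Profile-domain confirmation
(MIP/PF00230 scans) is treated as an optional imported annotation, never
computed.

**Nomenclature.** Queries sharing a best-reference ortholog group (e.g.
`PIP1;4`) are suffixed `a, b, c, …` ordered by (chromosome lexicographic,
start ascending); singletons keep the bare group name. More than ten paralogs
continue `k, l, …` with a warning.

## Motif profiling

TM helices are predicted from Kyte–Doolittle hydropathy smoothed with a
centered window (default 19 residues, truncated at the ends); maximal runs
with smoothed value ≥ 1.6 and length ≥ 15 are reported. These are standard
heuristics; all three values are parameters. Note that a 21-residue helix
flanked by strongly hydrophilic loops produces a run of almost exactly 15
positions under these defaults, i.e. it sits at the detection margin — real
helices (typically 19–25 hydrophobic residues) are detected robustly.

NPA boxes, the ar/R tetrad (H2, H5, LE1, LE2) and Froger's P1–P5 are resolved
by **reference-anchored mapping**: the query is globally aligned to an
annotated subfamily template, and each annotated template column is read off
the aligned query ('-' at gaps, so a single-NPA protein yields one
non-canonical slot rather than an error). This makes positional semantics
exact and testable without implementing multiple alignment. When the
subfamily is unknown, the query is scanned against all templates and the
best-scoring one wins. Alignments scoring below 20% of the template
self-score return an all-unresolved profile with a warning instead of
unreliable coordinates. A regex fallback (`N-P-x`) exists for template-less
use and is flagged lower-confidence.

The shipped templates are **synthetic**: deterministic, code-generated
sequences with the canonical architecture (six hydrophobic helices, two NPA
boxes, subfamily ar/R tetrads, a literature-style Froger pentad) rather than
real plant proteins. Cross-template identities are 19–28%, far below the
subfamily threshold, so template choice is unambiguous. Froger column
placement within loops C/E and the C-terminus is a package convention — the
positions are defined *by* the template annotation.

**ar/R groups.** An ordered rule table assigns the nine groups observed
across plant families: PIP (F|V, H, T, R); TIP-I (H,I,A,V); TIP-IIa
(H,I,G,R); TIP-IIb (H,I,A,R); TIP-III (N,V,·,·); NIP-I (W,V,A,R) or
(G,S,G,R); NIP-II (A|T, I|V, G|A, R); SIP-I (P|G|A, F|S|N, V|I|F, H|V);
SIP-II (S, H|N, G|P, A|S); XIP (I|V, I|T, V|R, R). At least three of four
positions must be resolved; unresolved positions match as wildcards; rules of
the stated subfamily are tried first. The SIP-I/SIP-II split is only loosely
fixed in the literature; the table above is this package's documented
reading. The function is total: anything unmatched is `unclassified`.

## Gene structure

Intron counts come from the representative transcript's exon features (UTR
exons included), where the representative is the transcript with the longest
summed exon length, ties broken by smallest transcript id. An intron between
exons (…, e) and (s, …) has length s − e − 1; coordinates are 1-based
inclusive throughout. The subfamily table reports counts and modal intron
numbers (ties to the smaller count).

## Tandem duplication and Ka/Ks

A pair is tandem when all three clauses hold: ≤ 5 annotated genes between the
two (counted strand-agnostically from the full annotation, not just family
members), nearest-boundary distance (`b.start − a.end`) ≤ 100 kb, and protein
global-alignment identity > 70% (the screening module's identity definition —
the similarity measure is protein-level, consistent with protein-based
screening). The windowed scan is validated against a brute-force all-pairs
filter on randomized chromosomes.

**NG86.** Ka/Ks follows Nei–Gojobori (1986) codon counting:

- Synonymous sites per codon: each position contributes the fraction of its
  three possible point mutations that preserve the amino acid; mutations into
  stop codons count as nonsynonymous. Site counts are averaged over both
  sequences.
- Observed differences per codon pair: averaged with equal weight over all
  minimal mutation paths; paths passing through stop codons are excluded
  (falling back to all paths if every path hits a stop). No
  transition/transversion weighting.
- Codons containing gaps, ambiguous bases (N/X) or stops are excluded from
  both site and difference counts.
- Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) on both proportions;
  p ≥ 3/4 makes the rate undefined (reported NA), as is ω when Ks = 0.

Unequal-length pairs are codon-aligned by back-threading a protein global
alignment onto the CDS. The estimator is symmetric in its arguments.
Selection calls: ω < 1 purifying, ω > 1 positive, within ±0.05 of 1 (the
configurable `neutral_band`) neutral.

Segmental/collinear duplication detection is not implemented; PGDD-style pair
lists are inputs, with Ka/Ks taken from the file or recomputed when CDS are
supplied.

## Phylogeny

Distances from an aligned FASTA use pairwise deletion of gap/ambiguous
columns; p-distance is the default (the Poisson transform −ln(1−p) is
available). Saitou–Nei NJ joins the pair minimizing
Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), with ties broken by the smallest
(i,j) index pair in the current matrix, and the standard branch-length
formulas; the final three nodes resolve as a star, giving the usual unrooted
tree with a trifurcating root. Negative length estimates are clamped to zero
and flagged on the node. On additive matrices the output reproduces the
generating topology and path lengths to machine precision (tested at 1e-9),
and the topology is cross-checked against an independent NJ implementation.

Bootstrap supports resample alignment columns with replacement; each internal
bipartition's support is the percentage of replicate NJ trees containing it,
reproducible under a fixed seed (the point-estimate topology is
seed-independent). "Rooted" presentation uses midpoint rooting — no outgroup
is assumed — and monophyly of a label group means its leaves form a clade on
the midpoint-rooted tree.

## Expression and qPCR

Normalization is log2(FPKM+1), refused on already-normalized matrices.
Clustering is agglomerative with average linkage on 1 − Pearson distances by
default (Euclidean available); zero-variance rows get the maximum correlation
distance (2.0) rather than NaN.

Tissue classes on raw FPKM with floor 5: `high_all_tissues` (every sample at
or above the floor), `low_all` (every sample below), `tissue_specific`
(expressed in at least one but at most ⌈30%⌉ of samples — the breadth cutoff
is a package convention, as published analyses draw these boxes visually),
otherwise `unflagged`.

Salt time courses: a gene whose treated and control series never reach the
floor is `low_expression`. Otherwise `induced` means some timepoint has
treated ≥ 2× the reference (paired control, or the t0 treated baseline when
no control exists) while above the floor; `repressed` is symmetric; if both
trigger, the larger log-ratio wins. "Induced" is not precisely defined in the
survey literature; the 2-fold-with-floor operationalization is recorded as a
parameter (`fold`, `fpkm_low`). Peak time is the argmax of the treated
series, earliest timepoint on ties (deliberately biased toward rapid
responders). Peak-time bias between species reports per-ortholog-pair
Δpeak = peak(B) − peak(A), the median Δpeak, and the count of pairs with
opposite early-phase trends over the first time interval; pairs with an
undefined peak are excluded but counted.

qPCR uses the Livak method with 100% amplification efficiency (base 2), as
the 2^−ΔΔCt formula presumes: ΔCt = mean(Ct_target) − mean(Ct_reference) per
(gene, sample) with replicate Cts averaged before differencing; the replicate
SD of ΔCt (square root of summed variances) is reported alongside — the
error-bar convention when publications leave SD-of-what unstated. The
calibrator sample is exactly 1 by construction. One-way ANOVA is the
classical F = MS_between/MS_within with (k−1, N−k) df; degenerate inputs
follow explicit contracts (all-identical → F=0, p=1; zero within-group
variance with distinct means → F=∞, p=0).

## Synthetic data

All generators are pure functions of their parameters and a seed;
regeneration is bit-identical. Defaults mirror the study conditions the
pipeline assumes: subfamily proportions weighted toward PIPs, subfamily
intron counts (PIP 3, TIP 2, NIP 4, SIP/XIP 2), tandem arrays of 2–3 copies
at ~5–8 kb spacing with ~5% copy divergence, a 35-member reference set with
the canonical 13 PIP / 10 TIP / 9 NIP / 3 SIP split (optional XIP references,
since *Arabidopsis*-style sets lack XIPs), planted ω = 0.3 for codon pairs,
FPKM base levels of 30–150 (high) vs < 2 (low) with log-normal noise at
CV 0.2, salt inductions of 8-fold at a planted peak on a (12, 24, 48) h grid,
and Ct noise of 0.15 cycles over 3 replicates — standard magnitudes for this
kind of data, chosen once and documented here.

Mutation models are deliberately simple: proteins mutate uniformly over the
19 alternative residues (hydrophobic-preserving within TM segments, annotated
motif columns protected), CDS evolve by single-nucleotide substitutions
uniform over non-stop neighbors with nonsynonymous acceptance scaled by the
planted ω. Duplicate-copy CDSs are derived codon-wise from their source CDS
with a small synonymous substitution rate, so silent sites stay correlated
within a duplicate pair — independent codon choices would saturate synonymous
differences and leave Ks undefined. Negative tandem decoys violate exactly
one rule clause each (span, intervening count, or identity), making the
detector's clause logic individually falsifiable.

What the generators do **not** emulate: indel evolution, codon-usage and
composition bias, rate heterogeneity across sites, genome-scale intergenic
structure, mapping/quantification noise in FPKM values, and amplification
efficiency drift in qPCR. Passing tests therefore demonstrate algorithmic
correctness against the stated rules and statistical recovery under idealized
noise — not robustness to every artifact of real genome annotations.

## Numerical and interface conventions

Coordinates are 1-based inclusive (GFF3 convention) everywhere; half-open
arithmetic is localized inside length computations. The representative
transcript, tie-breaks in screening, NJ joins, peak times and dendrogram leaf
order are all deterministic, so every pipeline output is reproducible
bit-for-bit under a fixed seed; the survey runner records its thresholds and
seed in the report metadata. Problem sizes in the test suite and acceptance
script (e.g. 100 random chromosomes of 12–200 genes, 50 codon-pair
replicates at 500 codons, 200 motif recoveries per subfamily, 200 bootstrap
replicates) were chosen to make the statistical checks decisive at desk
scale.

## Known limitations

- Screening quality is bounded by the reference set: subfamilies absent from
  the references (e.g. XIPs against an *Arabidopsis*-style set) cannot be
  retained or named — the machinery supports any reference FASTA.
- Heavily diverged family members (best identity 40–60%) are retained but
  deliberately left subfamily-unassigned; very short or partial proteins can
  fail the coverage clause.
- NG86 is a counting estimator: it underestimates ω under strong codon bias
  and saturates (NA) near p = 3/4; no maximum-likelihood (codeml-style)
  variant is provided.
- Bootstrap supports require the alignment path; trees built directly from a
  distance matrix carry no supports.
- The ar/R rule table is finite by design; genuinely novel tetrads classify
  as `unclassified` rather than being force-fitted.
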