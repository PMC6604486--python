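import math
import warnings

import numpy as np
import pytest
from Bio.Seq import Seq

from mipfam import synthetic_data as sd
from mipfam.alignment import make_aligner, pairwise_global_align
from mipfam.duplication_kaks import (DuplicatePair, _codon_path_diffs,
                                     classify_selection, compute_pair_kaks,
                                     find_tandem_pairs, load_segmental_pairs,
                                     ng86_kaks)
from mipfam.seqio import GeneModel, SequenceRecord


def _cds(name, codons):
    return SequenceRecord(name, "".join(codons), moltype="dna")


# ---------------------------------------------------------------------------
# NG86


class TestNG86:
    def test_identical_cds_is_zero_zero_na(self):
        a = _cds("a", ["ATG", "GCT", "AAA", "TGC"])
        ka, ks, omega = ng86_kaks(a, a)
        assert ka == 0.0 and ks == 0.0 and omega is None

    def test_fourfold_synonymous_only_diffs(self):
        """All differences at 4-fold degenerate third positions: the
        translation-comparison oracle confirms every change is synonymous,
        so Ka = 0 and Ks > 0."""
        codons_a = ["GGT", "CCT"] + ["GCT", "ACT", "GTT"] * 4
        codons_b = ["GGC", "CCA"] + ["GCT", "ACT", "GTT"] * 4
        for ca, cb in zip(codons_a, codons_b):  # independent oracle
            assert str(Seq(ca).translate()) == str(Seq(cb).translate())
        ka, ks, omega = ng86_kaks(_cds("a", codons_a), _cds("b", codons_b))
        assert ka == 0.0 and ks > 0.0 and omega == 0.0

    def test_site_and_difference_counts_against_enumeration_oracle(self):
        """Dual-route check of a small case: synonymous site fractions are
        recomputed by enumerating all single-nucleotide neighbors with
        Biopython translation, differences by direct translation equality."""
        codons_a = ["TTT", "GGT", "GAA", "GCT", "AAA", "CCC", "ATG", "TGG"]
        codons_b = ["TTC", "GGA", "GAA", "GCT", "AAA", "CCC", "ATG", "TGG"]

        def syn_sites_oracle(codon):
            aa = str(Seq(codon).translate())
            syn = 0
            for i in range(3):
                for b in "ACGT":
                    if b == codon[i]:
                        continue
                    alt = codon[:i] + b + codon[i + 1:]
                    alt_aa = str(Seq(alt).translate())
                    if alt_aa != "*" and alt_aa == aa:
                        syn += 1
            return syn / 3.0

        S = sum((syn_sites_oracle(a) + syn_sites_oracle(b)) / 2
                for a, b in zip(codons_a, codons_b))
        Sd = sum(1 for a, b in zip(codons_a, codons_b)
                 if a != b and str(Seq(a).translate()) == str(Seq(b).translate()))
        assert Sd == 2
        expected_ks = -0.75 * math.log(1 - 4 * (Sd / S) / 3)
        ka, ks, _ = ng86_kaks(_cds("a", codons_a), _cds("b", codons_b))
        assert ka == 0.0
        assert ks == pytest.approx(expected_ks, rel=1e-12)

    def test_two_position_leucine_change_counts_two_synonymous(self):
        # TTA -> CTG: both mutation orders pass through leucine codons
        assert _codon_path_diffs("TTA", "CTG") == (2.0, 0.0)

    def test_stop_avoiding_path_selection(self):
        # TAT -> TGG: the path through TAG (stop) is excluded
        assert _codon_path_diffs("TAT", "TGG") == (0.0, 2.0)

    def test_symmetry(self):
        a, b, _ = sd.make_cds_pair(120, omega=0.5, ks_target=0.2, seed=3)
        assert ng86_kaks(a, b) == ng86_kaks(b, a)

    def test_ambiguous_codons_excluded(self):
        a = _cds("a", ["ATG", "NNN", "GGT"] + ["GCT"] * 6)
        b = _cds("b", ["ATG", "AAA", "GGC"] + ["GCT"] * 6)
        ka, ks, _ = ng86_kaks(a, b)
        assert ka == 0.0 and ks > 0.0  # only the GGT/GGC codon differs

    def test_synonymous_additions_never_increase_ka(self):
        codons_a = ["ATG", "GGT", "CCT", "AAA", "TTT", "GAA"] * 5
        codons_b = list(codons_a)
        codons_b[1] = "GGA"
        codons_b[4] = "TTC"
        ka1, ks1, _ = ng86_kaks(_cds("a", codons_a), _cds("b", codons_b))
        codons_b[7] = "GGC"  # one more synonymous change (4-fold site)
        ka2, ks2, _ = ng86_kaks(_cds("a", codons_a), _cds("b2", codons_b))
        assert ka2 <= ka1 + 1e-12
        assert ks2 > ks1

    def test_protein_guided_alignment_for_unequal_lengths(self):
        codons = ["ATG", "GCT", "AAA", "TGC", "GAA", "TTT", "CCA", "GGG"]
        a = _cds("a", codons)
        b = _cds("b", codons[:3] + codons[4:])  # one codon deleted
        ka, ks, _ = ng86_kaks(a, b)
        assert ka == 0.0 and ks == 0.0

    def test_planted_omega_recovered_on_average(self):
        estimates = []
        for i in range(20):
            a, b, _ = sd.make_cds_pair(300, omega=0.3, ks_target=0.3, seed=100 + i)
            _, _, omega = ng86_kaks(a, b)
            estimates.append(omega)
        assert abs(float(np.mean(estimates)) - 0.3) < 0.15

    def test_purifying_calls_on_planted_low_omega(self):
        calls = []
        for i in range(20):
            a, b, _ = sd.make_cds_pair(300, omega=0.3, ks_target=0.3, seed=300 + i)
            _, _, omega = ng86_kaks(a, b)
            calls.append(classify_selection(omega))
        assert calls.count("purifying") >= 19


@pytest.mark.parametrize("omega,expected", [
    (0.023, "purifying"), (0.685, "purifying"), (1.0, "neutral~1"),
    (1.04, "neutral~1"), (1.3, "positive"), (None, "NA"),
])
def test_selection_classification(omega, expected):
    assert classify_selection(omega) == expected


# ---------------------------------------------------------------------------
# Tandem detection


def _gene(gid, chrom, start, end):
    return GeneModel(gid, chrom, start, end, "+", exons=((start, end),))


class TestTandem:
    def test_adjacent_identical_pair_found(self):
        prot = SequenceRecord("p", "MKVLHWSTNQERDAGILKVH" * 10)
        models = [_gene("a", "Chr01", 1000, 2000), _gene("b", "Chr01", 7000, 8000)]
        proteins = {"a": SequenceRecord("a", prot.sequence),
                    "b": SequenceRecord("b", prot.sequence)}
        pairs = find_tandem_pairs(models, proteins)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.gene_a, p.gene_b) == ("a", "b")
        assert p.span_bp == 5000 and p.intervening_genes == 0
        assert p.protein_identity_pct == 100.0

    def test_span_rule_excludes_distant_identical_genes(self):
        prot = "MKVLHWSTNQERDAGILKVH" * 10
        models = [_gene("a", "Chr01", 1000, 2000),
                  _gene("b", "Chr01", 155000, 156000)]
        proteins = {g: SequenceRecord(g, prot) for g in ("a", "b")}
        assert find_tandem_pairs(models, proteins) == []

    def test_missing_protein_candidate_warns_and_skips(self):
        models = [_gene("a", "Chr01", 1000, 2000), _gene("b", "Chr01", 7000, 8000)]
        proteins = {"a": SequenceRecord("a", "MKVLH" * 40)}
        with pytest.warns(UserWarning, match="lacks a protein"):
            pairs = find_tandem_pairs(models, proteins, candidate_ids=["a", "b"])
        assert pairs == []

    def test_planted_arrays_recovered_and_negatives_rejected(self):
        truth = sd.make_annotation(seed=5)
        got = {frozenset((p.gene_a, p.gene_b))
               for p in find_tandem_pairs(truth.models, truth.proteins)}
        assert got == truth.tandem_pairs
        assert not got & set(truth.negative_pairs)

    def test_matches_brute_force_on_random_chromosomes(self, aligner):
        """The windowed scan equals an O(n^2) all-pairs filter over the
        three rule clauses on random annotated chromosomes."""
        for seed in range(3):
            models, proteins = sd.make_random_chromosome(40, seed=seed)
            got = {frozenset((p.gene_a, p.gene_b))
                   for p in find_tandem_pairs(models, proteins, aligner=aligner)}
            genes = sorted(models, key=lambda m: (m.start, m.gene_id))
            expected = set()
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    if j - i - 1 > 5:
                        continue
                    if genes[j].start - genes[i].end > 100000:
                        continue
                    r = pairwise_global_align(proteins[genes[i].gene_id],
                                              proteins[genes[j].gene_id],
                                              aligner=aligner)
                    if r.identity_pct > 70.0:
                        expected.add(frozenset((genes[i].gene_id,
                                                genes[j].gene_id)))
            assert got == expected


# ---------------------------------------------------------------------------
# Segmental pairs


class TestSegmental:
    def test_rows_become_segmental_pairs(self, tmp_path):
        p = tmp_path / "seg.tsv"
        p.write_text("gene_a\tgene_b\tka\tks\ng1\tg2\t0.1\t0.5\ng3\tg4\t0.2\t0.4\n")
        pairs = load_segmental_pairs(p)
        assert len(pairs) == 2
        assert all(x.dup_type == "segmental" for x in pairs)
        assert pairs[0].omega == pytest.approx(0.2)
        assert pairs[0].selection == "purifying"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "seg.tsv"
        p.write_text("gene_a\tgene_b\n")
        assert load_segmental_pairs(p) == []

    def test_unknown_gene_row_skipped_with_warning(self, tmp_path):
        p = tmp_path / "seg.tsv"
        p.write_text("gene_a\tgene_b\ng1\tghost\n")
        with pytest.warns(UserWarning, match="ghost"):
            pairs = load_segmental_pairs(p, known_gene_ids={"g1", "g2"})
        assert pairs == []

    def test_kaks_recomputed_from_cds(self, tmp_path):
        p = tmp_path / "seg.tsv"
        p.write_text("gene_a\tgene_b\ng1\tg2\n")
        cds = {"g1": _cds("g1", ["ATG", "GGT", "AAA"] * 4),
               "g2": _cds("g2", ["ATG", "GGC", "AAA"] + ["ATG", "GGT", "AAA"] * 3)}
        (pair,) = load_segmental_pairs(p, cds_map=cds)
        assert pair.ka == 0.0 and pair.ks > 0


def test_duplicate_pair_validation():
    with pytest.raises(ValueError):
        DuplicatePair("a", "b", "weird")
    with pytest.raises(ValueError):
        DuplicatePair("a", "b", "tandem", ka=-0.1)
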