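import math

import numpy as np
import pandas as pd
import pytest

from mipfam import synthetic_data as sd
from mipfam.expression_stress import (ResponseProfile, classify_salt_response,
                                      cut_clusters, flag_expression_class,
                                      hierarchical_cluster, normalize_log2,
                                      peak_time_bias, profiles_from_matrices)
from mipfam.seqio import ExpressionMatrix


def _matrix(rows, columns=None):
    df = pd.DataFrame.from_dict(rows, orient="index")
    if columns:
        df.columns = columns
    return ExpressionMatrix(values=df.astype(float))


class TestNormalize:
    def test_closed_forms(self):
        m = _matrix({"g": [0.0, 7.0, 1023.0]})
        out = normalize_log2(m)
        assert list(out.values.loc["g"]) == pytest.approx([0.0, 3.0, 10.0])
        assert out.normalized

    def test_double_normalization_rejected(self):
        m = normalize_log2(_matrix({"g": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="already"):
            normalize_log2(m)

    def test_strictly_monotone_per_gene(self):
        raw = np.sort(np.random.default_rng(0).uniform(0, 500, size=20))
        m = _matrix({"g": list(raw)})
        out = normalize_log2(m).values.loc["g"].to_numpy()
        assert (np.diff(out) > 0).all()


class TestClustering:
    def test_identical_rows_merge_first(self):
        m = _matrix({"g1": [1, 2, 3, 4], "g2": [1, 2, 3, 4],
                     "g3": [9, 1, 7, 0]})
        order, Z = hierarchical_cluster(m, metric="euclidean")
        assert Z[0][0] == 0 and Z[0][1] == 1  # g1+g2 joined at distance 0
        assert Z[0][2] == 0.0

    def test_permutation_gives_same_dendrogram_up_to_relabeling(self):
        rows = {f"g{i}": list(np.random.default_rng(i).uniform(0, 50, 6))
                for i in range(6)}
        m1 = _matrix(rows)
        perm = list(rows)[::-1]
        m2 = ExpressionMatrix(values=m1.values.loc[perm])
        c1 = cut_clusters(m1, 3)
        c2 = cut_clusters(m2, 3)
        # same partition of gene ids regardless of input order
        parts1 = {frozenset(g for g in c1 if c1[g] == k) for k in set(c1.values())}
        parts2 = {frozenset(g for g in c2 if c2[g] == k) for k in set(c2.values())}
        assert parts1 == parts2

    def test_single_gene_singleton(self):
        order, Z = hierarchical_cluster(_matrix({"g": [1, 2, 3]}))
        assert order == ["g"] and Z.size == 0

    def test_zero_variance_rows_handled(self):
        m = _matrix({"flat": [5, 5, 5, 5], "g1": [1, 2, 3, 4], "g2": [2, 4, 6, 8]})
        order, _ = hierarchical_cluster(m, metric="correlation")
        assert set(order) == {"flat", "g1", "g2"}

    def test_planted_blocks_recovered_at_k2(self):
        m, truth = sd.make_coexpression_blocks(n_per_block=8, seed=4)
        clusters = cut_clusters(m, 2)
        labels_a = {clusters[g] for g, t in truth.items() if t == "A"}
        labels_b = {clusters[g] for g, t in truth.items() if t == "B"}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b


class TestTissueFlags:
    def test_trivial_classes(self):
        m = _matrix({"hi": [10] * 10, "lo": [0] * 10,
                     "spec": [50] + [0] * 9})
        flags = flag_expression_class(m)
        assert flags == {"hi": "high_all_tissues", "lo": "low_all",
                         "spec": "tissue_specific"}

    def test_broadly_expressed_gene_is_unflagged(self):
        m = _matrix({"g": [10, 10, 10, 10, 10, 0, 0, 0, 0, 0]})
        assert flag_expression_class(m)["g"] == "unflagged"

    def test_column_permutation_invariance(self):
        m, truth = sd.make_tissue_matrix(seed=1)
        flags = flag_expression_class(m)
        permuted = ExpressionMatrix(values=m.values[m.values.columns[::-1]])
        assert flag_expression_class(permuted) == flags

    def test_planted_classes_recovered(self):
        m, truth = sd.make_tissue_matrix(seed=2)
        flags = flag_expression_class(m)
        assert all(flags[g] == truth[g] for g in truth)

    def test_normalized_matrix_rejected(self):
        m = normalize_log2(_matrix({"g": [1, 2]}))
        with pytest.raises(ValueError):
            flag_expression_class(m)


class TestSaltResponse:
    def test_induction_with_peak(self):
        p = ResponseProfile("g", (12.0, 24.0, 48.0), (5.0, 40.0, 20.0),
                            (5.0, 5.0, 5.0))
        out = classify_salt_response(p)
        assert out.direction == "induced" and out.peak_time == 24.0

    def test_flat_profile_unchanged(self):
        p = ResponseProfile("g", (12.0, 24.0), (8.0, 8.0), (8.0, 8.0))
        assert classify_salt_response(p).direction == "unchanged"

    def test_low_expression_filter(self):
        p = ResponseProfile("g", (12.0, 24.0), (1.0, 4.0), (0.5, 0.5))
        out = classify_salt_response(p)
        assert out.direction == "low_expression" and out.peak_time is None

    def test_baseline_reference_when_no_control(self):
        p = ResponseProfile("g", (0.0, 24.0, 48.0), (6.0, 30.0, 10.0), None)
        assert classify_salt_response(p).direction == "induced"

    def test_fewer_than_two_timepoints_is_error(self):
        with pytest.raises(ValueError):
            classify_salt_response(ResponseProfile("g", (12.0,), (5.0,), (5.0,)))

    def test_raising_fold_never_grows_induced_set(self):
        treated, control, _ = sd.make_salt_timecourse(
            {f"g{i}": ("induced", 24.0) for i in range(5)} |
            {f"h{i}": ("unchanged", None) for i in range(5)}, seed=3)
        profiles = profiles_from_matrices(treated, control, (12, 24, 48))
        previous = None
        for fold in (1.5, 2.0, 4.0, 9.0):
            induced = {p.gene_id for p in
                       (classify_salt_response(q, fold=fold) for q in profiles)
                       if p.direction == "induced"}
            if previous is not None:
                assert induced <= previous
            previous = induced

    def test_planted_directions_and_peaks_recovered(self):
        patterns = {"i12": ("induced", 12.0), "i24": ("induced", 24.0),
                    "i48": ("induced", 48.0), "rep": ("repressed", 24.0),
                    "flat": ("unchanged", None), "low": ("low_expression", None)}
        treated, control, truth = sd.make_salt_timecourse(patterns, seed=6)
        profiles = [classify_salt_response(p)
                    for p in profiles_from_matrices(treated, control, (12, 24, 48))]
        by_gene = {p.gene_id: p for p in profiles}
        for _, row in truth.iterrows():
            p = by_gene[row["gene"]]
            assert p.direction == row["direction"]
            if row["direction"] == "induced":
                assert p.peak_time == row["peak_time"]


class TestPeakBias:
    def _profile(self, gid, treated):
        p = ResponseProfile(gid, (12.0, 24.0, 48.0), treated,
                            (10.0, 10.0, 10.0))
        return classify_salt_response(p)

    def test_identical_profiles_zero_delta(self):
        a = [self._profile("x", (10.0, 40.0, 12.0))]
        b = [self._profile("x", (10.0, 40.0, 12.0))]
        per_pair, summary = peak_time_bias(a, b, [("x", "x")])
        assert per_pair[("x", "x")] == 0.0
        assert summary["median_delta_peak"] == 0.0

    def test_directional_shift(self):
        a = [self._profile("x", (10.0, 12.0, 40.0))]  # peaks 48
        b = [self._profile("x", (10.0, 40.0, 12.0))]  # peaks 24
        per_pair, _ = peak_time_bias(a, b, [("x", "x")])
        assert per_pair[("x", "x")] == -24.0

    def test_na_peaks_excluded_and_counted(self):
        low = classify_salt_response(ResponseProfile(
            "x", (12.0, 24.0, 48.0), (1.0, 2.0, 1.0), (0.5, 0.5, 0.5)))
        a = [low]   # low_expression -> peak NA
        b = [self._profile("x", (10.0, 40.0, 12.0))]
        per_pair, summary = peak_time_bias(a, b, [("x", "x")])
        assert per_pair == {} and summary["n_excluded_na_peak"] == 1

    def test_planted_systematic_shift_recovered(self):
        """Species B peaking 24 h after species A yields median delta +24 h
        and opposite early-phase trends."""
        genes = [f"g{i}" for i in range(8)]
        a_t, a_c, _ = sd.make_salt_timecourse(
            {g: ("induced", 12.0) for g in genes}, seed=7)
        b_t, b_c, _ = sd.make_salt_timecourse(
            {g: ("induced", 48.0) for g in genes}, seed=8)
        pa = [classify_salt_response(p)
              for p in profiles_from_matrices(a_t, a_c, (12, 24, 48))]
        pb = [classify_salt_response(p)
              for p in profiles_from_matrices(b_t, b_c, (12, 24, 48))]
        per_pair, summary = peak_time_bias(pa, pb, [(g, g) for g in genes])
        assert summary["median_delta_peak"] == 36.0
        assert summary["n_opposite_early_phase"] >= 6
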