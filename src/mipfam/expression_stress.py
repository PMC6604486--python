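"""Expression normalization, clustering and salt-stress response calls.

Raw FPKM matrices are normalized as log2(FPKM+1). Tissue panels are flagged
as highly expressed everywhere, tissue-specific, or low everywhere using the
FPKM >= 5 expression floor. Salt time courses are classified as induced /
repressed / unchanged / low_expression against a paired control series (or
the t0 baseline), with the peak time taken as the argmax of the treated
series (earliest timepoint on ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .seqio import ExpressionMatrix

LOW_EXPRESSION_FPKM = 5.0


def normalize_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1) transform; refuses to double-normalize."""
    if matrix.normalized:
        raise ValueError("matrix is already log2(FPKM+1)-normalized")
    return ExpressionMatrix(values=np.log2(matrix.values + 1.0), normalized=True)


def _correlation_distances(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances; rows with zero variance get the
    maximum distance (2.0) to every other row."""
    n = values.shape[0]
    sd = values.std(axis=1)
    degenerate = sd == 0
    safe = values.copy()
    safe[degenerate] = 0.0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(safe) if n > 1 else np.ones((1, 1))
    dist = 1.0 - corr
    dist[degenerate, :] = 2.0
    dist[:, degenerate] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def hierarchical_cluster(matrix: ExpressionMatrix, metric: str = "correlation",
                         method: str = "average"):
    """Agglomerative clustering of gene rows.

    Returns ``(leaf_order, Z)``: gene ids in dendrogram leaf order and the
    scipy linkage matrix (empty for a single gene). Deterministic for fixed
    input; permuting gene order permutes only the labels.
    """
    genes = matrix.gene_ids
    if len(genes) == 0:
        return [], np.empty((0, 4))
    if len(genes) == 1:
        return list(genes), np.empty((0, 4))
    values = matrix.values.to_numpy(dtype=float)
    if metric == "correlation":
        condensed = _correlation_distances(values)
    elif metric == "euclidean":
        condensed = pdist(values, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = linkage(condensed, method=method)
    order = leaves_list(Z)
    return [genes[i] for i in order], Z


def cut_clusters(matrix: ExpressionMatrix, k: int, metric: str = "correlation",
                 method: str = "average") -> dict:
    """Cut the dendrogram into k flat clusters: gene id -> cluster label."""
    from scipy.cluster.hierarchy import fcluster

    genes = matrix.gene_ids
    _, Z = hierarchical_cluster(matrix, metric=metric, method=method)
    if len(genes) <= 1:
        return {g: 1 for g in genes}
    labels = fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(genes, (int(l) for l in labels)))


def flag_expression_class(matrix: ExpressionMatrix,
                          high_threshold: float = LOW_EXPRESSION_FPKM) -> dict:
    """Per-gene tissue-panel class on a raw FPKM matrix.

    high_all_tissues: every sample >= threshold; low_all: every sample below;
    tissue_specific: expressed in at least one but at most ceil(30%) of the
    samples; anything else is unflagged.
    """
    if matrix.normalized:
        raise ValueError("expression classes are defined on raw FPKM")
    n = len(matrix.sample_ids)
    breadth_cap = math.ceil(0.3 * n)
    out = {}
    for gene, row in matrix.values.iterrows():
        high = int((row >= high_threshold).sum())
        if high == n:
            out[gene] = "high_all_tissues"
        elif high == 0:
            out[gene] = "low_all"
        elif high <= breadth_cap:
            out[gene] = "tissue_specific"
        else:
            out[gene] = "unflagged"
    return out


@dataclass(frozen=True)
class ResponseProfile:
    """A gene's stress time course (FPKM), optionally with paired control."""

    gene_id: str
    timepoints: tuple
    treated: tuple
    control: tuple | None = None
    direction: str = "unclassified"
    peak_time: float | None = None

    def __post_init__(self):
        if len(self.treated) != len(self.timepoints):
            raise ValueError(f"{self.gene_id}: treated series length mismatch")
        if self.control is not None and len(self.control) != len(self.timepoints):
            raise ValueError(f"{self.gene_id}: control series length mismatch")


def classify_salt_response(profile: ResponseProfile, fold: float = 2.0,
                           low_threshold: float = LOW_EXPRESSION_FPKM) -> ResponseProfile:
    """Assign direction and peak time to a stress time course.

    A gene whose treated and control series never reach ``low_threshold`` is
    low_expression. Otherwise it is induced if at some timepoint treated >=
    fold x reference (paired control, or the t0 treated baseline when no
    control is available) with treated above the floor there; repressed
    symmetrically; unchanged otherwise. Peak time is the argmax of the
    treated series, earliest timepoint on ties.
    """
    if len(profile.timepoints) < 2:
        raise ValueError(f"{profile.gene_id}: need at least 2 timepoints")
    treated = np.asarray(profile.treated, dtype=float)
    if profile.control is not None:
        reference = np.asarray(profile.control, dtype=float)
        observed_max = max(treated.max(), reference.max())
    else:
        reference = np.full_like(treated, treated[0])
        observed_max = treated.max()

    # np.argmax returns the first maximum, i.e. the earliest peak on ties
    peak_time = float(profile.timepoints[int(np.argmax(treated))])

    if observed_max < low_threshold:
        return replace(profile, direction="low_expression", peak_time=None)

    induced = bool(np.any((treated >= fold * reference)
                          & (treated >= low_threshold)))
    repressed = bool(np.any((reference >= fold * treated)
                            & (reference >= low_threshold)))
    if induced and repressed:
        with np.errstate(divide="ignore"):
            up = np.max(np.log2(np.maximum(treated, 1e-9) / np.maximum(reference, 1e-9)))
            down = np.max(np.log2(np.maximum(reference, 1e-9) / np.maximum(treated, 1e-9)))
        direction = "induced" if up >= down else "repressed"
    elif induced:
        direction = "induced"
    elif repressed:
        direction = "repressed"
    else:
        direction = "unchanged"
    return replace(profile, direction=direction, peak_time=peak_time)


def profiles_from_matrices(treated: ExpressionMatrix,
                           control: ExpressionMatrix | None,
                           timepoints) -> list:
    """Build one ResponseProfile per gene from treated (and optional control)
    matrices whose columns are the shared timepoints, in order."""
    timepoints = tuple(float(t) for t in timepoints)
    if len(timepoints) != len(treated.sample_ids):
        raise ValueError("timepoints do not match treated matrix columns")
    out = []
    for gene in treated.gene_ids:
        ctrl = None
        if control is not None and gene in control.values.index:
            ctrl = tuple(float(v) for v in control.values.loc[gene])
        out.append(ResponseProfile(
            gene_id=gene,
            timepoints=timepoints,
            treated=tuple(float(v) for v in treated.values.loc[gene]),
            control=ctrl,
        ))
    return out


def peak_time_bias(profiles_a, profiles_b, ortholog_pairs):
    """Peak-time shift between two species' classified stress profiles.

    For each ortholog pair (gene_in_A, gene_in_B): delta = peak_time(B) -
    peak_time(A). Returns ``(per_pair, summary)`` where summary holds the
    median delta, the number of pairs with opposite early-phase trends (A
    falling while B rising over the first time interval, or vice versa), and
    the count of pairs excluded for an undefined peak.
    """
    by_a = {p.gene_id: p for p in profiles_a}
    by_b = {p.gene_id: p for p in profiles_b}
    per_pair = {}
    excluded = 0
    opposite = 0
    for ga, gb in ortholog_pairs:
        pa, pb = by_a[ga], by_b[gb]
        if pa.timepoints != pb.timepoints:
            raise ValueError(f"pair {ga}/{gb}: timepoint grids differ")
        if pa.peak_time is None or pb.peak_time is None:
            excluded += 1
            continue
        per_pair[(ga, gb)] = pb.peak_time - pa.peak_time
        early_a = pa.treated[1] - pa.treated[0]
        early_b = pb.treated[1] - pb.treated[0]
        if early_a * early_b < 0:
            opposite += 1
    deltas = list(per_pair.values())
    summary = {
        "median_delta_peak": float(np.median(deltas)) if deltas else None,
        "n_pairs": len(per_pair),
        "n_opposite_early_phase": opposite,
        "n_excluded_na_peak": excluded,
    }
    return per_pair, summary
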