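"""Relative quantification of qPCR data by the Livak 2^-ddCt method, with
replicate aggregation and one-way ANOVA.

Each measurement pairs a target-gene Ct with a reference-gene Ct (the
internal control, e.g. Histone3). Per (gene, sample): dCt = mean(Ct_target) -
mean(Ct_reference); ddCt subtracts the calibrator sample's dCt; relative
expression = 2^-ddCt, so the calibrator is exactly 1. Amplification
efficiency is assumed 100% (base 2), as the formula presumes. The replicate
SD of dCt (sqrt of summed variances) is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_MAX_CYCLES = 40.0


@dataclass(frozen=True)
class QPCRRecord:
    gene_id: str
    sample_id: str
    condition: str
    ct_target: float
    ct_reference: float
    replicate: int = 1

    def __post_init__(self):
        for name, ct in (("target", self.ct_target), ("reference", self.ct_reference)):
            if not 0.0 < ct <= CT_MAX_CYCLES:
                raise ValueError(
                    f"{self.gene_id}/{self.sample_id}: {name} Ct {ct} outside "
                    f"(0, {CT_MAX_CYCLES:g}]"
                )
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def read_ct_table(path) -> list:
    """Read a TSV with columns gene, sample, condition, replicate,
    ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "condition", "replicate", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        QPCRRecord(
            gene_id=str(r["gene"]), sample_id=str(r["sample"]),
            condition=str(r["condition"]), replicate=int(r["replicate"]),
            ct_target=float(r["ct_target"]), ct_reference=float(r["ct_reference"]),
        )
        for _, r in df.iterrows()
    ]


def delta_delta_ct(records, calibrator_sample: str) -> pd.DataFrame:
    """Relative expression per (gene, sample) against a calibrator sample.

    Returns a DataFrame with columns gene, sample, condition, n_replicates,
    delta_ct, delta_ct_sd, delta_delta_ct, rel_expression. Every gene must
    have measurements in the calibrator sample.
    """
    groups: dict = {}
    for r in records:
        groups.setdefault((r.gene_id, r.sample_id), []).append(r)

    stats_rows = {}
    for (gene, sample), recs in sorted(groups.items()):
        t = np.array([r.ct_target for r in recs])
        ref = np.array([r.ct_reference for r in recs])
        dct = float(t.mean() - ref.mean())
        var = (t.var(ddof=1) if len(t) > 1 else 0.0) + \
              (ref.var(ddof=1) if len(ref) > 1 else 0.0)
        stats_rows[(gene, sample)] = {
            "condition": recs[0].condition,
            "n_replicates": len(recs),
            "delta_ct": dct,
            "delta_ct_sd": math.sqrt(var),
        }

    genes = sorted({g for g, _ in stats_rows})
    rows = []
    for gene in genes:
        cal_key = (gene, calibrator_sample)
        if cal_key not in stats_rows:
            raise ValueError(
                f"gene {gene!r}: no measurements in calibrator sample "
                f"{calibrator_sample!r}"
            )
        cal_dct = stats_rows[cal_key]["delta_ct"]
        for (g, sample), st in sorted(stats_rows.items()):
            if g != gene:
                continue
            ddct = st["delta_ct"] - cal_dct
            rows.append({
                "gene": gene, "sample": sample, "condition": st["condition"],
                "n_replicates": st["n_replicates"],
                "delta_ct": st["delta_ct"], "delta_ct_sd": st["delta_ct_sd"],
                "delta_delta_ct": ddct,
                "rel_expression": 2.0 ** (-ddct),
            })
    return pd.DataFrame(rows)


def anova_oneway(groups):
    """Classical one-way ANOVA: F = MS_between / MS_within with (k-1, N-k)
    degrees of freedom; p from the F distribution.

    Degenerate contracts: all values identical everywhere -> (0, 1); zero
    within-group variance with distinct group means -> (inf, 0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    F = ms_between / ms_within
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), p
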