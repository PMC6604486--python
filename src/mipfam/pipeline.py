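"""End-to-end survey orchestration: screen -> nomenclature -> motifs ->
structure -> tandem/Ka-Ks -> tree -> expression -> qPCR, emitting a per-gene
characterization table plus stage tables, reproducibly under a fixed seed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from . import seqio
from .alignment import make_aligner
from .duplication_kaks import (compute_pair_kaks, find_tandem_pairs,
                               load_segmental_pairs, pairs_table)
from .expression_stress import (classify_salt_response, flag_expression_class,
                                hierarchical_cluster, normalize_log2,
                                profiles_from_matrices)
from .family_classify import assign_nomenclature, screen_candidates
from .gene_structure import count_introns, intron_pattern_table
from .motif_profile import default_templates, map_positions_best
from .phylogeny import bootstrap_supports
from .qpcr import delta_delta_ct, read_ct_table

logger = logging.getLogger("mipfam")

#: survey thresholds; the classical screening/tandem/expression parameters
#: surface here by name and are overridable from the config file.
DEFAULTS = {
    "min_identity": 30.0,      # candidate screen identity floor (%)
    "min_coverage": 50.0,      # candidate screen query coverage floor (%)
    "max_intervening": 5,      # tandem rule: genes between the pair
    "max_span": 100000,        # tandem rule: boundary distance (bp)
    "tandem_min_identity": 70.0,  # tandem rule: protein identity (%)
    "fpkm_low": 5.0,           # low-expression floor (FPKM)
    "fold": 2.0,               # induction/repression fold threshold
    "neutral_band": 0.05,      # omega band treated as neutral around 1
    "bootstrap_reps": 1000,
    "seed": 17,
    "calibrator": "control",
}

_PATH_KEYS = ("proteome", "refs", "gff", "cds", "segmental_pairs",
              "expression", "salt_treated", "salt_control", "ct", "msa")
_REQUIRED = ("proteome", "refs", "gff")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


def parse_config(path) -> dict:
    """Flat declarative key=value config (# comments allowed)."""
    config = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}: line {lineno}: expected key=value")
            key, value = line.split("=", 1)
            config[key.strip()] = value.strip()
    return config


@dataclass
class SurveyReport:
    tables: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def per_gene(self) -> pd.DataFrame:
        return self.tables["per_gene"]


def _floats(config, *keys):
    return [float(config.get(k, DEFAULTS[k])) for k in keys]


def run_survey(config: dict) -> SurveyReport:
    """Run the full survey described by a flat config mapping.

    Required keys: proteome, refs, gff (cds enables Ka/Ks). Optional inputs
    switch on the corresponding stages. All input files are checked before
    any computation; a stage failure aborts with the stage name.
    """
    missing = [k for k in _REQUIRED if k not in config]
    if missing:
        raise ConfigError(f"config missing required keys: {missing}")
    for key in _PATH_KEYS:
        if key in config and not os.path.exists(str(config[key])):
            raise ConfigError(f"input file for {key!r} not found: {config[key]}")

    seed = int(config.get("seed", DEFAULTS["seed"]))
    min_identity, min_coverage = _floats(config, "min_identity", "min_coverage")
    tandem_identity, fpkm_low, fold, neutral_band = _floats(
        config, "tandem_min_identity", "fpkm_low", "fold", "neutral_band")
    max_intervening = int(config.get("max_intervening", DEFAULTS["max_intervening"]))
    max_span = int(config.get("max_span", DEFAULTS["max_span"]))
    aligner = make_aligner()
    report = SurveyReport(metadata={
        "mipfam_version": __version__,
        "seed": seed,
        "thresholds": {
            "min_identity": min_identity, "min_coverage": min_coverage,
            "family_identity": 40.0, "subfamily_identity": 60.0,
            "max_intervening": max_intervening, "max_span": max_span,
            "tandem_min_identity": tandem_identity,
            "fpkm_low": fpkm_low, "fold": fold, "neutral_band": neutral_band,
        },
    })

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # pragma: no cover - message formatting
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    proteome = stage("read_inputs", lambda: seqio.read_fasta(config["proteome"]))
    refs = seqio.read_fasta(config["refs"])
    models = seqio.read_gff3(config["gff"])
    model_map = {m.gene_id: m for m in models}

    assignments = stage("screen", lambda: screen_candidates(
        proteome, refs, min_identity_pct=min_identity,
        min_coverage_pct=min_coverage, aligner=aligner))
    logger.info("screen retained %d of %d proteins", len(assignments), len(proteome))

    named = stage("nomenclature", lambda: assign_nomenclature(
        [a for a in assignments if a.query_id in model_map], model_map))
    by_query = {a.query_id: a for a in named}

    prot_map = {r.id: r for r in proteome}
    templates = default_templates()
    profiles = stage("motifs", lambda: {
        a.query_id: map_positions_best(prot_map[a.query_id], templates,
                                       aligner=aligner)
        for a in named})

    summaries = stage("structure", lambda: [
        count_introns(model_map[a.query_id], subfamily=a.subfamily)
        for a in named])
    report.tables["intron_patterns"] = intron_pattern_table(summaries)

    family_proteins = {a.query_id: prot_map[a.query_id] for a in named}
    tandem = stage("tandem", lambda: find_tandem_pairs(
        models, family_proteins, max_intervening=max_intervening,
        max_span_bp=max_span, min_identity_pct=tandem_identity,
        aligner=aligner))

    pairs = list(tandem)
    if "segmental_pairs" in config:
        pairs += stage("segmental", lambda: load_segmental_pairs(
            config["segmental_pairs"], known_gene_ids=set(model_map)))
    if "cds" in config:
        cds_map = {r.id: r for r in seqio.read_fasta(config["cds"], moltype="dna")}
        pairs = stage("kaks", lambda: compute_pair_kaks(
            pairs, cds_map, neutral_band=neutral_band, aligner=aligner))
    report.tables["duplicate_pairs"] = pairs_table(pairs)

    if "msa" in config:
        msa = seqio.read_fasta(config["msa"])
        reps = int(config.get("bootstrap_reps", DEFAULTS["bootstrap_reps"]))
        tree = stage("tree", lambda: bootstrap_supports(msa, n_reps=reps, seed=seed))
        report.metadata["newick"] = tree.to_newick()

    expression_class = {}
    if "expression" in config:
        matrix = seqio.read_expression_matrix(config["expression"])
        expression_class = stage("expression", lambda: flag_expression_class(
            matrix, high_threshold=fpkm_low))
        normalized = normalize_log2(matrix)
        leaf_order, _ = hierarchical_cluster(normalized)
        report.metadata["expression_leaf_order"] = leaf_order

    salt_direction = {}
    if "salt_treated" in config:
        treated = seqio.read_expression_matrix(config["salt_treated"])
        control = (seqio.read_expression_matrix(config["salt_control"])
                   if "salt_control" in config else None)
        timepoints = [float(t) for t in
                      str(config.get("timepoints", "12,24,48")).split(",")]
        classified = stage("salt_response", lambda: [
            classify_salt_response(p, fold=fold, low_threshold=fpkm_low)
            for p in profiles_from_matrices(treated, control, timepoints)])
        salt_direction = {p.gene_id: p for p in classified}
        report.tables["salt_response"] = pd.DataFrame([
            {"gene": p.gene_id, "direction": p.direction,
             "peak_time": p.peak_time} for p in classified])

    if "ct" in config:
        records = read_ct_table(config["ct"])
        calibrator = str(config.get("calibrator", DEFAULTS["calibrator"]))
        report.tables["qpcr"] = stage("qpcr", lambda: delta_delta_ct(
            records, calibrator))

    tandem_members = {}
    for p in tandem:
        tandem_members.setdefault(p.gene_a, set()).add(p.gene_b)
        tandem_members.setdefault(p.gene_b, set()).add(p.gene_a)
    omega_of = {}
    for p in pairs:
        if p.omega is not None:
            for g in (p.gene_a, p.gene_b):
                omega_of.setdefault(g, p.omega)

    rows = []
    for a in named:
        prof = profiles[a.query_id]
        summary = next(s for s in summaries if s.gene_id == a.query_id)
        npa_status = f"{prof.npa1.triplet}/{prof.npa2.triplet}"
        salt = salt_direction.get(a.query_id)
        rows.append({
            "gene": a.query_id,
            "name": a.standardized_name,
            "best_ref": a.best_ref_id,
            "identity_pct": round(a.best_identity_pct, 2),
            "family_call": a.family_call,
            "subfamily": a.subfamily,
            "arR_group": prof.group,
            "npa_status": npa_status,
            "n_introns": summary.n_introns,
            "tandem_partners": ",".join(sorted(tandem_members.get(a.query_id, ()))),
            "omega": omega_of.get(a.query_id),
            "expression_class": expression_class.get(a.query_id, ""),
            "salt_direction": salt.direction if salt else "",
        })
    report.tables["per_gene"] = pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)

    if "out_dir" in config:
        seqio.write_report(report.tables, config["out_dir"], basename="survey")
        if "newick" in report.metadata:
            with open(os.path.join(config["out_dir"], "survey.nwk"), "w") as fh:
                fh.write(report.metadata["newick"] + "\n")
    return report
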