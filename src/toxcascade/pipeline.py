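"""Config-driven orchestration of the full time-concordance workflow.

Stages: activity scoring -> differential testing -> event extraction and
histopathology labelling -> time concordance -> TF cascade -> time
dependence. :func:`analyze_study` runs the whole analysis in memory;
:func:`run_pipeline` wraps it with file reading, TSV writing and a manifest
recording the config hash, versions and seed, so any stage output can be
inspected or re-used independently. Stage outputs are pure functions of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .activity import add_fdr, differential, score_per_compound
from .cascade import build_cascade, cascade_edge_table, classify_tf_regulation, export_cascade
from .concordance import concordance_table
from .events import SERIES, ActivationCriteria, first_activation
from .histopath import binarize_toxscores, first_adverse_time, select_adverse_findings
from .timedep import concordance_vs_dependence, time_dependence
from .types import (
    ExpressionData,
    GeneSetCollection,
    InteractionNetwork,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All inputs and every named threshold of the workflow.

    Defaults follow the study's canonical values: FDR < 0.05 for
    activation, |logFC| cut-offs of 1.0 for gene-level and 0.5 for TF
    expression events, toxscore thresholds (0, 0.67, 1.34), adverse-finding
    selection at >= 5 adverse occurrences and >= 50% adverse fraction,
    enrichment alpha 0.05, cascade edge support >= 20%, per-series Spearman
    alpha 0.05, >= 6 measured timepoints per series and >= 5 genes per set.
    """

    expression_tsv: str = ""
    sheet_csv: str = ""
    pathways_gmt: str = ""
    regulons_gmt: str = ""
    toxscores_csv: str = ""
    annotations_csv: str = ""
    network_tsv: str = ""
    out_dir: str = "results"

    fdr_max: float = 0.05
    gene_min_abs_effect: float = 1.0
    tf_expression_min_abs_effect: float = 0.5
    toxscore_thresholds: dict = dataclasses.field(
        default_factory=lambda: {"null": 0.0, "low": 0.67, "high": 1.34})
    min_adverse_count: int = 5
    min_adverse_fraction: float = 0.5
    alpha: float = 0.05
    edge_min_freq: float = 0.2
    per_series_alpha: float = 0.05
    min_timepoints: int = 6
    min_set_size: int = 5
    background_mode: str = "no_findings_strict"
    scoring_method: str = "kernel_ecdf"
    es_form: str = "max_dev"
    moderation: str = "eb"
    relation: str = "before_or_at"
    include_gene_level: bool = False
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def analyze_study(
    expr: ExpressionData,
    pathways: GeneSetCollection,
    regulons: GeneSetCollection,
    toxscores: pd.DataFrame,
    annotations: pd.DataFrame,
    network: InteractionNetwork,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every analysis stage in memory and return the result tables.

    Keys: differential, histo_labels, finding_selection, outcomes,
    activations, concordance, tf_modes, cascade_graph, cascade_edges,
    time_dependence, joint.
    """
    config = config or PipelineConfig()
    results: dict = {}

    regulons = regulons.filter_confidence(("A", "B", "C")).drop_negative_members()
    pathways, _ = pathways.filter_to_universe(expr.genes, config.min_set_size)
    regulons, _ = regulons.filter_to_universe(expr.genes, config.min_set_size)

    pieces = []
    if len(pathways):
        act_pw = score_per_compound(expr, pathways, method=config.scoring_method,
                                    es=config.es_form, min_size=config.min_set_size)
        results["activity_pathway"] = act_pw
        pieces.append(differential(act_pw, expr.sheet, level="pathway",
                                   moderation=config.moderation))
    if len(regulons):
        act_tf = score_per_compound(expr, regulons, method=config.scoring_method,
                                    es=config.es_form, min_size=config.min_set_size)
        results["activity_tf"] = act_tf
        pieces.append(differential(act_tf, expr.sheet, level="tf_activity",
                                   moderation=config.moderation))
        tf_genes = [g for g in regulons.sets if g in set(expr.genes)]
        if tf_genes:
            pieces.append(differential(expr.matrix.loc[tf_genes], expr.sheet,
                                       level="tf_expression",
                                       moderation=config.moderation))
    if config.include_gene_level:
        pieces.append(differential(expr.matrix, expr.sheet, level="gene",
                                   moderation=config.moderation))
    if not pieces:
        raise ValidationError("no gene sets or gene-level analysis requested")
    diff = add_fdr(pd.concat(pieces, ignore_index=True))
    results["differential"] = diff

    labels = binarize_toxscores(toxscores, config.toxscore_thresholds)
    selection = select_adverse_findings(
        labels, annotations, config.min_adverse_count, config.min_adverse_fraction)
    adverse_labels = set(selection.loc[selection["selected"], "label"])
    outcomes = first_adverse_time(labels, adverse_labels, annotations,
                                  config.background_mode)
    keep = {(k.compound, k.dose_level)
            for k in expr.sheet.series_keys(config.min_timepoints)}
    outcomes = outcomes.loc[[
        (c, d) in keep
        for c, d in zip(outcomes["compound"], outcomes["dose_level"])]].reset_index(drop=True)
    results["histo_labels"] = labels
    results["finding_selection"] = selection
    results["outcomes"] = outcomes

    crit_sets = ActivationCriteria(config.fdr_max, 0.0)
    crit_by_level = {
        "pathway": crit_sets,
        "tf_activity": crit_sets,
        "tf_expression": ActivationCriteria(config.fdr_max,
                                            config.tf_expression_min_abs_effect),
        "gene": ActivationCriteria(config.fdr_max, config.gene_min_abs_effect),
    }
    act_pieces = []
    for level, crit in crit_by_level.items():
        sub = diff.loc[diff["level"] == level]
        if len(sub):
            act_pieces.append(first_activation(sub, crit))
    acts = pd.concat(act_pieces, ignore_index=True)
    acts = acts.loc[[
        (c, d) in keep
        for c, d in zip(acts["compound"], acts["dose_level"])]].reset_index(drop=True)
    results["activations"] = acts

    conc_pieces = []
    for level, crit in crit_by_level.items():
        if (acts["level"] == level).any():
            conc_pieces.append(concordance_table(
                acts, outcomes, diff=diff, criteria=crit, levels=[level],
                relation=config.relation))
    conc = pd.concat(conc_pieces, ignore_index=True)
    results["concordance"] = conc
    log.info("concordance: %d events tested, %d enriched at p<%g",
             len(conc), int((conc["p"] < config.alpha).sum()), config.alpha)

    tf_modes = classify_tf_regulation(conc, acts, outcomes, config.alpha)
    graph = build_cascade(network, conc, tf_modes, acts, outcomes,
                          config.edge_min_freq, config.alpha)
    results["tf_modes"] = tf_modes
    results["cascade_graph"] = graph
    results["cascade_edges"] = cascade_edge_table(graph)

    adverse_series = outcomes.loc[outcomes["is_adverse"], SERIES]
    dep_levels = [lv for lv in ("pathway", "tf_activity", "gene")
                  if (diff["level"] == lv).any()]
    dep = time_dependence(diff, adverse_series, config.per_series_alpha,
                          levels=dep_levels)
    results["time_dependence"] = dep
    results["joint"] = concordance_vs_dependence(conc, dep, config.alpha, config.alpha)
    return results


_TABLE_OUTPUTS = [
    ("differential", "differential.tsv"),
    ("histo_labels", "histo_labels.tsv"),
    ("finding_selection", "finding_selection.tsv"),
    ("outcomes", "outcomes.tsv"),
    ("activations", "activations.tsv"),
    ("concordance", "concordance.tsv"),
    ("tf_modes", "tf_modes.tsv"),
    ("cascade_edges", "cascade_edges.tsv"),
    ("time_dependence", "time_dependence.tsv"),
    ("joint", "concordance_vs_dependence.tsv"),
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Read the configured inputs, run :func:`analyze_study` and write every
    stage table plus a manifest under ``out_dir``. Any stage error halts the
    run with the stage name attached."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        expr = io.read_expression(config.expression_tsv, config.sheet_csv)
        pathways = io.read_gmt(config.pathways_gmt, kind="pathway")
        regulons = io.read_gmt(config.regulons_gmt, kind="regulon")
        tox = io.read_toxscores(config.toxscores_csv)
        annotations = io.read_adverse_annotations(config.annotations_csv)
        network = io.read_network(config.network_tsv)

        stage = "analyze"
        results = analyze_study(expr, pathways, regulons, tox, annotations,
                                network, config)

        stage = "write_outputs"
        for key, fname in _TABLE_OUTPUTS:
            io.write_table(results[key], out / fname)
        for key in ("activity_pathway", "activity_tf"):
            if key in results:
                io.write_table(results[key].rename_axis("set").reset_index(),
                               out / f"{key}.tsv")
        export_cascade(results["cascade_graph"], out / "cascade.sif", "sif")

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "config_sha256": config.digest(),
            "seed": config.rng_seed,
            "versions": {
                "toxcascade": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": sorted(f for _, f in _TABLE_OUTPUTS),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
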