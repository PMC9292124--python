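"""Seed-reproducible synthetic study generator with planted ground truth.

The generator emulates the repeat-dose study design the pipeline targets:
per compound-dose time series over 8 timepoints spanning 3 h to 4 weeks,
3 treated and 3 vehicle-control replicates per timepoint, log2-scale
expression with i.i.d. Gaussian noise around per-gene baselines. Planted
gene-set events shift their member genes by a configured effect in treated
samples from a configured onset onward — in penetrant adverse series at the
planted onset, and in background series at a random onset with a configured
background rate — so every downstream stage has a ground-truth surface.
Planted histopathology findings follow configured toxscore trajectories in
adverse series; background series carry no findings at all.

Effects enter at the gene level so activity scoring and differential
testing are exercised end-to-end; :func:`shortcut_activations` is a fast
score-level generator for unit tests of the downstream stages.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ExpressionData,
    GeneSetCollection,
    InteractionNetwork,
    SampleSheet,
    ValidationError,
)

log = logging.getLogger(__name__)

SERIES = ["compound", "dose_level"]

DEFAULT_TIMEPOINTS = (3.0, 6.0, 9.0, 24.0, 96.0, 192.0, 360.0, 672.0)


@dataclasses.dataclass
class PlantedEvent:
    """One planted directional gene-set event.

    ``level`` is "pathway" or "tf"; a TF event plants both the regulon
    member genes (from ``onset_h``, driving the tf_activity event) and the
    TF's own expression gene (from ``expr_onset_h``, driving the
    tf_expression event).
    """

    name: str
    level: str
    onset_h: float
    effect: float
    direction: str = "up"
    penetrance: float = 1.0
    background_rate: float = 0.0
    set_size: int = 10
    expr_onset_h: float | None = None


@dataclasses.dataclass
class PlantedFinding:
    """A histopathology finding with a toxscore trajectory over time
    (times absent from the mapping score 0)."""

    finding: str
    toxscores: dict[float, float]

    @property
    def onset_h(self) -> float:
        pos = [t for t, s in self.toxscores.items() if s > 0]
        return min(pos) if pos else float("nan")


@dataclasses.dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator."""

    n_adverse: int = 10
    n_background: int = 20
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    doses_per_compound: int = 1
    n_genes: int = 500
    n_pathway_sets: int = 40
    n_tfs: int = 5
    pathway_size: tuple[int, int] = (8, 15)
    regulon_size: int = 10
    events: list[PlantedEvent] = dataclasses.field(default_factory=list)
    findings: list[PlantedFinding] = dataclasses.field(default_factory=list)
    network_edges: list[tuple] = dataclasses.field(default_factory=list)
    cascade_edges: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    decoy_activation_rate: float = 0.0
    gene_event_rate: float = 0.0
    decoy_effect: float | None = None
    sigma: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    min_set_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("noise sigma must be positive")
        tps = set(float(t) for t in self.timepoints_h)
        for ev in self.events:
            if ev.set_size < self.min_set_size:
                raise ValidationError(
                    f"planted set {ev.name!r} smaller than min_size {self.min_set_size}")
            if not (0 <= ev.penetrance <= 1 and 0 <= ev.background_rate <= 1):
                raise ValidationError("penetrance and background_rate must lie in [0,1]")
            if float(ev.onset_h) not in tps:
                raise ValidationError(f"onset {ev.onset_h} of {ev.name!r} not a timepoint")
            if ev.expr_onset_h is not None and float(ev.expr_onset_h) not in tps:
                raise ValidationError(f"expression onset of {ev.name!r} not a timepoint")
            if ev.level not in ("pathway", "tf"):
                raise ValidationError(f"unknown planted level {ev.level!r}")


@dataclasses.dataclass
class TruthTable:
    """Ground truth emitted alongside the data, consistent by construction."""

    events: pd.DataFrame    # compound, dose_level, entity, level, direction, true_onset_h
    outcomes: pd.DataFrame  # compound, dose_level, is_adverse, finding_onset_h
    edges: pd.DataFrame     # source, target (planted cascade order)


@dataclasses.dataclass
class SimData:
    expr: ExpressionData
    pathways: GeneSetCollection
    regulons: GeneSetCollection
    toxscores: pd.DataFrame
    annotations: pd.DataFrame
    network: InteractionNetwork
    truth: TruthTable


def _series_list(config: SimConfig) -> list[tuple[str, str, bool]]:
    out = []
    for i in range(config.n_adverse):
        for d in range(config.doses_per_compound):
            out.append((f"adv{i + 1:03d}", f"dose{d + 1}", True))
    for i in range(config.n_background):
        for d in range(config.doses_per_compound):
            out.append((f"bg{i + 1:03d}", f"dose{d + 1}", False))
    return out


def simulate(config: SimConfig) -> SimData:
    """Generate the full synthetic input bundle plus its truth table.

    Identical config and seed yield byte-identical written outputs.
    """
    rng = np.random.default_rng(config.seed)
    tps = [float(t) for t in config.timepoints_h]

    # --- gene universe ------------------------------------------------------
    pool = [f"G{i:05d}" for i in range(config.n_genes)]
    genes: list[str] = list(pool)
    planted_members: dict[str, list[str]] = {}
    tf_entities: list[str] = []
    for ev in config.events:
        block = [f"{ev.name}_m{j:02d}" for j in range(ev.set_size)]
        planted_members[ev.name] = block
        genes.extend(block)
        if ev.level == "tf":
            genes.append(ev.name)  # the TF's own expression gene
            tf_entities.append(ev.name)

    decoy_tfs = [f"Tf{i + 1:02d}" for i in range(config.n_tfs)]
    genes.extend(decoy_tfs)

    # --- gene sets ----------------------------------------------------------
    lo, hi = config.pathway_size
    pw_sets = {}
    for i in range(config.n_pathway_sets):
        size = int(rng.integers(lo, hi + 1))
        pw_sets[f"PW{i + 1:03d}"] = frozenset(rng.choice(pool, size=size, replace=False))
    reg_sets = {}
    for tf in decoy_tfs:
        reg_sets[tf] = frozenset(rng.choice(pool, size=config.regulon_size, replace=False))
    for ev in config.events:
        members = frozenset(planted_members[ev.name])
        if ev.level == "pathway":
            pw_sets[ev.name] = members
        else:
            reg_sets[ev.name] = members
    pathways = GeneSetCollection(pw_sets, kind="pathway")
    regulons = GeneSetCollection(
        reg_sets, kind="regulon",
        confidence={name: "A" for name in reg_sets})

    # --- samples ------------------------------------------------------------
    series = _series_list(config)
    compounds = sorted({c for c, _, _ in series})
    sheet_rows = []
    for compound in compounds:
        doses = sorted({d for c, d, _ in series if c == compound})
        for t in tps:
            for r in range(1, config.n_replicates + 1):
                sheet_rows.append((f"{compound}_veh_{t:g}h_r{r}", compound,
                                   "vehicle", t, r, True))
            for dose in doses:
                for r in range(1, config.n_replicates + 1):
                    sheet_rows.append((f"{compound}_{dose}_{t:g}h_r{r}", compound,
                                       dose, t, r, False))
    sheet = pd.DataFrame(sheet_rows, columns=[
        "sample_id", "compound", "dose_level", "time_h", "replicate", "is_control"])

    # --- expression ---------------------------------------------------------
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    X = mu[:, None] + rng.normal(0.0, config.sigma, size=(len(genes), len(sheet)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    # treated column positions and times per series (X columns follow sheet order)
    treated_cols: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    tr = sheet.loc[~sheet["is_control"]]
    for key, grp in tr.groupby(["compound", "dose_level"]):
        treated_cols[key] = (grp.index.to_numpy(), grp["time_h"].to_numpy())

    def _cols(compound: str, dose: str, onset: float) -> np.ndarray:
        idx, times = treated_cols[(compound, dose)]
        return idx[times >= onset]

    # --- planting -----------------------------------------------------------
    truth_rows = []
    for ev in config.events:
        sgn = 1.0 if ev.direction == "up" else -1.0
        member_idx = np.array([gene_pos[g] for g in planted_members[ev.name]])
        for compound, dose, is_adv in series:
            if is_adv:
                active = rng.random() < ev.penetrance
                onset = float(ev.onset_h)
                expr_onset = float(ev.expr_onset_h if ev.expr_onset_h is not None
                                   else ev.onset_h)
            else:
                active = rng.random() < ev.background_rate
                onset = float(rng.choice(tps))
                expr_onset = onset
            if not active:
                continue
            cols = _cols(compound, dose, onset)
            X[np.ix_(member_idx, cols)] += sgn * ev.effect
            level = "pathway" if ev.level == "pathway" else "tf_activity"
            truth_rows.append((compound, dose, ev.name, level, ev.direction, onset))
            if ev.level == "tf":
                ecols = _cols(compound, dose, expr_onset)
                X[gene_pos[ev.name], ecols] += sgn * ev.effect
                truth_rows.append((compound, dose, ev.name, "tf_expression",
                                   ev.direction, expr_onset))

    # --- bystander (outcome-independent) activity ---------------------------
    # Non-adverse compounds still perturb expression: decoy sets and decoy
    # TFs activate in any series at `decoy_activation_rate`, with a random
    # onset and direction, independent of the adverse outcome. This is what
    # makes background series carry events at all (the evaluability rule
    # needs signal of the right level in the background window).
    decoy_effect = config.decoy_effect if config.decoy_effect is not None \
        else 2.0 * config.sigma
    if config.decoy_activation_rate > 0:
        planted_names = {ev.name for ev in config.events}
        decoy_items = [
            ("pathway", name, sorted(pw_sets[name]), None)
            for name in sorted(pw_sets) if name not in planted_names
        ] + [
            ("tf", name, sorted(reg_sets[name]), name)
            for name in sorted(reg_sets) if name not in planted_names
        ]
        for level, name, members, tf_gene in decoy_items:
            member_idx = np.array([gene_pos[g] for g in members])
            for compound, dose, _is_adv in series:
                active = rng.random() < config.decoy_activation_rate
                onset = float(rng.choice(tps))
                sgn = 1.0 if rng.random() < 0.5 else -1.0
                if not active:
                    continue
                cols = _cols(compound, dose, onset)
                X[np.ix_(member_idx, cols)] += sgn * decoy_effect
                direction = "up" if sgn > 0 else "down"
                truth_level = "pathway" if level == "pathway" else "tf_activity"
                truth_rows.append((compound, dose, name, truth_level, direction, onset))
                if tf_gene is not None:
                    X[gene_pos[tf_gene], cols] += sgn * decoy_effect
                    truth_rows.append((compound, dose, name, "tf_expression",
                                       direction, onset))
    if config.gene_event_rate > 0:
        # single-gene events at equal rate in every series (complete null
        # with respect to the outcome), for type-I-error studies
        for gi, gene in enumerate(pool):
            for compound, dose, _is_adv in series:
                active = rng.random() < config.gene_event_rate
                onset = float(rng.choice(tps))
                sgn = 1.0 if rng.random() < 0.5 else -1.0
                if not active:
                    continue
                cols = _cols(compound, dose, onset)
                X[gi, cols] += sgn * decoy_effect
                truth_rows.append((compound, dose, gene, "gene",
                                   "up" if sgn > 0 else "down", onset))

    expr = ExpressionData(
        pd.DataFrame(X, index=genes, columns=sheet["sample_id"]), SampleSheet(sheet))

    # --- histopathology -----------------------------------------------------
    tox_rows = []
    outcome_rows = []
    for compound, dose, is_adv in series:
        onset = float("nan")
        if is_adv:
            for f in config.findings:
                for t, score in sorted(f.toxscores.items()):
                    if score > 0:
                        tox_rows.append((compound, dose, float(t), f.finding, float(score)))
                if not np.isnan(f.onset_h):
                    onset = f.onset_h if np.isnan(onset) else min(onset, f.onset_h)
        outcome_rows.append((compound, dose, is_adv, onset))
    toxscores = pd.DataFrame(
        tox_rows, columns=SERIES + ["time_h", "finding", "toxscore"])
    annotations = pd.DataFrame(
        [(c, d, adv) for c, d, adv in series], columns=SERIES + ["is_adverse"])

    # --- network ------------------------------------------------------------
    net_rows = [
        {"source": s, "target": t, "sign": sign, "kind": kind,
         "confidence": conf, "provenance": "synthetic"}
        for (s, t, sign, kind, conf) in config.network_edges]
    network = InteractionNetwork(pd.DataFrame(
        net_rows, columns=["source", "target", "sign", "kind", "confidence", "provenance"])
        if net_rows else pd.DataFrame(
            {"source": pd.Series(dtype=str), "target": pd.Series(dtype=str),
             "sign": pd.Series(dtype=int), "kind": pd.Series(dtype=str),
             "confidence": pd.Series(dtype=str), "provenance": pd.Series(dtype=str)}))

    truth = TruthTable(
        events=pd.DataFrame(truth_rows, columns=SERIES + [
            "entity", "level", "direction", "true_onset_h"]),
        outcomes=pd.DataFrame(outcome_rows, columns=SERIES + [
            "is_adverse", "finding_onset_h"]),
        edges=pd.DataFrame(config.cascade_edges, columns=["source", "target"])
        if config.cascade_edges else pd.DataFrame(columns=["source", "target"]),
    )
    return SimData(expr, pathways, regulons, toxscores, annotations, network, truth)


def null_dataset(config: SimConfig) -> SimData:
    """The same design with no planted expression structure: findings (and
    hence the later event) remain for adverse series, but no gene-set event
    depends on the outcome. Used for type-I-error suites."""
    cfg = dataclasses.replace(config, events=[], cascade_edges=[])
    return simulate(cfg)


def shortcut_activations(
    config: SimConfig,
    events: list[PlantedEvent] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score-level shortcut: emit (activations, outcomes) directly, without
    expression or differential testing, for fast unit tests of the
    concordance/cascade/timedep stages. Planted events first-activate at
    their onset in penetrant adverse series and at a random timepoint in
    background series at the background rate."""
    rng = np.random.default_rng(config.seed)
    tps = [float(t) for t in config.timepoints_h]
    events = config.events if events is None else events
    series = _series_list(config)
    act_rows = []
    for ev in events:
        level = "pathway" if ev.level == "pathway" else "tf_activity"
        for compound, dose, is_adv in series:
            if is_adv and rng.random() < ev.penetrance:
                act_rows.append((compound, dose, ev.name, level, ev.direction,
                                 float(ev.onset_h)))
            elif not is_adv and rng.random() < ev.background_rate:
                act_rows.append((compound, dose, ev.name, level, ev.direction,
                                 float(rng.choice(tps))))
    activations = pd.DataFrame(act_rows, columns=SERIES + [
        "entity", "level", "direction", "first_time_h"])
    onset = min((f.onset_h for f in config.findings), default=float("nan"))
    outcome_rows = [
        (c, d, adv, onset if adv else float("nan"), adv, not adv)
        for c, d, adv in series]
    outcomes = pd.DataFrame(outcome_rows, columns=SERIES + [
        "is_adverse", "first_adverse_time_h", "is_background_dummy", "is_background"])
    outcomes = outcomes.drop(columns=["is_background_dummy"])
    return activations, outcomes


# ---------------------------------------------------------------------------
# study presets
# ---------------------------------------------------------------------------

def default_findings() -> list[PlantedFinding]:
    """An adverse finding whose toxscore crosses the "null"/"low" thresholds
    at 192 h and "high" later — the later event first occurs at 192 h."""
    return [PlantedFinding("hepatocellular_necrosis",
                           {192.0: 0.8, 360.0: 1.5, 672.0: 2.0})]


def planted_study_config(
    seed: int = 0,
    n_adverse: int = 40,
    n_background: int = 100,
    n_decoy_sets: int = 199,
    n_decoy_tfs: int = 10,
    sigma: float = 0.5,
    n_genes: int = 1200,
) -> SimConfig:
    """The planted-recovery study: the full design (8 timepoints, 3
    replicates, 40 adverse + 100 background series), one planted pathway
    event at effect 2*sigma, penetrance 0.8, background rate 0.05 among 200
    candidate sets, and a 3-TF induced cascade TfA -> TfB -> TfC with
    staggered expression-before-activity onsets, all before the adverse
    finding at 192 h. The prior network carries the two forward edges plus
    their reverses (which have no temporal support) and decoy edges."""
    events = [
        PlantedEvent("PlantedPW", "pathway", onset_h=24.0, effect=2.0 * sigma,
                     direction="up", penetrance=0.8, background_rate=0.05,
                     set_size=10),
        PlantedEvent("TfA", "tf", onset_h=6.0, expr_onset_h=3.0,
                     effect=3.0 * sigma, direction="down", penetrance=0.9,
                     background_rate=0.02, set_size=10),
        PlantedEvent("TfB", "tf", onset_h=24.0, expr_onset_h=9.0,
                     effect=3.0 * sigma, direction="down", penetrance=0.9,
                     background_rate=0.02, set_size=10),
        PlantedEvent("TfC", "tf", onset_h=192.0, expr_onset_h=96.0,
                     effect=3.0 * sigma, direction="down", penetrance=0.9,
                     background_rate=0.02, set_size=10),
    ]
    network_edges = [
        ("TfA", "TfB", 1, "tf_target", "A"),
        ("TfB", "TfC", 1, "tf_target", "A"),
        ("TfB", "TfA", 1, "tf_target", "A"),   # reverse, no temporal support
        ("TfC", "TfB", 1, "tf_target", "A"),   # reverse, no temporal support
        ("TfA", "TfC", -1, "tf_target", "B"),  # sign-inconsistent decoy
        ("Tf01", "Tf02", 1, "ppi", "C"),       # decoy between null TFs
    ]
    return SimConfig(
        n_adverse=n_adverse, n_background=n_background,
        n_genes=n_genes, n_pathway_sets=n_decoy_sets, n_tfs=n_decoy_tfs,
        events=events, findings=default_findings(),
        network_edges=network_edges,
        cascade_edges=[("TfA", "TfB"), ("TfB", "TfC")],
        decoy_activation_rate=0.1,
        sigma=sigma, seed=seed)


def null_study_config(
    seed: int = 0,
    n_adverse: int = 10,
    n_background: int = 20,
    n_genes: int = 1000,
) -> SimConfig:
    """The type-I-error study: no event depends on the outcome. Candidate
    events are the up/down directional events of the ``n_genes`` genes,
    each activating at an equal, outcome-independent rate in every series
    (random onset), so confusion tables are informative while the null
    of no enrichment holds exactly. Findings remain for adverse series so
    the later event is defined."""
    return SimConfig(
        n_adverse=n_adverse, n_background=n_background, n_genes=n_genes,
        n_pathway_sets=0, n_tfs=0, events=[], findings=default_findings(),
        gene_event_rate=0.1, seed=seed)
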