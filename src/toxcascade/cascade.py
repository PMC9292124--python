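"""TF regulation mode and sign-consistent causal cascade graphs.

A TF whose regulon-activity change is preceded (within the same adverse
time series) by a same-direction change of its own expression is likely
transcriptionally *induced*; a significant activity change without
significant expression points to *post-transcriptional* regulation. The
classified TFs, together with signed prior-knowledge interactions, are then
assembled into a cascade graph: a prior edge between two significantly
enriched events is kept when the node dysregulations match the edge sign
and the upstream event first-activates before-or-at the downstream event in
at least ``edge_min_freq`` of the adverse series where the downstream event
is observed before adverse histopathology.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .events import SERIES
from .types import EventKey, InteractionNetwork, ValidationError

log = logging.getLogger(__name__)

MODES = ("induced", "post_transcriptional", "expression_only",
         "counter_evidence", "untestable", "not_significant")

TF_RECORD_COLUMNS = [
    "tf", "direction", "expr_p", "act_p", "expr_significant", "act_significant",
    "n_qualifying_series", "strict_before_freq", "inclusive_freq", "mode",
]

EDGE_ATTRS = ["sign", "kind", "confidence", "support_count", "denominator",
              "support_freq", "strict_count", "strict_freq"]


def _first_times(activations: pd.DataFrame, entity: str, level: str,
                 direction: str) -> pd.Series:
    sub = activations.loc[
        (activations["entity"] == entity)
        & (activations["level"] == level)
        & (activations["direction"] == direction)
    ]
    return pd.Series(
        sub["first_time_h"].to_numpy(),
        index=pd.MultiIndex.from_frame(sub[SERIES]),
    )


def classify_tf_regulation(
    conc: pd.DataFrame,
    activations: pd.DataFrame,
    outcomes: pd.DataFrame,
    alpha: float = 0.05,
    measured_tf_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Assign each directional TF-activity event a regulation mode.

    ``conc`` is a concordance table containing tf_activity and
    tf_expression rows against the adverse outcome (expression events are
    expected to carry the |logFC| > 0.5 activation criterion upstream).

    Modes: *induced* — both enrichments significant and expression
    first-activates strictly before activity in >= 1 qualifying adverse
    series; *counter_evidence* — both significant but expression never at or
    before activity; *post_transcriptional* — activity significant only (or
    both significant with same-time-only evidence, which is weaker than
    induction); *expression_only*; *untestable* — no expression
    measurements for the TF; *not_significant* otherwise.
    """
    act_rows = conc.loc[conc["level"] == "tf_activity"]
    expr_rows = conc.loc[conc["level"] == "tf_expression"]
    expr_p = {(r.entity, r.direction): r.p for r in expr_rows.itertuples()}
    if measured_tf_genes is None:
        measured_tf_genes = set(
            activations.loc[activations["level"] == "tf_expression", "entity"])

    adv = outcomes.loc[
        outcomes["is_adverse"] & outcomes["first_adverse_time_h"].notna(),
        SERIES + ["first_adverse_time_h"]]
    le_time = pd.Series(
        adv["first_adverse_time_h"].to_numpy(),
        index=pd.MultiIndex.from_frame(adv[SERIES]))

    rows = []
    for r in act_rows.itertuples():
        tf, direction = r.entity, r.direction
        ap = float(r.p)
        ep = expr_p.get((tf, direction), np.nan)
        act_sig = ap < alpha
        expr_sig = bool(np.isfinite(ep) and ep < alpha)

        act_first = _first_times(activations, tf, "tf_activity", direction)
        expr_first = _first_times(activations, tf, "tf_expression", direction)
        qual = act_first.index.intersection(le_time.index)
        qual = qual[act_first.loc[qual].to_numpy() <= le_time.loc[qual].to_numpy()]
        n_qual = len(qual)
        strict = inclusive = 0
        for key in qual:
            if key in expr_first.index:
                if expr_first.loc[key] < act_first.loc[key]:
                    strict += 1
                if expr_first.loc[key] <= act_first.loc[key]:
                    inclusive += 1
        strict_freq = strict / n_qual if n_qual else np.nan
        incl_freq = inclusive / n_qual if n_qual else np.nan

        if tf not in measured_tf_genes:
            mode = "untestable"
        elif act_sig and expr_sig:
            if n_qual and strict > 0:
                mode = "induced"
            elif n_qual and inclusive == 0:
                mode = "counter_evidence"
            else:
                mode = "post_transcriptional"
        elif act_sig:
            mode = "post_transcriptional"
        elif expr_sig:
            mode = "expression_only"
        else:
            mode = "not_significant"
        rows.append({
            "tf": tf, "direction": direction, "expr_p": ep, "act_p": ap,
            "expr_significant": expr_sig, "act_significant": act_sig,
            "n_qualifying_series": n_qual,
            "strict_before_freq": strict_freq, "inclusive_freq": incl_freq,
            "mode": mode,
        })
    return pd.DataFrame(rows, columns=TF_RECORD_COLUMNS)


def _edge_support(
    src_first: pd.Series,
    tgt_first: pd.Series,
    le_time: pd.Series,
) -> tuple[int, int, int]:
    """(inclusive support count, strict count, denominator): the denominator
    is the number of adverse series where the target event occurs
    before-or-at the first LE time."""
    denom_idx = tgt_first.index.intersection(le_time.index)
    denom_idx = denom_idx[
        tgt_first.loc[denom_idx].to_numpy() <= le_time.loc[denom_idx].to_numpy()]
    support = strict = 0
    for key in denom_idx:
        if key in src_first.index:
            if src_first.loc[key] <= tgt_first.loc[key]:
                support += 1
            if src_first.loc[key] < tgt_first.loc[key]:
                strict += 1
    return support, strict, len(denom_idx)


def build_cascade(
    network: InteractionNetwork,
    conc: pd.DataFrame,
    tf_modes: pd.DataFrame,
    activations: pd.DataFrame,
    outcomes: pd.DataFrame,
    edge_min_freq: float = 0.2,
    alpha: float = 0.05,
) -> nx.DiGraph:
    """Assemble the sign-consistent cascade graph over prior-knowledge edges.

    Candidate nodes are directional events significantly enriched
    before-or-at the later event. For each prior edge, direction pairs must
    satisfy the edge sign (positive: same direction; negative: opposite).
    ppi edges connect activity events directly; tf_target edges require the
    target TF to be *induced* and are routed through the target's expression
    event (expression precedes activity), adding an induction edge
    expression -> activity. An edge is kept iff its inclusive temporal
    support frequency reaches ``edge_min_freq``; the strict-before support
    is carried as an edge attribute, not a filter.
    """
    sig = conc.loc[conc["p"] < alpha]
    sig_act = {(r.entity, r.direction) for r in
               sig.loc[sig["level"] == "tf_activity"].itertuples()}
    induced = {(r.tf, r.direction) for r in tf_modes.itertuples() if r.mode == "induced"}
    mode_rec = {(r.tf, r.direction): r for r in tf_modes.itertuples()}

    adv = outcomes.loc[
        outcomes["is_adverse"] & outcomes["first_adverse_time_h"].notna(),
        SERIES + ["first_adverse_time_h"]]
    le_time = pd.Series(
        adv["first_adverse_time_h"].to_numpy(),
        index=pd.MultiIndex.from_frame(adv[SERIES]))

    graph = nx.DiGraph()

    def node(entity: str, level: str, direction: str) -> str:
        key = EventKey(entity, level, direction).label()
        if key not in graph:
            graph.add_node(key, entity=entity, level=level, direction=direction)
        return key

    for e in network.edges.itertuples():
        for ds in ("up", "down"):
            dt = ds if e.sign > 0 else ("down" if ds == "up" else "up")
            if (e.source, ds) not in sig_act:
                continue
            src_first = _first_times(activations, e.source, "tf_activity", ds)
            if e.kind == "ppi":
                if (e.target, dt) not in sig_act:
                    continue
                tgt_first = _first_times(activations, e.target, "tf_activity", dt)
                support, strict, denom = _edge_support(src_first, tgt_first, le_time)
                if denom == 0 or support / denom < edge_min_freq:
                    continue
                graph.add_edge(
                    node(e.source, "tf_activity", ds), node(e.target, "tf_activity", dt),
                    sign=int(e.sign), kind="ppi", confidence=e.confidence,
                    support_count=support, denominator=denom,
                    support_freq=support / denom,
                    strict_count=strict, strict_freq=strict / denom)
            elif e.kind == "tf_target":
                if (e.target, dt) not in induced:
                    continue
                tgt_expr_first = _first_times(activations, e.target, "tf_expression", dt)
                support, strict, denom = _edge_support(src_first, tgt_expr_first, le_time)
                if denom == 0 or support / denom < edge_min_freq:
                    continue
                expr_node = node(e.target, "tf_expression", dt)
                graph.add_edge(
                    node(e.source, "tf_activity", ds), expr_node,
                    sign=int(e.sign), kind="tf_target", confidence=e.confidence,
                    support_count=support, denominator=denom,
                    support_freq=support / denom,
                    strict_count=strict, strict_freq=strict / denom)
                # central-dogma induction edge: expression precedes activity
                act_node = node(e.target, "tf_activity", dt)
                if not graph.has_edge(expr_node, act_node):
                    rec = mode_rec[(e.target, dt)]
                    n_q = int(rec.n_qualifying_series)
                    incl = int(round(rec.inclusive_freq * n_q)) if n_q else 0
                    strict_n = int(round(rec.strict_before_freq * n_q)) if n_q else 0
                    graph.add_edge(
                        expr_node, act_node,
                        sign=1, kind="induction", confidence="",
                        support_count=incl, denominator=n_q,
                        support_freq=incl / n_q if n_q else np.nan,
                        strict_count=strict_n,
                        strict_freq=strict_n / n_q if n_q else np.nan)
    return graph


def cascade_edge_table(graph: nx.DiGraph) -> pd.DataFrame:
    rows = []
    for u, v, data in graph.edges(data=True):
        rows.append({"source": u, "target": v, **{k: data.get(k) for k in EDGE_ATTRS}})
    return pd.DataFrame(rows, columns=["source", "target"] + EDGE_ATTRS)


def export_cascade(graph: nx.DiGraph, path: str | Path, fmt: str = "tsv") -> None:
    """Write the cascade graph as ``tsv`` (edge list with attributes),
    ``sif`` (one ``source kind target`` line per edge) or ``graphml``."""
    path = Path(path)
    if fmt == "tsv":
        cascade_edge_table(graph).to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in graph.edges(data=True):
                fh.write(f"{u}\t{data.get('kind', 'edge')}\t{v}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from((n, {k: v for k, v in d.items()}) for n, d in graph.nodes(data=True))
        for u, v, d in graph.edges(data=True):
            g.add_edge(u, v, **{k: ("" if vv is None else vv) for k, vv in d.items()})
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown cascade export format {fmt!r}")


def import_cascade(path: str | Path) -> nx.DiGraph:
    """Read back a TSV cascade export (round-trip inverse of ``tsv``)."""
    df = pd.read_csv(path, sep="\t")
    graph = nx.DiGraph()
    for r in df.itertuples(index=False):
        rec = r._asdict()
        u, v = rec.pop("source"), rec.pop("target")
        for n in (u, v):
            if n not in graph:
                entity, level, direction = n.split("|")
                graph.add_node(n, entity=entity, level=level, direction=direction)
        graph.add_edge(u, v, **{k: rec.get(k) for k in EDGE_ATTRS})
    return graph
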