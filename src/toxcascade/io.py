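"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices are TSV (gene rows, sample columns), sample sheets CSV,
gene sets GMT, interaction networks TSV, toxscores CSV. Every writer is the
inverse of its reader for the declared fields, and every reader validates;
malformed input raises :class:`~toxcascade.types.ValidationError` rather than
being silently dropped (the one logged exception is the min-size gene-set
filter).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EDGE_COLUMNS,
    SHEET_COLUMNS,
    ExpressionData,
    GeneSetCollection,
    InteractionNetwork,
    SampleSheet,
    ValidationError,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

_SIGN_ALIASES = {
    "+1": 1, "1": 1, "+": 1, "activation": 1,
    "-1": -1, "-": -1, "inhibition": -1,
}


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = sheet.frame.copy()
    df["is_control"] = df["is_control"].map({True: "true", False: "false"})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_expression(matrix_path: str | Path, sheet_path: str | Path) -> ExpressionData:
    """Read a gene x sample TSV matrix plus its CSV sample sheet.

    Raises a hard error for duplicate gene rows, sheet samples absent from
    the matrix, or treated conditions lacking a matched vehicle control.
    """
    sheet = read_sample_sheet(sheet_path)
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    return ExpressionData(mat, sheet)


def write_expression(expr: ExpressionData, matrix_path: str | Path, sheet_path: str | Path) -> None:
    mat = expr.matrix.copy()
    mat.index.name = "gene"
    mat.to_csv(matrix_path, sep="\t", float_format="%.17g")
    write_sample_sheet(expr.sheet, sheet_path)


def read_gmt(path: str | Path, min_size: int = 0, kind: str = "pathway") -> GeneSetCollection:
    """Read a standard GMT file (name, description, tab-separated members).

    Members are deduplicated (set semantics). Sets with fewer than
    ``min_size`` members are dropped and logged; intersection with an
    expression universe is applied later via
    :meth:`GeneSetCollection.filter_to_universe`.

    The description field round-trips a ``confidence=X`` tag for regulons.
    """
    sets: dict[str, frozenset[str]] = {}
    confidence: dict[str, str] = {}
    dropped = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            s = frozenset(members)
            if len(s) < min_size:
                dropped.append(name)
                continue
            sets[name] = s
            if desc.startswith("confidence="):
                confidence[name] = desc.split("=", 1)[1]
    if dropped:
        log.info("read_gmt: dropped %d sets below min_size=%d: %s",
                 len(dropped), min_size, dropped[:10])
    return GeneSetCollection(sets, kind=kind, confidence=confidence)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            desc = f"confidence={coll.confidence[name]}" if name in coll.confidence else "na"
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a signed interaction TSV (source, target, sign, kind, confidence
    [, provenance]). Signs may be +1/-1/+/-/activation/inhibition. Self-loops
    are retained with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["source", "target", "sign", "kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: network TSV missing columns {missing}")
    signs = []
    for i, raw in enumerate(df["sign"], start=2):
        key = str(raw).strip().lower()
        if key not in _SIGN_ALIASES:
            raise ValidationError(f"{path}: line {i}: unparseable sign {raw!r}")
        signs.append(_SIGN_ALIASES[key])
    df["sign"] = signs
    loops = df.loc[df["source"] == df["target"]]
    if len(loops):
        log.warning("read_network: %d self-loop edge(s) retained: %s",
                    len(loops), list(loops["source"])[:5])
    return InteractionNetwork(df)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    df = net.edges.copy()
    df["sign"] = df["sign"].map({1: "+1", -1: "-1"})
    df.to_csv(path, sep="\t", index=False)


def read_toxscores(path: str | Path) -> pd.DataFrame:
    """Read a toxscore CSV: compound, dose_level, time_h, finding, toxscore.

    Toxscores are replicate-averaged severity grades in [0, 4]; absent
    (compound, dose, time, finding) entries mean toxscore 0.
    """
    df = pd.read_csv(path)
    required = ["compound", "dose_level", "time_h", "finding", "toxscore"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: toxscore CSV missing columns {missing}")
    df = df[required].copy()
    df["compound"] = df["compound"].astype(str)
    df["dose_level"] = df["dose_level"].astype(str)
    df["time_h"] = df["time_h"].astype(float)
    df["finding"] = df["finding"].astype(str)
    df["toxscore"] = df["toxscore"].astype(float)
    if ((df["toxscore"] < 0) | (df["toxscore"] > 4)).any():
        raise ValidationError("toxscores must lie in [0, 4]")
    return df


def write_toxscores(tox: pd.DataFrame, path: str | Path) -> None:
    tox.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_adverse_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-series adverse/non-adverse annotations (external expert
    classification): compound, dose_level, is_adverse."""
    df = pd.read_csv(path)
    required = ["compound", "dose_level", "is_adverse"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: annotation CSV missing columns {missing}")
    df = df[required].copy()
    df["compound"] = df["compound"].astype(str)
    df["dose_level"] = df["dose_level"].astype(str)
    if df["is_adverse"].dtype == object:
        df["is_adverse"] = df["is_adverse"].astype(str).str.lower().isin(["true", "1", "yes"])
    df["is_adverse"] = df["is_adverse"].astype(bool)
    return df


def write_adverse_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    df = ann.copy()
    df["is_adverse"] = df["is_adverse"].map({True: "true", False: "false"})
    df.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline result table as TSV with full-precision floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
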