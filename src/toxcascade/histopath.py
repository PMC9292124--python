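"""Histopathology toxscores, severity labels and first adverse time.

Per-animal lesion severity grades (normal/minimal/slight/moderate/marked/
severe) are mapped to 0..4 and replicate-averaged into a *toxscore* per
(compound, dose, time, finding). Each finding is then binarised at three
severity thresholds — "null" (toxscore > 0), "low" (> 0.67) and
"high" (> 1.34), strict inequalities — into histopathology labels.
Labels frequent and specific among expert-annotated adverse series are
selected as *adverse histopathology*; the earliest occurrence of any
selected label within a time series approximates the time of the primary
adverse phenotype.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import TimeSeriesKey, ValidationError

log = logging.getLogger(__name__)

GRADE_MAP = {
    "normal": 0.0,
    "minimal": 1.0,
    "slight": 2.0,
    "moderate": 3.0,
    "marked": 4.0,
    "severe": 4.0,
}

DEFAULT_THRESHOLDS = {"null": 0.0, "low": 0.67, "high": 1.34}

SERIES = ["compound", "dose_level"]


def compute_toxscore(grades: list[str]) -> float:
    """Replicate-averaged numeric severity of one finding at one condition."""
    if not grades:
        raise ValidationError("empty grade list")
    vals = []
    for g in grades:
        key = str(g).strip().lower()
        if key not in GRADE_MAP:
            raise ValidationError(f"unknown severity grade {g!r}")
        vals.append(GRADE_MAP[key])
    return float(np.mean(vals))


def binarize_toxscores(
    tox: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Binary label presence per (series, time, finding, threshold).

    Presence is ``toxscore > threshold`` (strict), so presence is monotone
    across thresholds: a toxscore of 1 carries both "null" and "low" but not
    "high". Only present labels are returned; absent toxscore entries mean 0
    and never yield a label.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    vals = sorted(thresholds.values())
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValidationError("thresholds must be strictly increasing")
    rows = []
    for name, thr in sorted(thresholds.items(), key=lambda kv: kv[1]):
        hit = tox.loc[tox["toxscore"] > thr,
                      SERIES + ["time_h", "finding", "toxscore"]].copy()
        hit["threshold_name"] = name
        hit["threshold_value"] = thr
        hit["label"] = hit["finding"] + "|" + name
        rows.append(hit)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=SERIES + ["time_h", "finding", "toxscore",
                          "threshold_name", "threshold_value", "label"])
    return out.sort_values(SERIES + ["time_h", "label"], ignore_index=True)


def select_adverse_findings(
    labels: pd.DataFrame,
    annotations: pd.DataFrame,
    min_adverse_count: int = 5,
    min_adverse_fraction: float = 0.5,
) -> pd.DataFrame:
    """Select labels that are frequent and specific to adverse series.

    A label occurs in a series if present at any of its timepoints. Selected
    iff (occurrences among adverse series >= min_adverse_count) and
    (adverse occurrences / all occurrences >= min_adverse_fraction).
    Returns one row per label with counts and the ``selected`` flag.
    """
    adverse = annotations.loc[annotations["is_adverse"], SERIES]
    if len(adverse) == 0:
        raise ValidationError("no series annotated as adverse")
    adv_keys = set(map(tuple, adverse.itertuples(index=False)))
    occ = labels[SERIES + ["label"]].drop_duplicates()
    occ["in_adverse"] = [
        (c, d) in adv_keys for c, d in zip(occ["compound"], occ["dose_level"])]
    grp = occ.groupby("label").agg(
        n_adverse=("in_adverse", "sum"), n_total=("in_adverse", "size"))
    grp["fraction_adverse"] = grp["n_adverse"] / grp["n_total"]
    grp["selected"] = (grp["n_adverse"] >= min_adverse_count) & (
        grp["fraction_adverse"] >= min_adverse_fraction)
    return grp.reset_index()


def first_adverse_time(
    labels: pd.DataFrame,
    adverse_labels: set[str] | list[str],
    annotations: pd.DataFrame,
    background_mode: str = "no_findings_strict",
) -> pd.DataFrame:
    """Per-series adverse outcome: earliest occurrence of any selected
    adverse label, the labels present at that earliest time (the primary
    adverse phenotype), and the background flag.

    ``background_mode="no_findings_strict"`` (default): background series
    have no histological finding of any kind *and* belong to a compound not
    annotated adverse at any dose. ``"non_adverse"`` relaxes to all series
    not annotated adverse.
    """
    adverse_labels = set(adverse_labels)
    ann = annotations[SERIES + ["is_adverse"]].drop_duplicates()
    out = ann.copy()

    sel = labels.loc[labels["label"].isin(adverse_labels)]
    first = sel.groupby(SERIES)["time_h"].min().rename("first_adverse_time_h")
    out = out.merge(first, on=SERIES, how="left")

    trig = (
        sel.merge(first.reset_index(), on=SERIES)
        .loc[lambda d: d["time_h"] == d["first_adverse_time_h"]]
        .groupby(SERIES)["label"]
        .apply(lambda s: ";".join(sorted(set(s))))
        .rename("triggering_labels")
    )
    out = out.merge(trig, on=SERIES, how="left")
    out["triggering_labels"] = out["triggering_labels"].fillna("")

    any_finding = set(map(tuple, labels[SERIES].drop_duplicates().itertuples(index=False)))
    has_finding = [
        (c, d) in any_finding for c, d in zip(out["compound"], out["dose_level"])]
    if background_mode == "no_findings_strict":
        adverse_compounds = set(out.loc[out["is_adverse"], "compound"])
        out["is_background"] = [
            (not f) and (c not in adverse_compounds)
            for f, c in zip(has_finding, out["compound"])]
    elif background_mode == "non_adverse":
        out["is_background"] = ~out["is_adverse"]
    else:
        raise ValidationError(f"unknown background_mode {background_mode!r}")
    return out
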