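"""Directional events and first-activation times.

An event is a directional change (up or down) of one entity — a gene, a
pathway score or a TF regulon — within one time series. Its *first
activation* is the earliest measured timepoint at which the differential
test passes the activation criteria in the event's direction (FDR below the
cut-off, and for gene-level events additionally an absolute effect above a
minimum). Up and down are independent events: one entity can first-activate
in both directions within a single series. No smoothing or interpolation is
applied; missing timepoints are simply skipped.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .types import ValidationError

SERIES = ["compound", "dose_level"]

ACTIVATION_COLUMNS = SERIES + ["entity", "level", "direction", "first_time_h"]


@dataclasses.dataclass(frozen=True)
class ActivationCriteria:
    """Thresholds an event must pass at a timepoint to count as activated.

    ``fdr_max`` — significance cut-off on the BH-adjusted p (strict <).
    ``min_abs_effect`` — additional |effect| cut-off (strict >); 0 for
    set-level events, typically 0.5 or 1.0 for genes and 0.5 for TF
    expression in the cascade analysis.
    """

    fdr_max: float = 0.05
    min_abs_effect: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValidationError("fdr_max must lie in (0, 1]")
        if self.min_abs_effect < 0:
            raise ValidationError("min_abs_effect must be non-negative")


def qualifying_mask(diff: pd.DataFrame, criteria: ActivationCriteria) -> pd.Series:
    """Boolean mask of differential rows passing the activation criteria
    (in the direction of their effect sign)."""
    return (diff["fdr"] < criteria.fdr_max) & (
        diff["effect"].abs() > criteria.min_abs_effect)


def _check_duplicates(diff: pd.DataFrame) -> None:
    keys = ["entity", "level"] + SERIES + ["time_h"]
    dup = diff.duplicated(subset=keys, keep=False)
    if dup.any():
        sub = diff.loc[dup]
        conflicting = sub.duplicated(subset=keys + ["effect", "p"], keep=False)
        if not conflicting.all():
            bad = sub.loc[~conflicting, keys].head(3).to_dict("records")
            raise ValidationError(f"conflicting duplicate differential rows, e.g. {bad}")
        raise ValidationError("duplicate differential rows for one (entity, series, time)")


def first_activation(diff: pd.DataFrame, criteria: ActivationCriteria) -> pd.DataFrame:
    """First-activation time of every directional event in every series.

    Returns one row per (series, entity, level, direction) that qualifies at
    >= 1 timepoint; events with no qualifying timepoint are absent. The
    result is independent of input row order.
    """
    _check_duplicates(diff)
    qual = diff.loc[qualifying_mask(diff, criteria)].copy()
    if len(qual) == 0:
        return pd.DataFrame(columns=ACTIVATION_COLUMNS)
    qual["direction"] = np.where(qual["effect"] > 0, "up", "down")
    out = (
        qual.groupby(SERIES + ["entity", "level", "direction"], as_index=False)["time_h"]
        .min()
        .rename(columns={"time_h": "first_time_h"})
    )
    return out.sort_values(ACTIVATION_COLUMNS[:-1], ignore_index=True)[ACTIVATION_COLUMNS]


def max_effect_before(
    trajectory: pd.DataFrame,
    criteria: ActivationCriteria,
    direction: str,
    cutoff_time_h: float,
) -> float:
    """Maximum |effect| of one event over its qualifying timepoints at or
    before ``cutoff_time_h`` (inclusive boundary — "before or at").

    ``trajectory`` holds the differential rows of one (entity, series):
    columns time_h, effect, fdr. Returns NaN if no timepoint qualifies.
    """
    sign = 1.0 if direction == "up" else -1.0
    ok = (
        qualifying_mask(trajectory, criteria)
        & (np.sign(trajectory["effect"]) == sign)
        & (trajectory["time_h"] <= cutoff_time_h)
    )
    if not ok.any():
        return float("nan")
    return float(trajectory.loc[ok, "effect"].abs().max())


def max_effects_before(
    diff: pd.DataFrame,
    criteria: ActivationCriteria,
    cutoffs: pd.DataFrame,
) -> pd.DataFrame:
    """Vectorised :func:`max_effect_before` over many events and series.

    ``cutoffs`` has the series columns plus ``cutoff_time_h`` (one row per
    series). Returns rows (series, entity, level, direction, max_abs_effect)
    for every event with >= 1 qualifying timepoint at or before the series
    cutoff.
    """
    qual = diff.loc[qualifying_mask(diff, criteria)].copy()
    if len(qual) == 0:
        return pd.DataFrame(columns=SERIES + ["entity", "level", "direction", "max_abs_effect"])
    qual = qual.merge(cutoffs[SERIES + ["cutoff_time_h"]], on=SERIES)
    qual = qual.loc[qual["time_h"] <= qual["cutoff_time_h"]].copy()
    qual["direction"] = np.where(qual["effect"] > 0, "up", "down")
    qual["abs_effect"] = qual["effect"].abs()
    out = (
        qual.groupby(SERIES + ["entity", "level", "direction"], as_index=False)["abs_effect"]
        .max()
        .rename(columns={"abs_effect": "max_abs_effect"})
    )
    return out
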