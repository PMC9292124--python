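"""Time concordance between preceding events and a later event.

For a preceding event PE and later event LE (primarily adverse
histopathology), each time series containing LE contributes to a 2x2
confusion matrix according to whether PE first-activates before-or-at
(optionally strictly before) the first LE time; background series — series
without LE — contribute according to whether PE occurs at any timepoint.
Enrichment is the one-sided Fisher's exact test (upper tail of the central
hypergeometric under the observed margins), with the odds ratio estimated
by the conditional MLE of Fisher's noncentral hypergeometric distribution.

Series in which no event of PE's level activated within the relevant window
(timepoints <= first LE for LE-series; all timepoints for background) are
excluded as *not evaluable*: absence of any signal there is treated as
absence of evidence, not evidence of absence.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .activity import adjust_fdr
from .events import SERIES, ActivationCriteria, max_effects_before
from .types import ValidationError

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "entity", "level", "direction", "le",
    "a", "b", "c", "d",
    "odds_ratio", "p", "q", "tpr", "ppv",
    "median_max_abs_effect", "n_series_with_effect", "untestable",
]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Counts over evaluable series: a/b split the LE-series by whether PE
    precedes LE; c/d split the background series by whether PE occurs."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n_le(self) -> int:
        return self.a + self.b

    @property
    def n_background(self) -> int:
        return self.c + self.d


def fisher_one_sided(cm: ConfusionMatrix) -> tuple[float, float]:
    """One-sided exact enrichment test of the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p): p = P(X >= a) under the central hypergeometric
    with the observed margins (null: odds ratio <= 1); the odds ratio is the
    conditional MLE, infinite when b*c = 0 with a*d > 0, and NaN for a
    degenerate (zero-margin) table, with p = 1.
    """
    a, b, c, d = cm.a, cm.b, cm.c, cm.d
    n = a + b + c + d
    if n == 0 or (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        # a zero margin: the table carries no information on association
        or_hat = np.nan
        if a * d > 0 and b * c == 0:
            or_hat = np.inf
        return or_hat, 1.0
    p = float(stats.hypergeom.sf(a - 1, n, a + b, a + c))
    if b * c == 0:
        or_hat = np.inf if a * d > 0 else (0.0 if a * d == 0 and b * c == 0 else np.nan)
        if a * d == 0 and b * c == 0:
            or_hat = np.nan
        elif a * d == 0:
            or_hat = 0.0
    else:
        or_hat = float(_odds_ratio([[a, b], [c, d]], kind="conditional").statistic)
    return or_hat, min(p, 1.0)


def evaluable_series(
    level: str,
    activations: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split series into evaluable LE-series and evaluable background series
    for events of one level.

    LE-series (first LE time defined) are evaluable iff >= 1 event of
    ``level`` first-activated at or before the first LE time; background
    series iff >= 1 event of ``level`` activated at any timepoint.
    Returns (evaluable LE-series with ``le_time_h``, evaluable background).
    """
    acts = activations.loc[activations["level"] == level]
    earliest = acts.groupby(SERIES)["first_time_h"].min().rename("earliest_level_act")

    le = outcomes.loc[outcomes["first_adverse_time_h"].notna(),
                      SERIES + ["first_adverse_time_h"]].copy()
    le = le.rename(columns={"first_adverse_time_h": "le_time_h"})
    le = le.merge(earliest, on=SERIES, how="left")
    le = le.loc[le["earliest_level_act"] <= le["le_time_h"]]

    bg = outcomes.loc[outcomes["is_background"], SERIES].copy()
    bg = bg.merge(earliest, on=SERIES, how="inner")
    return le[SERIES + ["le_time_h"]].reset_index(drop=True), bg[SERIES].reset_index(drop=True)


def build_confusion(
    pe_first_times: pd.DataFrame,
    le_eval: pd.DataFrame,
    bg_eval: pd.DataFrame,
    relation: str = "before_or_at",
) -> ConfusionMatrix:
    """Confusion matrix for one PE given evaluable LE and background series.

    ``pe_first_times``: series columns + first_time_h for the PE.
    ``relation``: "before_or_at" counts ties as concordant (default);
    "before" requires strictly earlier first activation.
    """
    if relation not in ("before_or_at", "before"):
        raise ValidationError(f"unknown temporal relation {relation!r}")
    merged = le_eval.merge(pe_first_times, on=SERIES, how="left")
    if relation == "before_or_at":
        hit = merged["first_time_h"] <= merged["le_time_h"]
    else:
        hit = merged["first_time_h"] < merged["le_time_h"]
    a = int(hit.fillna(False).sum())
    b = len(le_eval) - a
    pe_series = set(map(tuple, pe_first_times[SERIES].itertuples(index=False)))
    c = int(sum((cc, dd) in pe_series
                for cc, dd in bg_eval.itertuples(index=False)))
    d = len(bg_eval) - c
    return ConfusionMatrix(a, b, c, d)


def concordance_table(
    activations: pd.DataFrame,
    outcomes: pd.DataFrame,
    diff: pd.DataFrame | None = None,
    criteria: ActivationCriteria | None = None,
    levels: list[str] | None = None,
    relation: str = "before_or_at",
    le_name: str = "adverse_histopathology",
) -> pd.DataFrame:
    """Time-concordance metrics of every directional event against the later
    event, one row per (entity, level, direction).

    Metrics: confusion counts, conditional-MLE odds ratio, one-sided exact
    p, BH q within each level family, TPR = a/(a+b), PPV = a/(a+c), and —
    when ``diff`` and ``criteria`` are given — the median over concordant
    LE-series of the maximum |effect| observed at qualifying timepoints
    before-or-at the first LE time. Series without the PE contribute nothing
    to that median. Events on a margin with zero evaluable series are
    flagged ``untestable`` (p = 1).
    """
    if levels is None:
        levels = sorted(activations["level"].unique())
    rows = []
    for level in levels:
        le_eval, bg_eval = evaluable_series(level, activations, outcomes)
        acts = activations.loc[activations["level"] == level]
        untestable = len(le_eval) == 0 or len(bg_eval) == 0
        if untestable:
            log.warning("concordance: level %s has zero evaluable series on a margin", level)

        med = None
        if diff is not None and criteria is not None and len(le_eval):
            cut = le_eval.rename(columns={"le_time_h": "cutoff_time_h"})
            med_tbl = max_effects_before(diff.loc[diff["level"] == level], criteria, cut)
            med = med_tbl.groupby(["entity", "level", "direction"])["max_abs_effect"]

        for (entity, direction), sub in acts.groupby(["entity", "direction"]):
            cm = build_confusion(sub[SERIES + ["first_time_h"]], le_eval, bg_eval, relation)
            or_hat, p = fisher_one_sided(cm)
            tpr = cm.a / cm.n_le if cm.n_le > 0 else np.nan
            ppv = cm.a / (cm.a + cm.c) if (cm.a + cm.c) > 0 else np.nan
            med_eff, n_eff = np.nan, 0
            if med is not None:
                key = (entity, level, direction)
                try:
                    vals = med.get_group(key)
                    med_eff = float(vals.median())
                    n_eff = int(len(vals))
                except KeyError:
                    pass
            rows.append({
                "entity": entity, "level": level, "direction": direction,
                "le": le_name,
                "a": cm.a, "b": cm.b, "c": cm.c, "d": cm.d,
                "odds_ratio": or_hat, "p": p, "q": np.nan,
                "tpr": tpr, "ppv": ppv,
                "median_max_abs_effect": med_eff,
                "n_series_with_effect": n_eff,
                "untestable": untestable,
            })
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(out):
        out["q"] = adjust_fdr(out["p"].to_numpy(), out["level"])
        out = out.sort_values(["level", "p", "entity", "direction"], ignore_index=True)
    return out


def event_le_concordance(
    activations: pd.DataFrame,
    le_entity: str,
    le_level: str,
    le_direction: str,
    pe_levels: list[str] | None = None,
    relation: str = "before_or_at",
) -> pd.DataFrame:
    """Concordance of events against another *event* as LE (used by the TF
    analyses): LE-series are those where the LE event activated, background
    series those lacking it. The evaluability rule is applied uniformly."""
    is_le = (
        (activations["entity"] == le_entity)
        & (activations["level"] == le_level)
        & (activations["direction"] == le_direction)
    )
    le_times = activations.loc[is_le, SERIES + ["first_time_h"]].rename(
        columns={"first_time_h": "first_adverse_time_h"})
    all_series = activations[SERIES].drop_duplicates()
    outcomes = all_series.merge(le_times, on=SERIES, how="left")
    outcomes["is_adverse"] = outcomes["first_adverse_time_h"].notna()
    outcomes["is_background"] = ~outcomes["is_adverse"]
    outcomes["triggering_labels"] = ""
    pe_acts = activations.loc[~is_le]
    if pe_levels is not None:
        pe_acts = pe_acts.loc[pe_acts["level"].isin(pe_levels)]
    le_label = f"{le_entity}|{le_level}|{le_direction}"
    return concordance_table(pe_acts, outcomes, relation=relation, le_name=le_label)
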