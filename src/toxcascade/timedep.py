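"""Time dependence: monotone association between effect size and time.

For each event and each adverse time series, the Spearman rank correlation
between timepoint and effect (the per-timepoint differential effect,
whether or not it passes activation criteria) is computed, anchoring the
trajectory with effect 0 at 0 h (no treated-vs-control difference before
dosing). Midranks handle ties. The two-sided p is exact — the full
permutation distribution of the rank statistic — for n <= 9 points, which
covers the 8-timepoint design; a t-approximation is used above.

Events whose significant per-series correlations all share one sign are
*consistent*, and for those Fisher's combined probability test pools the
per-series p-values across all adverse series with a defined correlation
(not only the significant ones).
"""

from __future__ import annotations

import functools
import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .events import SERIES
from .types import ValidationError

log = logging.getLogger(__name__)

EXACT_MAX_N = 9

RESULT_COLUMNS = [
    "entity", "level", "sign", "n_series", "n_significant",
    "consistent", "chi2", "df", "combined_p",
]


@functools.lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


@functools.lru_cache(maxsize=512)
def _perm_stat_distribution(rx_key: tuple, ry_key: tuple) -> np.ndarray:
    """Sorted permutation distribution of |T - E[T]| where T = sum rx * ry
    over all pairings. Keys are doubled midranks (integers)."""
    rx = np.asarray(rx_key, dtype=float) / 2.0
    ry = np.asarray(ry_key, dtype=float) / 2.0
    n = len(rx)
    perms = _perm_matrix(n)
    T = rx[perms] @ ry
    ET = rx.sum() * ry.sum() / n
    return np.sort(np.abs(T - ET))


def series_spearman(
    times: np.ndarray,
    effects: np.ndarray,
    anchor: bool = True,
) -> tuple[float, float, int]:
    """Spearman correlation of one trajectory against time.

    Prepends the (0 h, effect 0) anchor unless a 0 h point is present.
    Returns (rho, two-sided p, n_points); rho is NaN for a constant effect
    vector (the caller should skip such series).
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(effects, dtype=float)
    if len(t) != len(x):
        raise ValidationError("times and effects differ in length")
    order = np.argsort(t, kind="stable")
    t, x = t[order], x[order]
    if anchor and (len(t) == 0 or t[0] > 0):
        t = np.concatenate([[0.0], t])
        x = np.concatenate([[0.0], x])
    n = len(t)
    if len(np.unique(t)) < 3:
        raise ValidationError("need >= 3 distinct timepoints (after anchoring)")
    rt = stats.rankdata(t)
    rx = stats.rankdata(x)
    if np.ptp(x) == 0:
        return float("nan"), float("nan"), n
    rho = float(np.corrcoef(rt, rx)[0, 1])
    if n <= EXACT_MAX_N:
        dist = _perm_stat_distribution(
            tuple(np.sort(np.round(rt * 2).astype(int))),
            tuple(np.sort(np.round(rx * 2).astype(int))),
        )
        t_obs = float(rt @ rx)
        dev = abs(t_obs - rt.sum() * rx.sum() / n)
        # count permutations at least as extreme (two-sided), tie-tolerant
        idx = np.searchsorted(dist, dev - 1e-9, side="left")
        p = (len(dist) - idx) / len(dist)
    else:
        tstat = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(tstat), n - 2)
    return rho, float(min(p, 1.0)), n


def combine_fisher(p_values) -> tuple[float, int, float]:
    """Fisher's combined probability test: chi2 = -2 sum(ln p) on 2k df.

    A single p combines to itself exactly. Zero p-values are clamped to the
    smallest positive float and logged.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("combine_fisher needs at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if (p == 0).any():
        log.warning("combine_fisher: clamped %d zero p-value(s)", int((p == 0).sum()))
        p = np.maximum(p, np.nextafter(0.0, 1.0))
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def time_dependence(
    diff: pd.DataFrame,
    adverse_series: pd.DataFrame,
    per_series_alpha: float = 0.05,
    levels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-event time-dependence screen across adverse series.

    ``diff`` supplies each event's effect at every measured timepoint of
    every series; ``adverse_series`` holds the series columns of the adverse
    time series. An event is ``consistent`` iff >= 1 series is significant
    at ``per_series_alpha`` and all significant series agree in correlation
    sign; the combined p (Fisher) is computed only then, across *all*
    adverse series with a defined correlation.
    """
    adv = set(map(tuple, adverse_series[SERIES].itertuples(index=False)))
    sub = diff.loc[[
        (c, d) in adv for c, d in zip(diff["compound"], diff["dose_level"])]]
    if levels is not None:
        sub = sub.loc[sub["level"].isin(levels)]
    rows = []
    for (entity, level), grp in sub.groupby(["entity", "level"], sort=True):
        per_series = []
        for _, ser in grp.groupby(SERIES, sort=True):
            try:
                rho, p, n = series_spearman(ser["time_h"].to_numpy(),
                                            ser["effect"].to_numpy())
            except ValidationError:
                continue
            if math.isnan(rho):
                log.info("time_dependence: constant trajectory skipped (%s, %s)",
                         entity, level)
                continue
            per_series.append((rho, p, n))
        if not per_series:
            continue
        rhos = np.array([r for r, _, _ in per_series])
        ps = np.array([p for _, p, _ in per_series])
        sig = ps < per_series_alpha
        n_sig = int(sig.sum())
        consistent = bool(n_sig >= 1 and (
            (rhos[sig] > 0).all() or (rhos[sig] < 0).all()))
        sign = ""
        chi2 = df = comb = np.nan
        if consistent:
            sign = "up" if (rhos[sig] > 0).all() else "down"
            chi2, df, comb = combine_fisher(ps)
        rows.append({
            "entity": entity, "level": level, "sign": sign,
            "n_series": len(per_series), "n_significant": n_sig,
            "consistent": consistent, "chi2": chi2, "df": df,
            "combined_p": comb,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def concordance_vs_dependence(
    conc: pd.DataFrame,
    dep: pd.DataFrame,
    conc_alpha: float = 0.05,
    dep_alpha: float = 0.05,
) -> pd.DataFrame:
    """Joint table of time concordance and time dependence per event.

    Events are joined on (entity, level) with the dependence correlation
    sign matched to the concordance direction, and classified into the four
    quadrants: both / concordant_only / dependent_only / neither.
    """
    c = conc[["entity", "level", "direction", "p"]].rename(columns={"p": "concordance_p"})
    d = dep.loc[dep["consistent"], ["entity", "level", "sign", "combined_p"]].rename(
        columns={"sign": "direction", "combined_p": "dependence_p"})
    joint = c.merge(d, on=["entity", "level", "direction"], how="outer")
    if len(joint) == 0:
        log.warning("concordance_vs_dependence: empty event intersection")
        return joint.assign(quadrant=pd.Series(dtype=str))
    conc_sig = joint["concordance_p"] < conc_alpha
    dep_sig = joint["dependence_p"] < dep_alpha
    joint["quadrant"] = np.select(
        [conc_sig & dep_sig, conc_sig & ~dep_sig, ~conc_sig & dep_sig],
        ["both", "concordant_only", "dependent_only"],
        default="neither",
    )
    return joint.sort_values(["level", "entity", "direction"], ignore_index=True)
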