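"""Per-sample gene-set activity scoring and differential activity testing.

Gene-set activity is scored with a single-sample, rank-based enrichment
statistic (the GSVA approach): each gene's expression is transformed to a
Gaussian-kernel cumulative density across the sample universe, converted to
per-sample gene ranks, and each set is summarised by the signed maximum
deviation of a weighted Kolmogorov-Smirnov-like random walk down the ranked
gene list. Scores are dimensionless and bounded in [-1, 1].

Differential activity (or expression) of each treated condition against its
matched vehicle control is assessed with an empirical-Bayes moderated
t-statistic: per-row residual variances from a per-compound group-means
model are shrunk toward a common prior estimated from the distribution of
row variances (Smyth's scaled-F formulation), and p-values come from a t
distribution with residual + prior degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionData, GeneSetCollection, SampleSheet, ValidationError

log = logging.getLogger(__name__)

DIFF_COLUMNS = [
    "entity", "level", "compound", "dose_level", "time_h",
    "effect", "t_stat", "p", "fdr", "n_treated", "n_control",
]


# ---------------------------------------------------------------------------
# gene-set scoring
# ---------------------------------------------------------------------------

def _kernel_cdf(X: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Gaussian-kernel cumulative density of each value across samples,
    estimated per gene row. Bandwidth is the per-gene standard deviation / 4.
    """
    n_genes, n_samples = X.shape
    sd = X.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1e-8)
    out = np.empty_like(X, dtype=float)
    for lo in range(0, n_genes, chunk):
        hi = min(lo + chunk, n_genes)
        block = X[lo:hi]
        diff = (block[:, :, None] - block[:, None, :]) / h[lo:hi, None, None]
        out[lo:hi] = special.ndtr(diff).mean(axis=2)
    return out


def _walk_extrema(ranks: np.ndarray, weights: np.ndarray, member_idx: np.ndarray,
                  n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """Max positive and min negative deviation of the set's random walk,
    per sample, computed from member positions only (the walk rises only at
    member genes and decays linearly between them)."""
    m = len(member_idx)
    if m >= n_genes:
        raise ValidationError("gene set spans the whole expression universe")
    r = ranks[member_idx]          # m x S positions in the ranked list (1-based)
    w = weights[member_idx]
    order = np.argsort(r, axis=0, kind="stable")
    q = np.take_along_axis(r, order, 0).astype(float)
    ww = np.take_along_axis(w, order, 0)
    denom = ww.sum(axis=0)
    denom = np.where(denom > 0, denom, 1.0)
    cum = np.cumsum(ww, axis=0) / denom
    step = 1.0 / (n_genes - m)
    i = np.arange(1, m + 1, dtype=float)[:, None]
    v_plus = cum - (q - i) * step              # just after each member
    v_minus = (cum - ww / denom) - (q - i) * step  # just before each member
    vmax = np.maximum(v_plus.max(axis=0), 0.0)
    vmin = np.minimum(v_minus.min(axis=0), 0.0)
    return vmax, vmin


def score_gene_sets(
    expr: ExpressionData,
    sets: GeneSetCollection,
    method: str = "kernel_ecdf",
    es: str = "max_dev",
    tau: float = 1.0,
    min_size: int = 1,
) -> pd.DataFrame:
    """Score per-sample activity of every gene set.

    Parameters
    ----------
    expr
        Expression data defining the sample universe (for the kernel ECDF the
        density of each gene is estimated across exactly these samples, so
        pass the per-compound universe when emulating per-treatment scoring).
    sets
        Gene sets; regulon negative-mode members should already be removed.
    method
        ``kernel_ecdf`` (the default, the GSVA statistic) or ``zscore``
        (a documented fallback: the combined z of per-gene standardised
        values, mapped into (-1, 1) through the normal CDF).
    es
        ``max_dev`` — signed maximum deviation of the random walk (default) —
        or ``diff`` — sum of the maximum positive and minimum negative
        deviations.

    Returns
    -------
    DataFrame, sets x samples, values in [-1, 1].
    """
    X = expr.matrix.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValidationError("activity scoring needs at least 3 samples")
    if method not in ("kernel_ecdf", "zscore"):
        raise ValidationError(f"unknown scoring method {method!r}")
    if es not in ("max_dev", "diff"):
        raise ValidationError(f"unknown ES form {es!r}")

    gene_pos = {g: i for i, g in enumerate(expr.matrix.index)}
    retained: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        if len(idx) < max(min_size, 1):
            log.warning("score_gene_sets: set %r vanished after intersection; dropped", name)
            continue
        retained[name] = idx
    if not retained:
        return pd.DataFrame(index=pd.Index([], name="set"), columns=expr.matrix.columns, dtype=float)

    if method == "zscore":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        Z = (X - mu) / np.where(sd > 0, sd, 1.0)
        rows = {}
        for name, idx in retained.items():
            combined = Z[idx].sum(axis=0) / np.sqrt(len(idx))
            rows[name] = 2.0 * special.ndtr(combined) - 1.0
        return pd.DataFrame(rows, index=expr.matrix.columns).T.rename_axis("set")

    F = _kernel_cdf(X)
    # per-sample gene ranks, 1 = largest kernel CDF; stable tie-break by row order
    order = np.argsort(-F, axis=0, kind="stable")
    ranks = np.empty_like(order)
    put = np.arange(1, n_genes + 1)[:, None] * np.ones((1, n_samples), dtype=int)
    np.put_along_axis(ranks, order, put, axis=0)
    weights = np.abs(n_genes / 2.0 - ranks) ** tau

    rows = {}
    for name, idx in retained.items():
        vmax, vmin = _walk_extrema(ranks, weights, idx, n_genes)
        if es == "max_dev":
            rows[name] = np.where(vmax >= -vmin, vmax, vmin)
        else:
            rows[name] = vmax + vmin
    out = pd.DataFrame(rows, index=expr.matrix.columns).T.rename_axis("set")
    return out


def score_per_compound(
    expr: ExpressionData,
    sets: GeneSetCollection,
    **kwargs,
) -> pd.DataFrame:
    """Score each compound's sample universe separately (all doses, timepoints
    and vehicle controls of one treatment) and concatenate the columns."""
    pieces = []
    for compound in sorted(expr.sheet.frame["compound"].unique()):
        sub = expr.subset_compound(compound)
        pieces.append(score_gene_sets(sub, sets, **kwargs))
    out = pd.concat(pieces, axis=1)
    return out.loc[:, expr.sheet.sample_ids]


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (prior_df d0, prior variance s0^2) of the scaled-F model for
    row variances ``s2`` with common residual df, by matching the moments of
    log s2 (Smyth 2004)."""
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) < 2 or df <= 0:
        return np.inf, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def squeeze_variances(s2: np.ndarray, df: float, prior_df: float | None = None,
                      prior_var: float | None = None) -> tuple[np.ndarray, float, float]:
    """Shrink row variances toward the common prior.

    Returns (posterior variances, d0, s0^2). ``prior_df`` may be forced
    (0 disables moderation, yielding the ordinary two-sample t exactly).
    """
    s2 = np.asarray(s2, dtype=float)
    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        s0_sq = prior_var if prior_var is not None else (
            estimate_variance_prior(s2, df)[1] if d0 > 0 else 0.0)
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        post = s2.copy()
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0, s0_sq


# ---------------------------------------------------------------------------
# differential activity / expression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _CompoundFit:
    group_means: pd.DataFrame     # rows x groups
    group_sizes: dict[tuple, int]
    s2: np.ndarray                # pooled residual variance per row
    df_resid: float


def _fit_group_means(values: pd.DataFrame, sheet: pd.DataFrame) -> _CompoundFit:
    """Per-row group-means model over one compound's samples. Groups are
    (dose_level, time_h, is_control); the residual variance is pooled across
    all groups (the linear-model residual with one coefficient per group)."""
    groups = sheet.groupby(["dose_level", "time_h", "is_control"], sort=True)
    means = {}
    sizes = {}
    rss = np.zeros(len(values), dtype=float)
    n_total = 0
    n_groups = 0
    V = values.to_numpy(dtype=float)
    col_pos = {s: i for i, s in enumerate(values.columns)}
    for key, sub in groups:
        cols = [col_pos[s] for s in sub["sample_id"]]
        block = V[:, cols]
        mu = block.mean(axis=1)
        means[key] = mu
        sizes[key] = len(cols)
        rss += ((block - mu[:, None]) ** 2).sum(axis=1)
        n_total += len(cols)
        n_groups += 1
    df_resid = float(n_total - n_groups)
    s2 = rss / df_resid if df_resid > 0 else np.full(len(values), np.nan)
    gm = pd.DataFrame(means, index=values.index)
    return _CompoundFit(gm, sizes, s2, df_resid)


def differential(
    values_by_sample: pd.DataFrame,
    sheet: SampleSheet,
    level: str,
    moderation: str = "eb",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Differential effect of every treated (compound, dose, time) condition
    against its matched vehicle control, for every row of
    ``values_by_sample`` (gene-set scores or gene expression).

    The effect is the treated-minus-control mean difference (a logFC on the
    log2 scale for genes, a score difference for sets). ``moderation="eb"``
    shrinks per-row variances toward a per-compound prior; ``"none"`` is the
    ordinary two-sample t. Contrasts with fewer than 2 treated or 2 control
    samples are skipped and logged. FDR is left NaN; apply
    :func:`adjust_fdr` with the desired family.
    """
    if moderation not in ("eb", "none"):
        raise ValidationError(f"unknown moderation {moderation!r}")
    sdf = sheet.frame
    missing = [s for s in sdf["sample_id"] if s not in values_by_sample.columns]
    if missing:
        raise ValidationError(f"values matrix lacks sheet samples: {missing[:10]}")

    records: list[pd.DataFrame] = []
    for compound in sorted(sdf["compound"].unique()):
        sub = sdf.loc[sdf["compound"] == compound]
        fit = _fit_group_means(values_by_sample[list(sub["sample_id"])], sub)
        if fit.df_resid <= 0:
            raise ValidationError(
                f"zero residual degrees of freedom for compound {compound!r}")
        if moderation == "eb":
            s2_post, d0, _ = squeeze_variances(fit.s2, fit.df_resid, prior_df=prior_df)
        else:
            s2_post, d0 = fit.s2.copy(), 0.0
        df_total = fit.df_resid + (d0 if np.isfinite(d0) else np.inf)

        ctrl_keys = {k[1]: k for k in fit.group_sizes if k[2]}  # time -> group key
        treated_keys = [k for k in fit.group_sizes if not k[2]]
        for key in sorted(treated_keys):
            dose, time_h, _ = key
            n_t = fit.group_sizes[key]
            ckey = ctrl_keys.get(time_h)
            n_c = fit.group_sizes.get(ckey, 0) if ckey else 0
            if n_t < 2 or n_c < 2:
                log.info("differential: skipped %s dose=%s t=%gh (n_t=%d, n_c=%d)",
                         compound, dose, time_h, n_t, n_c)
                continue
            effect = fit.group_means[key].to_numpy() - fit.group_means[ckey].to_numpy()
            se = np.sqrt(s2_post * (1.0 / n_t + 1.0 / n_c))
            with np.errstate(divide="ignore", invalid="ignore"):
                t_stat = np.where(effect == 0.0, 0.0, effect / se)
            t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
            if np.isinf(df_total):
                p = 2.0 * stats.norm.sf(np.abs(t_stat))
            else:
                p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
            records.append(pd.DataFrame({
                "entity": values_by_sample.index,
                "level": level,
                "compound": compound,
                "dose_level": dose,
                "time_h": time_h,
                "effect": effect,
                "t_stat": t_stat,
                "p": p,
                "fdr": np.nan,
                "n_treated": n_t,
                "n_control": n_c,
            }))
    if not records:
        return pd.DataFrame(columns=DIFF_COLUMNS)
    return pd.concat(records, ignore_index=True)[DIFF_COLUMNS]


def adjust_fdr(
    p_values: Sequence[float] | np.ndarray,
    family: Sequence | None = None,
) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, computed within each declared
    family (``family`` is a label per p-value; None pools everything)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    q = np.empty_like(p)
    if family is None:
        q[:] = multipletests(p, method="fdr_bh")[1]
        return q
    fam = pd.Series(list(family))
    for _, idx in fam.groupby(fam).groups.items():
        sel = np.asarray(idx)
        q[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return q


def add_fdr(diff: pd.DataFrame, family_cols: Sequence[str] = ("compound", "level")) -> pd.DataFrame:
    """Fill the ``fdr`` column of a differential table, BH-adjusted within
    each (compound, level) family (per-treatment adjustment scope)."""
    out = diff.copy()
    if len(out) == 0:
        return out
    fam = list(map(tuple, out[list(family_cols)].itertuples(index=False)))
    out["fdr"] = adjust_fdr(out["p"].to_numpy(), fam)
    return out
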