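"""Gene-set scoring against a naive independent re-implementation, and the
moderated-t machinery against direct formula evaluation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from toxcascade.activity import (
    add_fdr,
    adjust_fdr,
    differential,
    score_gene_sets,
    squeeze_variances,
)
from toxcascade.types import ExpressionData, GeneSetCollection, SampleSheet, ValidationError


# ---------------------------------------------------------------------------
# naive scorer: plain-loop re-implementation, shares no code with the package
# ---------------------------------------------------------------------------

def naive_scores(matrix: pd.DataFrame, sets: dict, es: str = "max_dev") -> pd.DataFrame:
    genes = list(matrix.index)
    samples = list(matrix.columns)
    p = len(genes)
    # kernel CDF per gene
    F = np.zeros((p, len(samples)))
    for i, g in enumerate(genes):
        row = matrix.loc[g].to_numpy(dtype=float)
        sd = np.std(row, ddof=1)
        h = sd / 4 if sd > 0 else 1e-8
        for j in range(len(samples)):
            F[i, j] = np.mean([stats.norm.cdf((row[j] - v) / h) for v in row])
    out = {}
    for name, members in sets.items():
        scores = []
        for j in range(len(samples)):
            # rank genes by decreasing F, stable
            order = sorted(range(p), key=lambda i: (-F[i, j], i))
            rank_of = {gi: r + 1 for r, gi in enumerate(order)}
            member_idx = {genes.index(m) for m in members if m in genes}
            m = len(member_idx)
            wsum = sum(abs(p / 2 - rank_of[i]) for i in member_idx)
            walk, vmax, vmin = 0.0, 0.0, 0.0
            for r, gi in enumerate(order):
                if gi in member_idx:
                    walk += abs(p / 2 - rank_of[gi]) / wsum
                    vmax = max(vmax, walk)
                else:
                    walk -= 1.0 / (p - m)
                    vmin = min(vmin, walk)
            scores.append(vmax + vmin if es == "diff" else
                          (vmax if vmax >= -vmin else vmin))
        out[name] = scores
    return pd.DataFrame(out, index=samples).T


def _expr(matrix: pd.DataFrame) -> ExpressionData:
    n = matrix.shape[1]
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": list(matrix.columns),
        "compound": ["cpd"] * n,
        "dose_level": ["vehicle"] * (n // 2) + ["high"] * (n - n // 2),
        "time_h": [24.0] * n,
        "replicate": list(range(1, n // 2 + 1)) + list(range(1, n - n // 2 + 1)),
        "is_control": [True] * (n // 2) + [False] * (n - n // 2),
    }))
    return ExpressionData(matrix, sheet)


class TestScoring:
    @pytest.mark.parametrize("es", ["max_dev", "diff"])
    def test_matches_naive_reimplementation(self, es):
        rng = np.random.default_rng(42)
        mat = pd.DataFrame(rng.normal(7, 1, size=(6, 4)),
                           index=[f"g{i}" for i in range(6)],
                           columns=[f"s{j}" for j in range(4)])
        sets = {"A": {"g0", "g1", "g2"}, "B": {"g3", "g5"}}
        got = score_gene_sets(_expr(mat), GeneSetCollection(sets), es=es)
        want = naive_scores(mat, sets, es=es)
        np.testing.assert_allclose(got.to_numpy(), want.loc[got.index].to_numpy(),
                                   atol=1e-6)

    def test_global_maximum_gene_scores_positive(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(7, 1, size=(10, 4)),
                           index=[f"g{i}" for i in range(10)],
                           columns=[f"s{j}" for j in range(4)])
        mat.loc["g0", "s2"] = mat.to_numpy().max() + 5  # g0 tops sample s2
        scores = score_gene_sets(_expr(mat), GeneSetCollection({"one": {"g0"}}))
        assert scores.loc["one", "s2"] > 0

    def test_gene_row_order_invariance(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(7, 1, size=(12, 5)),
                           index=[f"g{i}" for i in range(12)],
                           columns=[f"s{j}" for j in range(5)])
        sets = GeneSetCollection({"A": {"g1", "g4", "g7"}})
        a = score_gene_sets(_expr(mat), sets)
        shuffled = mat.sample(frac=1, random_state=3)
        b = score_gene_sets(_expr(shuffled), sets)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_scores_bounded(self, small_results):
        for key in ("activity_pathway", "activity_tf"):
            vals = small_results[key].to_numpy()
            assert np.isfinite(vals).all()
            assert (vals >= -1).all() and (vals <= 1).all()

    def test_too_few_samples_rejected(self):
        mat = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["x", "y"])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["x", "y"], "compound": ["c"] * 2,
            "dose_level": ["vehicle", "high"], "time_h": [3.0, 3.0],
            "replicate": [1, 1], "is_control": [True, False]}))
        with pytest.raises(ValidationError, match="3 samples"):
            score_gene_sets(ExpressionData(mat, sheet), GeneSetCollection({"s": {"a"}}))

    def test_zscore_fallback_bounded_and_monotone(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(0, 1, size=(8, 6)),
                           index=[f"g{i}" for i in range(8)],
                           columns=[f"s{j}" for j in range(6)])
        mat.loc[["g0", "g1"], "s0"] += 4.0
        scores = score_gene_sets(_expr(mat), GeneSetCollection({"A": {"g0", "g1"}}),
                                 method="zscore")
        assert scores.to_numpy().max() <= 1 and scores.to_numpy().min() >= -1
        assert scores.loc["A", "s0"] == scores.loc["A"].max()


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _two_group_data(rng, n_rows=20, n1=3, n2=3, scale=None):
    cols = [f"c{i}" for i in range(n1)] + [f"t{i}" for i in range(n2)]
    scale = scale if scale is not None else rng.uniform(0.3, 2.0, size=n_rows)
    mat = pd.DataFrame(rng.normal(0, 1, size=(n_rows, n1 + n2)) * scale[:, None],
                       index=[f"r{i}" for i in range(n_rows)], columns=cols)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": cols,
        "compound": ["cpd"] * (n1 + n2),
        "dose_level": ["vehicle"] * n1 + ["high"] * n2,
        "time_h": [24.0] * (n1 + n2),
        "replicate": list(range(1, n1 + 1)) + list(range(1, n2 + 1)),
        "is_control": [True] * n1 + [False] * n2,
    }))
    return mat, sheet


def reference_prior(s2, df):
    """Independent route to the scaled-F prior: same moment equations solved
    with brentq instead of the package's Newton iteration."""
    z = np.log(s2)
    e = z - special.digamma(df / 2) + math.log(df / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    half_d0 = optimize.brentq(lambda y: special.polygamma(1, y) - evar, 1e-8, 1e8)
    d0 = 2 * half_d0
    s0 = float(np.exp(np.mean(e) + special.digamma(half_d0) - math.log(half_d0)))
    return d0, s0


class TestModeratedT:
    def test_matches_direct_shrinkage_formula(self):
        rng = np.random.default_rng(5)
        mat, sheet = _two_group_data(rng, n_rows=20)
        table = differential(mat, sheet, level="gene", moderation="eb")
        # independent recomputation straight from the definitions
        ctrl, treat = mat.iloc[:, :3], mat.iloc[:, 3:]
        s2 = (ctrl.var(axis=1, ddof=1) * 2 + treat.var(axis=1, ddof=1) * 2) / 4
        d0, s0 = reference_prior(s2.to_numpy(), 4.0)
        s2_post = (d0 * s0 + 4.0 * s2) / (d0 + 4.0)
        t_ref = (treat.mean(axis=1) - ctrl.mean(axis=1)) / np.sqrt(s2_post * (2 / 3))
        got = table.set_index("entity")["t_stat"]
        np.testing.assert_allclose(got[t_ref.index].to_numpy(), t_ref.to_numpy(),
                                   atol=1e-8)

    def test_prior_df_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(6)
        mat, sheet = _two_group_data(rng)
        eb0 = differential(mat, sheet, level="gene", moderation="eb", prior_df=0.0)
        for r in eb0.itertuples():
            c = mat.loc[r.entity].iloc[:3]
            t = mat.loc[r.entity].iloc[3:]
            t_ref, p_ref = stats.ttest_ind(t, c, equal_var=True)
            assert abs(r.t_stat - t_ref) < 1e-10
            assert abs(r.p - p_ref) < 1e-10

    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(7)
        mat, sheet = _two_group_data(rng, n_rows=5)
        mat.iloc[:, 3:] = mat.iloc[:, :3].to_numpy()
        table = differential(mat, sheet, level="gene")
        assert np.allclose(table["effect"], 0)
        assert np.allclose(table["t_stat"], 0)
        assert np.allclose(table["p"], 1)

    def test_shrinkage_direction(self):
        rng = np.random.default_rng(8)
        mat, sheet = _two_group_data(rng, n_rows=60)
        eb = differential(mat, sheet, level="gene", moderation="eb").set_index("entity")
        plain = differential(mat, sheet, level="gene", moderation="none").set_index("entity")
        ctrl, treat = mat.iloc[:, :3], mat.iloc[:, 3:]
        s2 = ((ctrl.var(axis=1, ddof=1) + treat.var(axis=1, ddof=1)) / 2)
        _, d0, s0 = squeeze_variances(s2.to_numpy(), 4.0)
        below = s2.index[s2.to_numpy() < s0]
        assert len(below) > 0
        assert (eb.loc[below, "t_stat"].abs().to_numpy()
                <= plain.loc[below, "t_stat"].abs().to_numpy() + 1e-12).all()

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(9)
        mat, sheet = _two_group_data(rng, n_rows=2000)
        table = differential(mat, sheet, level="gene", moderation="eb")
        ks = stats.kstest(table["p"], "uniform").statistic
        assert ks < 0.05

    def test_skips_underpowered_contrast(self, caplog):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)),
                           index=list("abc"),
                           columns=["c1", "c2", "t1", "t2", "u1"])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["c1", "c2", "t1", "t2", "u1"],
            "compound": ["cpd"] * 5,
            "dose_level": ["vehicle", "vehicle", "high", "high", "low"],
            "time_h": [24.0] * 5,
            "replicate": [1, 2, 1, 2, 1],
            "is_control": [True, True, False, False, False]}))
        table = differential(mat, sheet, level="gene")
        assert set(table["dose_level"]) == {"high"}  # single-replicate dose skipped


class TestFDR:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_empty(self):
        assert adjust_fdr([]).size == 0

    def test_fdr_at_least_p_within_families(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        fam = rng.integers(0, 4, size=200)
        q = adjust_fdr(p, fam)
        assert (q >= p - 1e-12).all()

    def test_add_fdr_respects_family(self):
        df = pd.DataFrame({
            "entity": ["e"] * 4, "level": ["pathway", "pathway", "gene", "gene"],
            "compound": ["c"] * 4, "dose_level": ["d"] * 4,
            "time_h": [3.0, 6.0, 3.0, 6.0],
            "effect": [1.0] * 4, "t_stat": [1.0] * 4,
            "p": [0.01, 0.04, 0.5, 1.0], "fdr": np.nan,
            "n_treated": 3, "n_control": 3})
        out = add_fdr(df)
        np.testing.assert_allclose(out.loc[out.level == "pathway", "fdr"], [0.02, 0.04])
        np.testing.assert_allclose(out.loc[out.level == "gene", "fdr"], [1.0, 1.0])
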