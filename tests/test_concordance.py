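"""Exact enrichment test against brute-force hypergeometric enumeration,
evaluability rule, confusion counting and planted-event ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from toxcascade import synth
from toxcascade.concordance import (
    ConfusionMatrix,
    build_confusion,
    concordance_table,
    evaluable_series,
    event_le_concordance,
    fisher_one_sided,
)
from toxcascade.types import ValidationError

SERIES = ["compound", "dose_level"]


def brute_force_upper_p(a, b, c, d):
    """P(X >= a) for X hypergeometric with the observed margins, by direct
    enumeration of all tables."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(math.comb(r1, x) * math.comb(n - r1, c1 - x)
               for x in range(a, hi + 1)) / denom


def brute_force_cmle(a, b, c, d):
    """Conditional-MLE odds ratio by direct maximisation of the noncentral
    hypergeometric likelihood on a psi grid."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    w = np.array([math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in xs],
                 dtype=float)

    def loglik(log_psi):
        logs = np.log(w) + xs * log_psi
        m = logs.max()
        return a * log_psi - (m + np.log(np.exp(logs - m).sum()))

    grid = np.linspace(-12, 12, 4001)
    vals = [loglik(g) for g in grid]
    return float(np.exp(grid[int(np.argmax(vals))]))


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((1, 0, 0, 1), 0.5),
        ((2, 0, 0, 2), 1 / 6),
    ])
    def test_closed_form_cases(self, table, expected):
        _, p = fisher_one_sided(ConfusionMatrix(*table))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration(self):
        _, p = fisher_one_sided(ConfusionMatrix(5, 2, 1, 8))
        assert p == pytest.approx(brute_force_upper_p(5, 2, 1, 8), abs=1e-12)

    def test_cmle_odds_ratio_matches_numeric_maximisation(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b, c, d = (int(rng.integers(1, 10)) for _ in range(4))
            or_hat, _ = fisher_one_sided(ConfusionMatrix(a, b, c, d))
            ref = brute_force_cmle(a, b, c, d)
            assert or_hat == pytest.approx(ref, rel=0.02)

    def test_infinite_odds_ratio_when_off_diagonal_empty(self):
        or_hat, _ = fisher_one_sided(ConfusionMatrix(3, 0, 0, 5))
        assert np.isinf(or_hat)

    def test_all_zero_table(self):
        or_hat, p = fisher_one_sided(ConfusionMatrix(0, 0, 0, 0))
        assert p == 1.0 and np.isnan(or_hat)

    def test_monotone_in_a_and_c(self):
        _, p0 = fisher_one_sided(ConfusionMatrix(3, 4, 2, 6))
        _, p_more_a = fisher_one_sided(ConfusionMatrix(4, 4, 2, 6))
        _, p_more_c = fisher_one_sided(ConfusionMatrix(3, 4, 3, 6))
        assert p_more_a <= p0 <= p_more_c

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionMatrix(-1, 0, 0, 0)


def _acts(rows):
    return pd.DataFrame(rows, columns=SERIES + [
        "entity", "level", "direction", "first_time_h"])


def _outcomes(rows):
    return pd.DataFrame(rows, columns=SERIES + [
        "is_adverse", "first_adverse_time_h", "is_background"])


class TestEvaluability:
    def test_le_series_needs_event_of_level_in_window(self):
        acts = _acts([("x", "d", "P1", "pathway", "up", 9.0),
                      ("y", "d", "P1", "pathway", "up", 96.0)])
        outcomes = _outcomes([("x", "d", True, 24.0, False),
                              ("y", "d", True, 24.0, False)])
        le, bg = evaluable_series("pathway", acts, outcomes)
        assert list(le["compound"]) == ["x"]  # y's only event is after LE

    def test_background_needs_event_anywhere(self):
        acts = _acts([("b1", "d", "P1", "pathway", "up", 672.0)])
        outcomes = _outcomes([("a1", "d", True, 24.0, False),
                              ("b1", "d", False, np.nan, True),
                              ("b2", "d", False, np.nan, True)])
        _, bg = evaluable_series("tf_activity", acts, outcomes)
        assert len(bg) == 0  # no TF events anywhere
        _, bg2 = evaluable_series("pathway", acts, outcomes)
        assert list(bg2["compound"]) == ["b1"]


class TestConfusion:
    def test_direct_count(self):
        le = pd.DataFrame({"compound": list("wxyz"), "dose_level": ["d"] * 4,
                           "le_time_h": [24.0] * 4})
        bg = pd.DataFrame({"compound": [f"b{i}" for i in range(10)],
                           "dose_level": ["d"] * 10})
        pe = _acts([(c, "d", "P", "pathway", "up", 6.0) for c in "wxy"]
                   + [("b0", "d", "P", "pathway", "up", 96.0)])[
            SERIES + ["first_time_h"]]
        cm = build_confusion(pe, le, bg)
        assert (cm.a, cm.b, cm.c, cm.d) == (3, 1, 1, 9)

    def test_strict_relation_excludes_ties(self):
        le = pd.DataFrame({"compound": ["x"], "dose_level": ["d"],
                           "le_time_h": [24.0]})
        bg = pd.DataFrame(columns=SERIES)
        pe = pd.DataFrame({"compound": ["x"], "dose_level": ["d"],
                           "first_time_h": [24.0]})
        assert build_confusion(pe, le, bg, "before_or_at").a == 1
        cm = build_confusion(pe, le, bg, "before")
        assert cm.a == 0 and cm.b == 1

    def test_absent_pe_gives_zero_a_and_c(self):
        le = pd.DataFrame({"compound": ["x"], "dose_level": ["d"],
                           "le_time_h": [24.0]})
        bg = pd.DataFrame({"compound": ["b"], "dose_level": ["d"]})
        pe = pd.DataFrame(columns=SERIES + ["first_time_h"])
        cm = build_confusion(pe, le, bg)
        assert cm.a == 0 and cm.c == 0


class TestConcordanceTable:
    def test_planted_event_ranks_first_of_200(self):
        cfg = synth.SimConfig(
            n_adverse=20, n_background=60, findings=synth.default_findings(),
            seed=5)
        planted = synth.PlantedEvent("TRUE_PE", "pathway", onset_h=24.0,
                                     effect=1.0, penetrance=0.8,
                                     background_rate=0.05)
        decoys = [synth.PlantedEvent(f"D{i:03d}", "pathway",
                                     onset_h=24.0, effect=1.0,
                                     penetrance=0.15, background_rate=0.15)
                  for i in range(199)]
        acts, outcomes = synth.shortcut_activations(cfg, [planted] + decoys)
        conc = concordance_table(acts, outcomes)
        assert len(conc) >= 200
        best = conc.sort_values("p").iloc[0]
        assert best["entity"] == "TRUE_PE"
        assert best["p"] < 1e-4

    def test_a_zero_gives_tpr_zero_p_one(self):
        acts = _acts([("b1", "d", "P", "pathway", "up", 24.0),
                      ("a1", "d", "Q", "pathway", "up", 3.0)])
        outcomes = _outcomes([("a1", "d", True, 24.0, False),
                              ("b1", "d", False, np.nan, True)])
        conc = concordance_table(acts, outcomes).set_index("entity")
        assert conc.loc["P", "tpr"] == 0.0
        assert conc.loc["P", "p"] == 1.0

    def test_identical_counts_identical_p(self):
        acts = _acts([("a1", "d", "P", "pathway", "up", 3.0),
                      ("a1", "d", "Q", "pathway", "up", 3.0),
                      ("b1", "d", "R", "pathway", "up", 3.0)])
        outcomes = _outcomes([("a1", "d", True, 24.0, False),
                              ("b1", "d", False, np.nan, True)])
        conc = concordance_table(acts, outcomes).set_index("entity")
        assert conc.loc["P", "p"] == conc.loc["Q", "p"]

    def test_ppv_one_when_no_background_occurrence(self):
        acts = _acts([("a1", "d", "P", "pathway", "up", 3.0),
                      ("a2", "d", "P", "pathway", "up", 3.0),
                      ("b1", "d", "Q", "pathway", "up", 3.0)])
        outcomes = _outcomes([("a1", "d", True, 24.0, False),
                              ("a2", "d", True, 24.0, False),
                              ("b1", "d", False, np.nan, True)])
        conc = concordance_table(acts, outcomes).set_index("entity")
        assert conc.loc["P", "c"] == 0 and conc.loc["P", "a"] > 0
        assert conc.loc["P", "ppv"] == 1.0

    def test_median_effect_only_over_concordant_series(self, small_results):
        conc = small_results["concordance"]
        row = conc.query("entity == 'PlantedPW' and direction == 'up' "
                        "and level == 'pathway'").iloc[0]
        assert row["n_series_with_effect"] == row["a"]
        assert row["median_max_abs_effect"] > 0.5


class TestEventAsLaterEvent:
    def test_event_vs_event_concordance(self):
        acts = _acts([
            ("s1", "d", "UP", "pathway", "up", 3.0),
            ("s1", "d", "LE", "pathway", "up", 24.0),
            ("s2", "d", "UP", "pathway", "up", 6.0),
            ("s2", "d", "LE", "pathway", "up", 24.0),
            ("s3", "d", "UP", "pathway", "up", 96.0),
        ])
        conc = event_le_concordance(acts, "LE", "pathway", "up")
        row = conc.set_index("entity").loc["UP"]
        assert row["a"] == 2 and row["c"] == 1
        assert row["le"] == "LE|pathway|up"
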