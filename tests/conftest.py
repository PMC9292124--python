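"""Shared fixtures: small hand-built containers plus session-scoped
synthetic studies run end-to-end through the analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from toxcascade import synth
from toxcascade.pipeline import PipelineConfig, analyze_study
from toxcascade.types import ExpressionData, SampleSheet


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": ["c1", "c2", "t1", "t2"],
        "compound": ["cpdA"] * 4,
        "dose_level": ["vehicle", "vehicle", "high", "high"],
        "time_h": [24.0, 24.0, 24.0, 24.0],
        "replicate": [1, 2, 1, 2],
        "is_control": [True, True, False, False],
    }))


@pytest.fixture
def tiny_expr(tiny_sheet) -> ExpressionData:
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.normal(7, 1, size=(3, 4)),
                       index=["g1", "g2", "g3"],
                       columns=tiny_sheet.sample_ids)
    return ExpressionData(mat, tiny_sheet)


@pytest.fixture(scope="session")
def small_sim() -> synth.SimData:
    """A reduced planted study (8 adverse + 16 background series)."""
    cfg = synth.planted_study_config(
        seed=7, n_adverse=8, n_background=16, n_decoy_sets=12,
        n_decoy_tfs=4, n_genes=250)
    return synth.simulate(cfg)


@pytest.fixture(scope="session")
def small_results(small_sim) -> dict:
    res = analyze_study(
        small_sim.expr, small_sim.pathways, small_sim.regulons,
        small_sim.toxscores, small_sim.annotations, small_sim.network,
        PipelineConfig())
    res["sim"] = small_sim
    return res


@pytest.fixture(scope="session")
def planted_results() -> dict:
    """The full planted-recovery study (40 adverse + 100 background series,
    200 candidate pathway sets, planted pathway event and 3-TF cascade) run
    end-to-end."""
    data = synth.simulate(synth.planted_study_config(seed=11))
    res = analyze_study(
        data.expr, data.pathways, data.regulons, data.toxscores,
        data.annotations, data.network, PipelineConfig())
    res["sim"] = data
    return res


@pytest.fixture(scope="session")
def null_results() -> dict:
    """The type-I-error study: 1000 genes (2000 directional candidate
    events) activating at equal rates regardless of outcome."""
    data = synth.null_dataset(synth.null_study_config(seed=13))
    cfg = PipelineConfig(include_gene_level=True, gene_min_abs_effect=0.5)
    res = analyze_study(
        data.expr, data.pathways, data.regulons, data.toxscores,
        data.annotations, data.network, cfg)
    res["sim"] = data
    return res
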