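"""Shared fixtures: small synthetic datasets and one full pipeline run."""

from __future__ import annotations

import datetime

import numpy as np
import pytest
from hypothesis import settings

from metalrisk.config import ConsumptionTable, ToxicologyParams
from metalrisk.records import DailyMetalSummary, DetectionRecord, Metal
from metalrisk.synthetic import GeneratorConfig, MetalGenParams, generate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tox() -> ToxicologyParams:
    return ToxicologyParams()


@pytest.fixture(scope="session")
def consumption() -> ConsumptionTable:
    return ConsumptionTable()


@pytest.fixture
def summary_factory():
    """Build a DailyMetalSummary with sensible defaults."""

    def make(
        metal=Metal.CADMIUM,
        p_max=1.5,
        p_avg=1.0,
        x_q50=0.2,
        x_q95=0.29,
        n_samples=3,
        date=datetime.date(2020, 3, 1),
    ):
        return DailyMetalSummary(
            date=date,
            metal=metal,
            n_samples=n_samples,
            p_max=p_max,
            p_avg=p_avg,
            x_q50=x_q50,
            x_q95=x_q95,
        )

    return make


@pytest.fixture(scope="session")
def small_generated():
    """A compact synthetic dataset (60 days, light sampling) plus truth."""
    cfg = GeneratorConfig(
        n_days=60,
        metals={
            m: MetalGenParams(
                daily_count_mean=20, median=p.median, sigma=p.sigma, lod=p.lod
            )
            for m, p in GeneratorConfig().metals.items()
        },
        seed=7,
    )
    records, truth = generate(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default 300-day pipeline run (seed 0), shared across tests."""
    from metalrisk.pipeline import run_pipeline

    return run_pipeline(seed=0, n_days=300)
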