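"""Shared fixtures: one fully analyzed synthetic ensemble member.

The default-configuration pipeline run is expensive enough (~6 s) that the
tests needing its outputs share a single session-scoped run.
"""

from __future__ import annotations

import numpy as np
import pytest

from pco2season.grid import build_masks
from pco2season.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_grid():
    grid, regions = build_masks()
    return grid, regions


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline on the default synthetic scenario, one member (seed 0)."""
    return run_pipeline(PipelineConfig(seeds=(0,)))


@pytest.fixture(scope="session")
def member(pipeline_result):
    return pipeline_result.members[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
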