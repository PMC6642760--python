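import numpy as np
import pandas as pd
import pytest

from harkit import (CohortConfig, PipelineParams, WindowSpec, generate_cohort)
from harkit.optflow import FlowParams


@pytest.fixture(scope="session")
def tiny_config() -> CohortConfig:
    """Two subjects, 2-3 repetitions, small frames: enough structure for
    every stage without slowing the suite."""
    return CohortConfig(n_subjects=2, reps_range=(2, 3), video_size=(60, 48), seed=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_recordings(tiny_cohort):
    return tiny_cohort[0]


@pytest.fixture(scope="session")
def tiny_segments(tiny_cohort) -> pd.DataFrame:
    return tiny_cohort[1]


@pytest.fixture(scope="session")
def fast_pipeline_params() -> PipelineParams:
    """Pipeline settings matched to the synthetic desk-scale clips: flow
    threshold below the rendered silhouette speeds, fewer Jacobi sweeps."""
    return PipelineParams(window=WindowSpec(),
                          flow=FlowParams(T=0.3, n_iter=40),
                          split_seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
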