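import warnings

import pandas as pd
import pytest

from eistrat import pipeline
from eistrat.config import PipelineConfig, SelectionConfig, SimConfig, TrainingConfig


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    """Small, fast end-to-end configuration for shape/determinism tests."""
    return PipelineConfig(
        sim=SimConfig(n_participants=16, frames_per_video=80, seed=0),
        selection=SelectionConfig(k_per_dimension=20),
        training=TrainingConfig(
            stage_schedule=[
                {"scope": "heads", "epochs": 2, "lr": 3e-4},
                {"scope": "all", "epochs": 2, "lr": 1e-4},
            ]
        ),
        repetitions=2,
        seed=3,
    )


@pytest.fixture(scope="session")
def default_state() -> dict:
    """Pipeline state at default study-scale settings (44 participants,
    4 quadrant videos, 300 frames/video, k = 100), with two training
    repetitions; shared across tests that probe study-scale behavior."""
    cfg = PipelineConfig(repetitions=2, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state = pipeline.simulate_tables(cfg)
        pipeline.assess_stage(state, cfg)
        pipeline.select_stage(state, cfg)
        pipeline.evaluate_stage(state, cfg)
        pipeline.compare_stage(state, cfg)
    state["config"] = cfg
    return state


@pytest.fixture(scope="session")
def default_labels(default_state) -> pd.DataFrame:
    return default_state["labels"]
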