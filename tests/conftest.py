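"""Shared fixtures: a small simulated plate reused across the suite.

All fixtures are generated programmatically — no binary files ship with
the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from pmtraffic.config import PipelineConfig
from pmtraffic.pipeline_io import load_layout, run_pipeline
from pmtraffic.synthetic_plate import (
    ConditionSpec,
    GroundTruth,
    SimulationConfig,
    simulate_plate,
)


def demo_simulation_config(seed: int = 11) -> SimulationConfig:
    """A 5-condition plate exercising apoptosis, saturation and defocus."""
    return SimulationConfig(
        image_shape=(192, 192),
        conditions=[
            ConditionSpec(
                "scrambled",
                true_traffic_efficiency=0.5,
                n_cells_mean=25,
                control_role="negative",
            ),
            ConditionSpec(
                "apo",
                true_traffic_efficiency=0.5,
                n_cells_mean=25,
                frac_apoptotic=0.3,
                frac_saturating=0.1,
            ),
            ConditionSpec(
                "defoc",
                true_traffic_efficiency=0.5,
                n_cells_mean=25,
                frac_defocused_fields=0.4,
            ),
            ConditionSpec("enhancer_like", true_traffic_efficiency=0.7, n_cells_mean=25),
            ConditionSpec(
                "transfection_ctrl",
                true_traffic_efficiency=0.5,
                n_cells_mean=25,
                control_role="transfection_control",
            ),
        ],
        fields_per_well=4,
        replicate_wells_per_condition=3,
        seed=seed,
    )


def fast_pipeline_config() -> PipelineConfig:
    """Pipeline config with a smaller smoothing kernel for test speed."""
    return PipelineConfig(smoothing_scale=31)


@pytest.fixture(scope="session")
def plate_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("plate")
    simulate_plate(demo_simulation_config(), outdir=outdir)
    return outdir


@pytest.fixture(scope="session")
def plate_truth(plate_dir) -> GroundTruth:
    return GroundTruth.read(plate_dir)


@pytest.fixture(scope="session")
def plate_layout(plate_dir):
    return load_layout(plate_dir / "layout.csv")


@pytest.fixture(scope="session")
def pipeline_result(plate_dir, plate_layout):
    return run_pipeline(plate_dir, plate_layout, fast_pipeline_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
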