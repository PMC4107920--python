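"""Shared fixtures: a binned small-detector configuration that keeps
per-frame cost low while preserving the full beam/cell physics, plus
cached simulated frames and measurement streams."""

from __future__ import annotations

import numpy as np
import pytest

from ssxkit.config import PipelineConfig, SimulationParams
from ssxkit.physics import DetectorSpec
from ssxkit.simulator import iter_simulated_frames, simulate_measurements


def small_detector() -> DetectorSpec:
    """A 4×4-binned Pilatus-like panel: same solid angle and edge
    resolution as the default geometry at 1/16 the pixel count."""
    return DetectorSpec(n_fast=620, n_slow=620, pixel_size=0.688,
                        distance=300.0, beam_center_fast=310.0,
                        beam_center_slow=310.0)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(detector=small_detector())


@pytest.fixture(scope="session")
def clean_config() -> PipelineConfig:
    """Small detector, no arc smear — for truth-matching tests."""
    return PipelineConfig(detector=small_detector(),
                          simulation=SimulationParams(rolling_fraction=0.0))


@pytest.fixture(scope="session")
def single_hit_frames(clean_config):
    """Eight simulated single-crystal frames with truth and events."""
    return list(iter_simulated_frames(clean_config, 8, seed=42,
                                      force_singles=True))


@pytest.fixture(scope="session")
def measurement_stream():
    """300 patterns of measurement-level simulation, default geometry."""
    cfg = PipelineConfig()
    return cfg, simulate_measurements(cfg, 300, seed=11)
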