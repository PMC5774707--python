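"""Shared fixtures: generator configs, templates, a reusable annotated cell."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from apdecomp.config import AnalysisConfig
from apdecomp.pipeline import annotate_cell
from apdecomp.synthetic import GeneratorConfig, gen_recording, true_template_set

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def true_tpl(gen_config):
    return true_template_set(gen_config)


@pytest.fixture(scope="session")
def recording(gen_config):
    """One 6-minute synthetic recording with ground truth."""
    cfg = gen_config.replace(seed=101, duration_min=6.0, ap_rate=2.0,
                             sejp_rate=3.0, typeb_rate=0.2)
    return gen_recording(cfg)


@pytest.fixture(scope="session")
def annotated(recording, analysis_config):
    """The same recording after full event detection."""
    return annotate_cell(recording.id, recording.trace, analysis_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
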