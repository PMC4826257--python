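from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from consurvey.synthgen import SimConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A few-second study: 30+60 genes, 3 species, 1 sequence species."""
    return SimConfig(
        n_targets=30,
        n_nontargets=60,
        species=("amel", "btau", "cfam"),
        sequence_species=("amel",),
        seq_len_range=(40, 80),
        seed=20240917,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture(scope="session")
def tiny_study_dir(tiny_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    simulate_study(tiny_config, out_dir=out)
    return out
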