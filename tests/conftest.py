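"""Shared fixtures: desk-scale synthetic study used by the heavier tests.

The full multi-participant study (synthesis -> detection -> EEMD/HFA ->
similarity -> group statistics) is expensive, so it runs once per session
and is shared by the detector-validity and effect-recovery tests.
"""

import numpy as np
import pytest

from ripplemem import pipeline


@pytest.fixture(scope="session")
def scaled_study():
    cfg = pipeline.desk_scale_config(seed=11)
    return pipeline.simulate_study(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
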