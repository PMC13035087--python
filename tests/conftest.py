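import numpy as np
import pytest

from vrnirs.protocol import CycleParams, ProtocolTiming, make_protocol
from vrnirs.synth import QUIET, NeuralTruth, default_truth, simulate_subject


@pytest.fixture(scope="session")
def short_design():
    """Compressed session (2 movement cycles, 60 s VR blocks) for fast tests."""
    return make_protocol(
        CycleParams(n_cycles=2),
        vr_duration_s=60.0,
        timing=ProtocolTiming(lead_in_s=20, between_sides_s=20, pre_vr_rest_s=30,
                              between_vr_s=20, tail_s=10),
    )


@pytest.fixture(scope="session")
def full_design():
    """Study-layout session: 10 cycles per side, 6-minute VR blocks."""
    return make_protocol()


@pytest.fixture(scope="session")
def quiet_truth():
    t = default_truth("pre")
    return NeuralTruth(beta=t.beta, shared_components=[])


@pytest.fixture(scope="session")
def quiet_recording(short_design, quiet_truth):
    """Noise-free forward-model recording on the short design."""
    return simulate_subject(short_design, quiet_truth, QUIET, age=47.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
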