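import numpy as np
import pytest

from fsampen import (
    ProtocolSpec,
    gen_subject,
    preprocess_subject,
    segment_subject,
)

#: Scaled-down protocol shared across tests: two threshold loads, four
#: breaths per condition, EMG generated directly at the 2000 Hz analysis rate.
SMALL_PROTOCOL = ProtocolSpec(
    fs_pressure=100.0,
    fs_emg=2000.0,
    fs_mmg=500.0,
    load_fractions=(0.24, 0.48),
    breaths_per_condition=4,
    insp_duration_s=1.0,
    exp_duration_s=1.5,
    pressure_noise_sd=0.05,
    seed=11,
)


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolSpec:
    return SMALL_PROTOCOL


@pytest.fixture(scope="session")
def healthy_subject(small_protocol):
    return gen_subject(small_protocol, montage="healthy", seed=7)


@pytest.fixture(scope="session")
def processed_subject(healthy_subject):
    proc = preprocess_subject(healthy_subject)
    segment_subject(proc)
    return proc
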