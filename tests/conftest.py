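import numpy as np
import pytest

from ppgrhythm.synth import PPGRecord, RhythmClass, SimParams, simulate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_params():
    """Study-condition generator parameters at a desk-scale duration."""
    return SimParams(duration_s=30.0, seed=7)


@pytest.fixture(scope="session")
def one_record_per_class(short_params):
    return {
        label: simulate_record(label, short_params, seed=100 + int(label))
        for label in RhythmClass
    }


def make_stub_record(record_id: str, label: RhythmClass,
                     fs: float = 10.0, n: int = 10) -> PPGRecord:
    """Cheap record for split/bookkeeping tests (waveform content unused)."""
    return PPGRecord(samples=np.zeros(n), fs=fs, label=label,
                     record_id=record_id)
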