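import numpy as np
import pytest

from ecgattn.records import BeatAnnotation, ECGRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(
    n_samples=1000,
    n_leads=2,
    fs=360.0,
    ann=((100, "N"), (400, "A"), (700, "V")),
    record_id="rec",
    seed=0,
):
    """A small record with deterministic noise and the given annotations."""
    r = np.random.default_rng(seed)
    signals = r.normal(0, 0.1, size=(n_samples, n_leads))
    return ECGRecord(
        record_id=record_id,
        fs=fs,
        signals=signals,
        lead_names=[f"L{i}" for i in range(n_leads)],
        annotations=[BeatAnnotation(i, s) for i, s in ann],
    )


@pytest.fixture
def tiny_record():
    return make_record()
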