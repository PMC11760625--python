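import numpy as np
import pytest

from lfpseg.core import AnnotationTrack, EventInterval, LFPRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_track():
    return AnnotationTrack(
        intervals=[
            EventInterval(2.0, 4.0, 1),
            EventInterval(10.0, 30.0, 2),
            EventInterval(40.0, 41.5, 1),
        ],
        duration_s=60.0,
    )


def make_noise_record(seed: int, n: int, fs: float = 2000.0) -> LFPRecord:
    rng = np.random.default_rng(seed)
    return LFPRecord(rng.standard_normal(n), fs, record_id=f"noise-{seed}")
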