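import numpy as np
import pytest
from hypothesis import settings

import beatwise as bw

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> bw.SynthConfig:
    return bw.SynthConfig(seed=1)


@pytest.fixture(scope="session")
def synth_record(default_cfg) -> bw.SynthRecord:
    """The standard noisy 300-beat record (240 s @ 360 Hz, 20 dB SNR)."""
    return bw.generate(default_cfg)


@pytest.fixture(scope="session")
def clean_record() -> bw.SynthRecord:
    """Noiseless, wander-free record for geometry-sensitive tests."""
    return bw.generate(bw.SynthConfig(seed=2, duration=60.0, noise_snr=None,
                                      baseline_amp=0.0))


@pytest.fixture(scope="session")
def oracle(default_cfg) -> bw.OracleBeatDetector:
    return bw.oracle_detector(bw.make_template(default_cfg))


@pytest.fixture(scope="session")
def segmentation(synth_record, oracle) -> bw.SegmentationResult:
    """One full adaptive-windowing run shared by the invariant tests."""
    return bw.segment_record(synth_record.record, oracle)


@pytest.fixture()
def annotated_short_record() -> bw.EcgRecord:
    """A small noiseless record with exact annotations for augmentation."""
    sr = bw.generate(bw.SynthConfig(seed=7, duration=20.0, noise_snr=None,
                                    baseline_amp=0.0))
    return sr.record
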