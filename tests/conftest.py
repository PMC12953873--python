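import numpy as np
import pandas as pd
import pytest

from choirsync import (
    PerformanceSimConfig,
    default_design,
    tiny_design,
)
from choirsync import simulate as sim


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_design():
    return tiny_design(conditions=("modern", "touch", "no_touch"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_perf_cfg():
    """All noise off: both streams render the score exactly."""
    return PerformanceSimConfig(
        onset_jitter_sd=0.0,
        shared_timing_sd=0.0,
        pitch_jitter_sd=0.0,
        drift_slope=0.0,
        pitch_offset=0.0,
        gross_pitch_error_rate=0.0,
        gross_onset_error_rate=0.0,
        omission_rate=0.0,
    )


def tag_streams(a: pd.DataFrame, b: pd.DataFrame, voice="soprano") -> pd.DataFrame:
    """Label a unison pair of streams as one recording instance."""
    frames = []
    for i, s in ((1, a), (2, b)):
        s = s.copy()
        s["singer"] = f"{voice}_{i}"
        s["condition"] = "modern"
        s["block"] = 0
        s["repeat"] = 0
        s["unit"] = "u"
        frames.append(s)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def unison_pair():
    """A moderately noisy unison recording used by several cascade tests."""
    score = sim.make_score("soprano", "p1", 80, seed=5)
    cfg = PerformanceSimConfig(seed=5)
    a, b = sim.generate_unison_performance(score, cfg, rng=np.random.default_rng(5))
    return score, tag_streams(a, b)
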