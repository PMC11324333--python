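import numpy as np
import pytest

from sitpose.preprocess import TimeSeriesPlanar
from sitpose.synthetic import CohortConfig


def make_series(values, rate=100.0, start=0.0):
    """Build a TimeSeriesPlanar from an (n, 2) array at a uniform rate."""
    values = np.asarray(values, dtype=float)
    t = start + np.arange(values.shape[0]) / rate
    return TimeSeriesPlanar(t, values, rate)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


#: Reduced problem-size settings for simulation-heavy checks: short,
#: coarser reach trials and no COP/training/questionnaire blocks.  The
#: design structure (3 groups, 8 directions, pre/post) is unchanged.
FAST_REACH_ONLY = dict(
    trial_duration_s=1.0,
    rate_hz=25.0,
    include_cop=False,
    include_training=False,
    include_questionnaires=False,
)


def fast_config(**overrides) -> CohortConfig:
    kwargs = {**FAST_REACH_ONLY, **overrides}
    return CohortConfig(**kwargs)
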