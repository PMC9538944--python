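import numpy as np
import pytest

from fishbcf import DepletionTimecourse
from fishbcf.depletion import STANDARD_TIMES_H


def make_timecourse(times, conc, **overrides):
    defaults = dict(
        run_id="run-1",
        species="trout",
        chemical="MXC",
        cell_state="fresh",
        condition="live",
        replicate_id=1,
    )
    defaults.update(overrides)
    return DepletionTimecourse(
        times=np.asarray(times, dtype=float),
        concentrations=np.asarray(conc, dtype=float),
        **defaults,
    )


@pytest.fixture
def exact_exponential():
    """Noiseless first-order decay on the standard 8-point assay grid."""
    t = np.array(STANDARD_TIMES_H)
    k, c0 = 0.5, 2.0
    return t, c0 * np.exp(-k * t), k, c0


@pytest.fixture
def tc_factory():
    return make_timecourse
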