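import hypothesis
import numpy as np
import pytest

from msft import GravityTrace, load_paired_results

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def case_study():
    """Packaged seven-volunteer case-study table, keyed by test item."""
    return load_paired_results()


@pytest.fixture
def make_trace():
    """Trace factory from a y-channel; z completes the norm, x is zero."""

    def _make(y, rate=50.0, g=9.81):
        y = np.asarray(y, dtype=float)
        t = np.arange(y.size) / rate
        z = np.sqrt(np.maximum(g**2 - y**2, 0.0))
        return GravityTrace(t, np.column_stack([np.zeros_like(y), y, z]),
                            sample_rate_hz=rate)

    return _make
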