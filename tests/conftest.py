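import numpy as np
import pytest
from dataclasses import replace

import csaeeg as c

#: Reduced sampling rate used for signal-level tests; the 2-s epochs keep
#: the 0.5 Hz grid and every threshold unchanged, synthesis just gets cheap.
TEST_FS = 256.0


@pytest.fixture
def fast_config():
    return replace(c.PipelineConfig(), fs=TEST_FS)


@pytest.fixture
def make_recording():
    """Synthesize a posterior-only recording of a given pattern archetype."""

    def _make(pattern="1", seed=0, duration=182.0, fs=TEST_FS, **overrides):
        arch = c.DEFAULT_ARCHETYPES[pattern]
        if overrides:
            from dataclasses import replace as _r

            arch = _r(arch, **overrides)
        return c.synthesize_recording(
            arch, c.POSTERIOR, duration=duration, fs=fs, seed=seed
        )

    return _make


@pytest.fixture
def flat_csa():
    """CSA with unit power in every 1-12 Hz bin (zero elsewhere)."""
    freqs = np.arange(0.5, 70.0 + 0.25, 0.5)
    power = np.zeros((4, freqs.size))
    power[:, (freqs >= 1.0) & (freqs <= 12.0)] = 1.0
    return c.CSAMatrix(power=power, freqs=freqs, label="flat")
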