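import numpy as np
import pytest

from hrvkit import HRVConfig, SynthParams, synth_ibi


@pytest.fixture(scope="session")
def config() -> HRVConfig:
    return HRVConfig()


@pytest.fixture
def tone_series():
    """Factory: noise-free single-tone IBI series for oracle checks."""

    def make(freq_hz=0.25, amp_ms=56.34, duration_s=300.0, mean_ibi_ms=1000.0, seed=0):
        params = SynthParams(
            mean_ibi_ms=mean_ibi_ms,
            resp_hz=freq_hz,
            resp_amp_ms=amp_ms,
            lf_amp_ms=0.0,
            noise_sd_ms=0.0,
            artifact_rate=0.0,
            seed=seed,
        )
        return synth_ibi(params, duration_s)

    return make


def closed_form_ln_variance(amp_ms: float) -> float:
    """Variance of a sinusoid of amplitude A is A^2/2."""
    return float(np.log(amp_ms**2 / 2.0))
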