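import numpy as np
import pytest

from strokephys.ephys import epoch_and_average
from strokephys.synth import CohortConfig, gen_evoked_lfp


@pytest.fixture(scope="session")
def noiseless_subject():
    """One noiseless sham subject with single-pulse and ISI-50 recordings."""
    cfg = CohortConfig(condition="sham", n_subjects=1, seed=7, noise_sd=0.0,
                       n_trials=3, trial_spacing=1.0)
    return gen_evoked_lfp(cfg, [None, 50])[0]


@pytest.fixture(scope="session")
def noiseless_average(noiseless_subject):
    return epoch_and_average(noiseless_subject.recordings[None], (-50.0, 250.0))


def make_flat_average(value=0.0, n_channels=4, sr=1000.0,
                      window=(-50.0, 250.0), depths_step=100.0):
    """Hand-built EvokedAverage with a constant trace."""
    from strokephys.ephys import EvokedAverage

    times = np.arange(round(window[0] * sr / 1e3), round(window[1] * sr / 1e3) + 1) / sr * 1e3
    trace = np.full((n_channels, times.size), float(value))
    return EvokedAverage(mean_trace=trace, sem_trace=np.zeros_like(trace),
                         times_ms=times, n_trials=1, sample_rate=sr,
                         channel_depths=(np.arange(n_channels) + 1) * depths_step)
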