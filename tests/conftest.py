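import numpy as np
import pytest

import strfglm as sg
from strfglm.glm import GLMConfig, GLMParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def tiny_params(n_freq=3, n_lags=4, J=2, seed=0, nonlinearity="exp",
                scale=0.3):
    """Small random GLM parameter set for oracle comparisons."""
    r = np.random.default_rng(seed)
    return GLMParams(k=scale * r.standard_normal((n_freq, n_lags)),
                     h=scale * r.standard_normal(J),
                     b=np.log(12.0) + 0.1 * r.standard_normal(),
                     nonlinearity=nonlinearity, bin_width_ms=3.0)


def tiny_instance(n_freq=3, n_lags=4, J=2, T=200, seed=0,
                  nonlinearity="exp"):
    """Random small (spectrogram, spikes, params) triple on a 3 ms grid."""
    r = np.random.default_rng(seed + 1)
    spec = sg.Spectrogram(values=r.standard_normal((T, n_freq)),
                          bin_width_ms=3.0,
                          freq_centers_hz=sg.default_freq_centers(n_freq),
                          is_log=True, stimulus_id=f"tiny{seed}")
    params = tiny_params(n_freq, n_lags, J, seed, nonlinearity)
    spikes = sg.simulate_glm(params, spec, n_trials=3, seed=seed + 2)
    return spec, spikes, params


@pytest.fixture(scope="session")
def white_fit_pair():
    """A moderately sized white-noise recovery problem solved once and
    shared: (true params, fitted params, config).  Used by recovery,
    sparsity and tuning-consistency checks."""
    ens = sg.make_ensemble("white", 8, 2.0, seed=42)
    neuron = sg.make_neuron("gabor", ens.spectrograms, 15.0, seed=7)
    data = [(s, sg.simulate_glm(neuron.params, s, 10, seed=300 + i))
            for i, s in enumerate(ens)]
    cfg = GLMConfig(seed=0, track_trace=False)
    fit = sg.fit_glm(data, 2.0, cfg)
    return neuron.params, fit, data, cfg
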