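import numpy as np
import pytest
from hypothesis import settings

import optoclock as oc

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """Default parameter set: alpha=0.75/h, beta=300/h, n=3, beta'=80/h."""
    return oc.OptoParams()


@pytest.fixture(scope="session")
def T0(params):
    """Free-running period of the default oscillator (close to 17.5 h)."""
    return oc.natural_period(params)


@pytest.fixture(scope="session")
def prc64(params, T0):
    """64-point phase response curve for the standard 2 h, 80/h pulse."""
    return oc.compute_prc(params, tau=2.0, beta_prime_pulse=80.0, n_points=64, T0=T0)


@pytest.fixture(scope="session")
def free_running_mean():
    """Population mean of a dephasing 200-cell ensemble under constant red."""
    spec = oc.EnsembleSpec(n_cells=200, seed=3)
    res = oc.simulate_ensemble(spec, oc.LightProtocol.constant("off"), t_end=24 * 17.5)
    return res.times, res.population_mean


def contrast_amplitudes(times, signal, min_separation=2.0):
    """Peak-to-following-trough amplitudes of an oscillatory signal."""
    peaks = oc.detect_peaks(times, signal, min_separation=min_separation,
                            min_prominence=0.02)
    heights = np.interp(peaks, times, signal)
    amps = []
    for k in range(len(peaks) - 1):
        between = (times > peaks[k]) & (times < peaks[k + 1])
        amps.append(heights[k] - signal[between].min())
    return np.asarray(amps)
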