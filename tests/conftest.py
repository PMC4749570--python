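import warnings

import numpy as np
import pytest

from perigate.experiments import (ExperimentConfig, _default_params,
                                  amplitude_for_contrast)
from perigate.gating import run_gating_model
from perigate.stimuli import PeripheralSchedule, gen_pink_noise

# windowed fits on sparse windows legitimately warn; keep test output clean
warnings.filterwarnings("ignore", message="only .* spikes")
warnings.filterwarnings("ignore", message="conditioning cell")
warnings.filterwarnings("ignore", message="center cell")
warnings.filterwarnings("ignore", message="only .* distinct values")


@pytest.fixture(scope="session")
def pink_gating_run():
    """One reference gating-model run on 10% pink noise with a shifting
    periphery, shared by analysis tests."""
    dt = 0.025
    stim = gen_pink_noise(300.0, dt, 0.10, seed=421)
    schedule = PeripheralSchedule.regular(300.0, 1.0)
    params = _default_params(dt, A=amplitude_for_contrast(0.10, theta_sd=1.5))
    rate, spikes = run_gating_model(stim, schedule, params, n_trials=20,
                                    seed=422)
    return {"stim": stim, "schedule": schedule, "params": params,
            "rate": rate, "spikes": spikes}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250919)
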