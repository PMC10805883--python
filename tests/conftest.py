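import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stopcancel as sc
from stopcancel import emg

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_params():
    return sc.RaceModelParams()


@pytest.fixture(scope="session")
def sst_session(default_params):
    """A 1,000-trial SST run with traces on stop trials, plus a CRT
    reference session -- shared by phenotype / recovery tests."""
    rng = np.random.default_rng(1234)
    crt = sc.simulate_session(
        default_params, sc.generate_session("CRT", seed=11, n_trials=100, n_practice=0), rng
    )
    ref_peak = emg.reference_peak(crt.trials, crt.traces)
    sim = sc.simulate_session(
        default_params,
        sc.generate_session("SST", seed=12, n_trials=1000, n_practice=0),
        rng,
        traces_for="stop",
    )
    results = emg.process_session_emg(sim.trials[sim.trials["is_stop"]], sim.traces, ref_peak)
    return {"crt": crt, "sim": sim, "ref_peak": ref_peak, "emg": results}
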