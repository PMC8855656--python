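import numpy as np
import pytest

import hcosim as H


@pytest.fixture(scope="session")
def params():
    return H.canonical_parameters()


@pytest.fixture(scope="session")
def short_hco_trace(params):
    """Canonical HCO with a shortened transient; episodic and cheap."""
    return H.integrate(params, transient=300.0, record=300.0)


@pytest.fixture(scope="session")
def short_single_trace(params):
    return H.integrate(H.decouple(params), ncell=1,
                       transient=300.0, record=200.0)


@pytest.fixture(scope="session")
def synthetic_vm():
    spec = H.SyntheticTraceSpec(mode="vm", duration=200.0,
                                episode_period=50.0, episode_duration=20.0,
                                burst_rate=1.0, seed=1)
    return H.generate_synthetic_trace(spec)


@pytest.fixture(scope="session")
def synthetic_neurogram():
    spec = H.SyntheticTraceSpec(mode="neurogram", duration=300.0,
                                episode_period=50.0, episode_duration=20.0,
                                burst_rate=5.0, noise_sd=0.05,
                                sample_dt=0.01, seed=2)
    return H.generate_synthetic_trace(spec)


@pytest.fixture(scope="session")
def sym_state(params):
    c = H.steady_state_cell(-55.0, params, nai=18.0)
    return H.HCOState(c, c)
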