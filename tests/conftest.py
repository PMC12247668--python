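import numpy as np
import pytest

from hvcseq import (
    NetworkParameters,
    apply_boundary_compensation,
    build_connectivity,
    canned_configs,
    simulate,
)


@pytest.fixture(scope="session")
def default_params():
    return NetworkParameters()


@pytest.fixture(scope="session")
def default_conn(default_params):
    return apply_boundary_compensation(build_connectivity(default_params), default_params)


@pytest.fixture(scope="session")
def configs():
    return canned_configs()


@pytest.fixture(scope="session")
def song_trace(configs, default_conn):
    """One noise-free default-song run covering two full motifs."""
    cfg = configs["default_song"]
    return simulate(cfg["params"], default_conn, cfg["protocol"], 2400.0, seed=0)


@pytest.fixture(scope="session")
def pulse_trace(configs, default_conn):
    """Noise-free run truncated by the canned mid-motif pulse."""
    cfg = configs["pulse_mid"]
    return simulate(cfg["params"], default_conn, cfg["protocol"], cfg["duration"], seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
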