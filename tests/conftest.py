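import numpy as np
import pytest

from svpop.protocol import StimProtocol
from svpop.synthetic import KineticParams, RenderParams, render_movie, simulate_pools


@pytest.fixture(scope="session")
def default_protocol() -> StimProtocol:
    return StimProtocol()


@pytest.fixture(scope="session")
def fast_protocol() -> StimProtocol:
    """Short two-train protocol used to keep rendered-movie tests cheap."""
    return StimProtocol(
        frame_interval=2.0,
        train_onsets=[20.0, 96.0],
        train_n_aps=[150, 150],
        train_freq=10.0,
        baf_time=66.0,
        nh4cl_time=130.0,
        total_duration=150.0,
    )


@pytest.fixture(scope="session")
def default_kinetics() -> KineticParams:
    return KineticParams()


@pytest.fixture(scope="session")
def depletion_protocol() -> StimProtocol:
    """Single 1200-AP train with Baf: maximally depletes the releasable pool."""
    return StimProtocol(
        train_onsets=[60.0],
        train_n_aps=[1200],
        baf_time=30.0,
        nh4cl_time=200.0,
        total_duration=230.0,
    )


@pytest.fixture(scope="session")
def rendered_default_field(default_protocol, default_kinetics):
    """50 identical-kinetics boutons rendered at default SNR (seed 0)."""
    pools = simulate_pools(default_kinetics, default_protocol)
    rng = np.random.default_rng(0)
    rf = render_movie(np.tile(pools.f, (50, 1)), RenderParams(), rng)
    return rf, pools
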