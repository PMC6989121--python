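import numpy as np
import pytest

from ninsync import SynthConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """A short two-region session with planted synchrony and behavior."""
    cfg = SynthConfig(duration_s=120.0, seed=7)
    return cfg, simulate_session(cfg)


@pytest.fixture(scope="session")
def coupled_session():
    """Every planted synchronous event is followed by a movement bout."""
    cfg = SynthConfig(
        duration_s=400.0,
        seed=11,
        p_move_given_sp=1.0,
        sp_rate_hz=0.05,  # SPs well separated so 2 s windows rarely overlap
        n_cells_a=2,
        n_cells_b=2,
        rearing_rate_per_min=0.0,
        turn_rate_per_min=0.0,
        spont_bout_rate_hz=0.0,
    )
    return cfg, simulate_session(cfg)


@pytest.fixture(scope="session")
def stim_session():
    """Stimulation session with known per-cell response classes."""
    cfg = SynthConfig(
        duration_s=220.0,
        seed=3,
        n_stimuli=10,
        stim_isi_s=20.0,
        sp_rate_hz=0.0,
        rearing_rate_per_min=0.0,
    )
    return cfg, simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
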