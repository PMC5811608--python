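import numpy as np
import pytest

import protconf as pc


def make_stream(timestamps, channel=None, excitation=None):
    """Photon stream with default all-donor tags."""
    t = np.asarray(timestamps, dtype=np.int64)
    ch = np.zeros(len(t), np.uint8) if channel is None else np.asarray(channel, np.uint8)
    ex = np.zeros(len(t), np.uint8) if excitation is None else np.asarray(excitation, np.uint8)
    return pc.PhotonStream(t, ch, ex)


@pytest.fixture(scope="session")
def single_state_run():
    """One-state measurement (E* = 0.58) with the calibrated corrections
    embedded, analyzed end to end; shared across tests."""
    cfg = pc.SimConfig(duration_s=60, burst_rate=50, states=((1.0, 0.58),), seed=42)
    stream, truth = pc.simulate_photon_stream(cfg)
    df = pc.analyze_stream(stream)
    return cfg, stream, truth, df


@pytest.fixture(scope="session")
def two_state_run():
    """Default 80/20 closed/open mixture, analyzed end to end."""
    cfg = pc.SimConfig(duration_s=120, burst_rate=50, seed=7)
    stream, truth = pc.simulate_photon_stream(cfg)
    df = pc.analyze_stream(stream)
    return cfg, stream, truth, df


@pytest.fixture(scope="session")
def toy_dumbbell():
    """Two 40-atom domains 45 A apart; site residues 1 and 41."""
    return pc.generate_toy_structure(40, 10.0, 45.0, seed=7)
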