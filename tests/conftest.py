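import numpy as np
import pandas as pd
import pytest

from tntfusion import synth
from tntfusion.containers import EpochedEEG


def make_epochs(data, sfreq=250.0, t0_ms=-500.0, ch_names=None,
                conditions=None, learned=None):
    """Small EpochedEEG factory for hand-built arrays."""
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_s = data.shape
    times = t0_ms + 1000.0 / sfreq * np.arange(n_s)
    ch_names = ch_names or [f"ch{i}" for i in range(n_ch)]
    meta = pd.DataFrame({
        "condition": conditions if conditions is not None
        else ["No-Think"] * n_tr,
        "learned": learned if learned is not None else [True] * n_tr,
        "block": 0,
        "onset_s": np.arange(n_tr, dtype=float) * 5.0,
        "artifact": False,
        "run": 0,
    })
    return EpochedEEG(data=data, sfreq=sfreq, times=times,
                      ch_names=ch_names, metadata=meta)


@pytest.fixture(scope="session")
def tiny_config():
    """Six-participant configuration used for cheap end-to-end checks."""
    return synth.reduced_config(seed=7, n_participants=6)


@pytest.fixture(scope="session")
def one_participant(tiny_config):
    return synth.simulate_participant(tiny_config, 0)


@pytest.fixture(scope="session")
def one_participant_truth(tiny_config):
    sources, events, truth = synth.simulate_sources(tiny_config, 0)
    return sources, events, truth
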