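import numpy as np
import pytest

from deglutio import dataset as ds
from deglutio import signalproc as sp
from deglutio import simulate as sim
from deglutio.labels import EVENT_LABELS


@pytest.fixture(scope="session")
def uniform_mix():
    return {lab: 1.0 / len(EVENT_LABELS) for lab in EVENT_LABELS}


@pytest.fixture(scope="session")
def small_session(uniform_mix):
    """3 participants x 4 events, short gaps to keep tests fast."""
    return sim.generate_session(3, 4, uniform_mix, seed=11, gap_s=4.0)


@pytest.fixture(scope="session")
def preprocessed_session(small_session):
    return [sp.preprocess_recording(r) for r in small_session]


@pytest.fixture(scope="session")
def small_epochs(preprocessed_session):
    epochs = []
    for rec in preprocessed_session:
        eps = ds.segment(rec)
        eps, _ = ds.augment(eps, rec, n_shifts=1)
        epochs.extend(eps)
    return epochs


def make_rest_recording(duration_s: float = 10.0, fs_hz: float = 250.0,
                        seed: int = 0, participant: str = "P001"):
    """Plain noise recording at the model rate, no annotations."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs_hz)
    return sim.MultimodalRecording(
        rng.normal(0, 1.0, n), rng.normal(0, 1.0, n), rng.normal(0, 0.01, n),
        fs_hz, participant, [],
    )
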