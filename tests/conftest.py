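import numpy as np
import pytest

from binlat.cohort import ListenerModel, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ideal_session():
    """Noiseless, unbiased, unit-gain listener: every entry is forced."""
    model = ListenerModel()
    return simulate_session(
        model, np.random.default_rng(0), "IDEAL", "control", "control"
    )


@pytest.fixture
def noisy_session_factory():
    """Random synthetic sessions with varied generative parameters."""

    def make(seed: int):
        r = np.random.default_rng(seed)
        model = ListenerModel(
            gain_itd=float(r.uniform(0.5, 1.1)),
            gain_ild=float(r.uniform(0.5, 1.1)),
            bias=float(r.uniform(-1.5, 1.5)),
            response_noise_sd=float(r.uniform(0.2, 1.5)),
            confusion_prob=float(r.uniform(0, 0.3)),
            side_oriented=bool(r.random() < 0.15),
        )
        return simulate_session(model, r, f"S{seed}", "patient", "acute")

    return make
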