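import numpy as np
import pytest

from bandcsp.synthetic import SimConfig, generate


@pytest.fixture(scope="session")
def small_planted():
    """Desk-scale planted-band data: 8 ch, 30 trials/class, 10–14 Hz source."""
    cfg = SimConfig(trials_per_class=30)
    return generate(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_epochs():
    """Minimal random two-class epochs for structural checks."""
    rng = np.random.default_rng(0)
    from bandcsp.epochs import EpochSet

    X = rng.standard_normal((12, 4, 64))
    y = np.array([1, 2] * 6)
    return EpochSet(X, y, fs=100.0)


def spd(rng, n):
    """Random symmetric positive-definite matrix."""
    A = rng.standard_normal((n, n))
    return A @ A.T + n * np.eye(n) * 0.1
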