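import numpy as np
import pytest

from sleepcortex.hypnogram import Hypnogram

#: 30-epoch toy hypnogram: 3 W, 2 N1, 10 N2, 2 W, 8 N2, 2 N3, 3 REM.
TOY_STAGES = (
    ("W",) * 3 + ("N1",) * 2 + ("N2",) * 10 + ("W",) * 2
    + ("N2",) * 8 + ("N3",) * 2 + ("REM",) * 3
)


@pytest.fixture
def toy_hypnogram() -> Hypnogram:
    return Hypnogram(TOY_STAGES)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_hypnogram(rng: np.random.Generator, max_epochs: int = 200) -> Hypnogram:
    """A random hypnogram with random lights bounds (for property tests)."""
    n = int(rng.integers(2, max_epochs + 1))
    stages = tuple(rng.choice(["W", "N1", "N2", "N3", "REM"], size=n))
    lights_off = int(rng.integers(0, n))
    lights_on = int(rng.integers(lights_off + 1, n + 1))
    return Hypnogram(stages, lights_off=lights_off, lights_on=lights_on)
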