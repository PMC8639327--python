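import numpy as np
import pytest

from riskval import build_battery
from riskval.lotteries import Lottery


@pytest.fixture(scope="session")
def battery():
    """Default 180-pair battery over the task's magnitude/probability sets."""
    return build_battery(n_pairs=180, seed=1)


@pytest.fixture(scope="session")
def random_lotteries():
    """1,000 random valid lotteries spanning the stimulus space."""
    rng = np.random.default_rng(7)
    out = []
    while len(out) < 1000:
        x = np.sort(rng.uniform(0, 50, size=2))[::-1]
        p = rng.uniform(0, 1)
        if x[0] == x[1]:
            continue
        out.append(Lottery(float(x[0]), float(x[1]), float(p)))
    return out
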