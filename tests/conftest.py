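import numpy as np
import pytest

import hepadial as hd


def mass_action_alpha(ctox: float, calb: float, kb: float) -> float:
    """Independent free-fraction oracle: bisection on the 1:1 mass-action
    system CT + kB·CT·CALB/(1 + kB·CT) = Ctox (free albumin eliminated
    analytically), solved to ~1e-14 absolute in CT."""
    if ctox == 0.0:
        return 1.0 / (1.0 + kb * calb)
    lo, hi = 0.0, ctox

    def f(ct):
        return ct + kb * ct * calb / (1.0 + kb * ct) - ctox

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi) / ctox


# transient-resolving sampling schedule used by the recovery studies:
# 0.5 min steps over the first ~5 solid relaxation times, then coarser
RECOVERY_SCHEDULE = np.unique(
    np.concatenate(
        (np.arange(0.0, 15.0, 0.5), np.arange(15.0, 60.0, 2.0), np.arange(60.0, 721.0, 30.0))
    )
)


@pytest.fixture(scope="session")
def config_a():
    return hd.default_config_a()


@pytest.fixture(scope="session")
def config_b():
    return hd.default_config_b()


@pytest.fixture(scope="session")
def result_a(config_a):
    return hd.simulate_config_a(config_a)


@pytest.fixture(scope="session")
def result_b(config_b):
    return hd.simulate_config_b(config_b)
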