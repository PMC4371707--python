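import numpy as np
import pytest

from cbreach import config as cbconfig


@pytest.fixture(scope="session")
def cfg():
    return cbconfig.default_config()


@pytest.fixture(scope="session")
def geometry(cfg):
    return cbconfig.build_geometry(cfg)


@pytest.fixture(scope="session")
def targets():
    return cbconfig.standard_targets()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_reachable_targets(geometry, rng, n, anterior=True):
    """Random targets inside the reachable annulus (y > 0 workspace)."""
    lo, hi = abs(geometry.l_arm - geometry.l_farm), geometry.reach
    out = []
    while len(out) < n:
        t = rng.uniform([-0.65, 0.0, -0.65], [0.65, 0.65, 0.65])
        d = np.linalg.norm(t)
        if lo + 1e-3 < d < hi - 1e-3 and (not anterior or t[1] > 0.01):
            out.append(t)
    return np.array(out)
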