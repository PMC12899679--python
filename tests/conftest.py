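import numpy as np
import pytest

from pbdp.fixtures import (
    gen_polyol_chain,
    gen_pyranose_template,
    gen_water_cluster,
    gen_water_dimer,
)
from pbdp.params import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def water():
    return gen_water_cluster(1, seed=11)


@pytest.fixture(scope="session")
def water3():
    return gen_water_cluster(3, seed=7)


@pytest.fixture(scope="session")
def water_dimer():
    return gen_water_dimer()


@pytest.fixture(scope="session")
def glucose():
    return gen_pyranose_template("alpha")


@pytest.fixture(scope="session")
def glycol():
    """Ethylene-glycol-like two-carbon polyol."""
    return gen_polyol_chain(2)


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
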