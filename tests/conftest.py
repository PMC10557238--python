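import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import semdrive as sd

ALL_DESIGNS = [d.value for d in sd.Design]
ALL_FLAVORS = [f.value for f in sd.Flavor]


@pytest.fixture(scope="session")
def sem_release_config():
    return sd.preset_sem_release()


@pytest.fixture(scope="session")
def sem_release_build(sem_release_config):
    """Cubes, lifecycle model and equilibrium state of the canonical scenario."""
    cube_off, cube_on, model, state0, K = sd.build_scenario(sem_release_config)
    return {
        "config": sem_release_config,
        "cube_off": cube_off,
        "cube_on": cube_on,
        "model": model,
        "state0": state0,
        "K": K,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20230927)


def random_params(rng):
    """A random (DriveParams, SemParams) draw."""
    return (
        sd.DriveParams(p=rng.random(), q=rng.random(), rho=rng.random()),
        sd.SemParams(a=rng.random(), b=rng.random(), c=rng.random()),
    )
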