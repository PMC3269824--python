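import numpy as np
import pytest

from pubshape3d import fixtures as fx


@pytest.fixture(scope="session")
def embedded():
    """Session cache of embedded toy molecules (one conformer each)."""
    cache = {}

    def get(name, n_conformers=1, seed=0, sample=False):
        key = (name, n_conformers, seed, sample)
        if key not in cache:
            cache[key] = fx.embedded_model(
                name, n_conformers=n_conformers, seed=seed, sample=sample
            )
        return cache[key]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_clouds():
    """Eight mutually distinct rigid point-cloud conformers."""
    out = []
    for s in range(8):
        _rec, confs = fx.point_cloud_ensemble(
            n_atoms=7, n_conformers=1, seed=500 + s, jitter=0.0
        )
        out.append(confs[0])
    return out
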