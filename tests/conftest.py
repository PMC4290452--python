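import numpy as np
import pytest

from spindlemech.synthetic import PackingSpec, mmo_architecture, synthesize_traces


@pytest.fixture(scope="session")
def early_anaphase_spindle():
    """11-microtubule fully-overlapped MMO spindle (L_s = 2.5 μm), noiseless."""
    arch = mmo_architecture(27.1, 2.5, 2.5)
    pack = PackingSpec(seed=0)
    return arch, synthesize_traces(arch, pack)


@pytest.fixture(scope="session")
def mid_anaphase_spindle():
    """6-microtubule L_s = 6 μm spindle with distinct polar and midzone phases."""
    arch = mmo_architecture(27.1, 6.0, 2.5)
    pack = PackingSpec(positional_noise_sd=2.0, seed=2)
    return arch, synthesize_traces(arch, pack)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng):
    """Haar-random 3D rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
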