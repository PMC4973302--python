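import numpy as np
import pytest

from tunneldock.cli import run_synthetic_analysis
from tunneldock.synthetic import (
    LigandSpec,
    TunnelSpec,
    make_ligand_library,
    make_templates,
    make_tunnel_protein,
)


@pytest.fixture(scope="session")
def asym_run():
    """Full pipeline products on the default (pocketed) tunnel."""
    return run_synthetic_analysis(seed=7)


@pytest.fixture(scope="session")
def sym_run():
    """Full pipeline products on the symmetric null tunnel."""
    return run_synthetic_analysis(tunnel_spec=TunnelSpec.symmetric(), seed=7)


@pytest.fixture(scope="session")
def tunnel_system():
    """Default tunnel protein + portal definitions + generator metadata."""
    return make_tunnel_protein(TunnelSpec())


@pytest.fixture(scope="session")
def small_library():
    return make_ligand_library(LigandSpec(n_conformers=5, seed=3))


@pytest.fixture(scope="session")
def canonical_ligand():
    """Single jitter-free conformer."""
    return make_ligand_library(LigandSpec(n_conformers=1, jitter=0.0))[0]


def random_rigid(rng: np.random.Generator):
    """A uniformly random proper rotation and a bounded translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t
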