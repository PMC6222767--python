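import numpy as np
import pytest

from qmmm_embed import (HartreeFockBackend, MMCharges, SurrogateBackend,
                        builtin_solute)


@pytest.fixture(scope="session")
def rhf():
    """Shared RHF backend; integral caches persist across tests."""
    return HartreeFockBackend()


@pytest.fixture(scope="session")
def hydroxide():
    return builtin_solute("hydroxide")


@pytest.fixture(scope="session")
def water_qm():
    return builtin_solute("water")


@pytest.fixture(scope="session")
def hydroxide_gas(rhf, hydroxide):
    """Gas-phase converged density of the benchmark anion."""
    density, e_first, e_conv = rhf.converged_scf(hydroxide)
    return density, e_first, e_conv


@pytest.fixture(scope="session")
def anion_cloud_surrogate(hydroxide):
    """Cloud surrogate around the hydroxide sites: net -1, with dipole and
    higher moments, standing in for a polarized anion density."""
    cloud_xyz = np.array([
        [0.22, 0.10, -0.05], [-0.18, 0.14, 0.08], [0.02, -0.28, 0.15],
        [0.08, 0.03, 0.72], [-0.06, -0.04, 1.18],
    ])
    cloud_q = np.array([0.35, -0.65, -0.55, -0.35, 0.20])  # sums to -1
    return SurrogateBackend(hydroxide, cloud_coords=cloud_xyz, cloud_charges=cloud_q)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def random_mm(rng, n, rmin=3.0, rmax=20.0, qscale=0.8):
    """Random MM charges in a shell rmin..rmax Angstrom around the origin."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    r = rng.uniform(rmin, rmax, size=n)
    return MMCharges(u * r[:, None], rng.uniform(-qscale, qscale, size=n),
                     np.arange(n))
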