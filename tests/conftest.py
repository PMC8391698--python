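import numpy as np
import pytest

from bayesmech import StatePartition, build_gaussian_ness
from bayesmech.io import blanket_fixture_matrices
from bayesmech.soup import SoupConfig, simulate_soup


def random_spd(rng, dim, scale=1.0):
    """Random symmetric positive-definite matrix, well conditioned."""
    A = rng.standard_normal((dim, dim))
    return scale * (A @ A.T / dim + np.eye(dim))


def random_antisymmetric(rng, dim, scale=1.0):
    A = rng.standard_normal((dim, dim))
    return scale * (A - A.T) / 2.0


def random_blanket_system(rng, sizes=(2, 1, 1, 2)):
    """Random Gaussian system satisfying the sparse blanket form.

    ``sizes`` gives the (eta, s, a, mu) block sizes.  The precision has
    chain-structured couplings eta-s, s-a, a-mu only; the solenoidal
    matrix couples only within the permitted blocks.
    """
    ne, ns, na, nm = sizes
    dim = ne + ns + na + nm
    eta = list(range(ne))
    s = list(range(ne, ne + ns))
    a = list(range(ne + ns, ne + ns + na))
    mu = list(range(ne + ns + na, dim))
    H = np.eye(dim) * (2.0 + rng.random(dim))
    def couple(I, J):
        B = 0.3 * rng.standard_normal((len(I), len(J)))
        for bi, i in enumerate(I):
            for bj, j in enumerate(J):
                H[i, j] = H[j, i] = B[bi, bj]
    couple(eta, s)
    couple(s, a)
    couple(a, mu)
    Q = np.zeros((dim, dim))
    def solenoid(I, J):
        B = 0.4 * rng.standard_normal((len(I), len(J)))
        for bi, i in enumerate(I):
            for bj, j in enumerate(J):
                Q[i, j] = B[bi, bj]
                Q[j, i] = -B[bi, bj]
    solenoid(eta, eta)
    solenoid(eta, s)
    solenoid(s, s)
    solenoid(a, a)
    solenoid(a, mu)
    solenoid(mu, mu)
    Q = (Q - Q.T) / 2.0
    Gamma = np.diag(0.5 + rng.random(dim))
    part = StatePartition(eta=eta, s=s, a=a, mu=mu)
    return build_gaussian_ness(H, Q, Gamma), part


def random_markov_system(rng, sizes=(2, 1, 1, 2), coupling=0.3):
    """Random Gaussian system satisfying only the blanket condition.

    The precision has H[mu, eta] = 0 but every other block (including
    eta-a couplings) is generically nonzero, so the posterior over
    external states depends on the whole blanket.  Q = 0.
    """
    ne, ns, na, nm = sizes
    dim = ne + ns + na + nm
    eta = list(range(ne))
    mu = list(range(ne + ns + na, dim))
    H = np.diag(2.0 + rng.random(dim))
    for i in range(dim):
        for j in range(i + 1, dim):
            if (i in eta and j in mu) or (i in mu and j in eta):
                continue
            H[i, j] = H[j, i] = coupling * rng.standard_normal()
    # enforce positive definiteness by a diagonal shift if needed
    lo = np.linalg.eigvalsh(H)[0]
    if lo < 0.5:
        H += (0.5 - lo) * np.eye(dim)
    part = StatePartition(
        eta=eta,
        s=list(range(ne, ne + ns)),
        a=list(range(ne + ns, ne + ns + na)),
        mu=mu,
    )
    return build_gaussian_ness(H, np.zeros((dim, dim)), np.eye(dim)), part


@pytest.fixture(scope="session")
def fixture_system():
    H, Q, Gamma = blanket_fixture_matrices()
    return build_gaussian_ness(H, Q, Gamma)


@pytest.fixture(scope="session")
def fixture_partition():
    return StatePartition(eta=[0], s=[1], a=[2], mu=[3])


@pytest.fixture(scope="session")
def mini_soup_state():
    """One shared short-horizon soup run (expensive; session scoped)."""
    return simulate_soup(SoupConfig().mini(seed=1))
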