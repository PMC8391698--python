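"""Nonequilibrium steady-state systems via the Helmholtz decomposition.

A system is specified by a surprisal function ``I(x) = -ln p(x)`` (the
negative log of the prescribed steady-state density), an antisymmetric
solenoidal matrix ``Q`` and a diagonal positive-definite diffusion matrix
``Gamma``.  The drift is

    f(x) = (Q - Gamma) grad I(x)
         = Q grad I(x)          (solenoidal, divergence-free against p)
         - Gamma grad I(x)      (dissipative gradient descent on I)

and random fluctuations are Wiener increments with covariance
``2 Gamma dt``, the convention under which ``p`` is stationary.  ``Q`` and
``Gamma`` are treated as constant in ``x``.

For a Gaussian steady state with precision ``H`` the surprisal is quadratic,
the Jacobian ``J = (Q - Gamma) H`` is constant and the stationary covariance
``Sigma = H^{-1}`` satisfies the continuous Lyapunov identity
``J Sigma + Sigma J^T + 2 Gamma = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import linalg

__all__ = [
    "NESSSystem",
    "GaussianNESS",
    "Trajectory",
    "helmholtz_flow",
    "vector_potential",
    "build_gaussian_ness",
    "integrate",
]

#: default absolute tolerance for exact-algebra invariant checks
DEFAULT_TOL = 1e-8

#: per-coordinate divergence guard for trajectory integration
DIVERGENCE_BOUND = 1e6


def _as_matrix(M, dim: int, name: str) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape != (dim, dim):
        raise ValueError(f"{name} must be {dim}x{dim}, got {M.shape}")
    return M


def check_antisymmetric(Q: np.ndarray, tol: float = DEFAULT_TOL) -> None:
    """Raise ``ValueError`` if ``Q + Q^T`` exceeds ``tol`` in max-abs."""
    asym = np.max(np.abs(Q + Q.T)) if Q.size else 0.0
    if asym > tol:
        raise ValueError(
            f"solenoidal matrix is not antisymmetric: max|Q+Q^T| = {asym:.3e}"
        )


def check_spd(H: np.ndarray, name: str = "H") -> np.ndarray:
    """Validate symmetric positive-definiteness; return eigenvalues."""
    if np.max(np.abs(H - H.T)) > DEFAULT_TOL * max(1.0, np.max(np.abs(H))):
        raise ValueError(f"{name} is not symmetric")
    eigvals = linalg.eigvalsh(H)
    if eigvals[0] <= 0:
        raise ValueError(
            f"{name} is not positive definite: smallest eigenvalue {eigvals[0]:.3e}"
        )
    return eigvals


@dataclass
class NESSSystem:
    """A stochastic system with prescribed steady state.

    Parameters
    ----------
    dim
        Number of state variables.
    surprisal
        Callable ``x -> I(x)`` returning the scalar surprisal in nats.
    grad
        Callable ``x -> grad I(x)``.  If omitted, central finite
        differences of ``surprisal`` are used.
    Q
        Antisymmetric ``dim x dim`` solenoidal coupling matrix.
    Gamma
        Diagonal positive-definite ``dim x dim`` diffusion matrix; random
        fluctuation increments have covariance ``2 Gamma dt``.
    """

    dim: int
    surprisal: Callable[[np.ndarray], float]
    Q: np.ndarray
    Gamma: np.ndarray
    grad: Optional[Callable[[np.ndarray], np.ndarray]] = None
    hess: Optional[Callable[[np.ndarray], np.ndarray]] = None
    fd_step: float = 1e-6

    def __post_init__(self):
        self.Q = _as_matrix(self.Q, self.dim, "Q")
        self.Gamma = _as_matrix(self.Gamma, self.dim, "Gamma")
        check_antisymmetric(self.Q)
        off = self.Gamma - np.diag(np.diag(self.Gamma))
        if np.max(np.abs(off)) > DEFAULT_TOL:
            raise ValueError("Gamma must be diagonal (independent fluctuations)")
        if np.any(np.diag(self.Gamma) < 0):
            raise ValueError("Gamma must have nonnegative diagonal")

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = self._check_state(x)
        if self.grad is not None:
            g = np.asarray(self.grad(x), dtype=float)
        else:
            g = _fd_gradient(self.surprisal, x, self.fd_step)
        if not np.all(np.isfinite(g)):
            bad = np.flatnonzero(~np.isfinite(g))
            raise FloatingPointError(
                f"non-finite surprisal gradient at coordinates {bad.tolist()} (x={x})"
            )
        return g

    def hessian(self, x: np.ndarray) -> np.ndarray:
        x = self._check_state(x)
        if self.hess is not None:
            return np.asarray(self.hess(x), dtype=float)
        return _fd_hessian(self.surprisal, x, max(self.fd_step, 1e-5))

    def _check_state(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.shape != (self.dim,):
            raise ValueError(f"state must have length {self.dim}, got {x.shape}")
        return x


def _fd_gradient(f, x, h):
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _fd_hessian(f, x, h):
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


class GaussianNESS(NESSSystem):
    """NESS system with Gaussian steady state ``N(mean, H^{-1})``.

    The surprisal is the quadratic form
    ``I(x) = 1/2 (x-mean)^T H (x-mean) + 1/2 ln det(2 pi H^{-1})``
    (fully normalised so that evidence identities hold exactly), the
    Jacobian ``J = (Q - Gamma) H`` is constant and the stationary
    covariance is ``H^{-1}``.
    """

    def __init__(self, H, Q, Gamma, mean=None):
        H = np.atleast_2d(np.asarray(H, dtype=float))
        dim = H.shape[0]
        check_spd(H, "H")
        self.H = H
        self.mean = np.zeros(dim) if mean is None else np.asarray(mean, float).ravel()
        if self.mean.shape != (dim,):
            raise ValueError(f"mean must have length {dim}")
        sign, logdet = np.linalg.slogdet(H)
        self._log_norm = 0.5 * (dim * np.log(2 * np.pi) - logdet)
        super().__init__(
            dim=dim,
            surprisal=self._quadratic_surprisal,
            Q=Q,
            Gamma=Gamma,
            grad=self._quadratic_grad,
            hess=lambda x: self.H,
        )

    def _quadratic_surprisal(self, x):
        d = np.asarray(x, float).ravel() - self.mean
        return 0.5 * d @ self.H @ d + self._log_norm

    def _quadratic_grad(self, x):
        return self.H @ (np.asarray(x, float).ravel() - self.mean)

    @property
    def jacobian(self) -> np.ndarray:
        """Constant flow Jacobian ``(Q - Gamma) H``."""
        return (self.Q - self.Gamma) @ self.H

    @property
    def covariance(self) -> np.ndarray:
        """Stationary covariance ``H^{-1}``."""
        return linalg.inv(self.H)


@dataclass
class Trajectory:
    """A realised sample path of a NESS system."""

    times: np.ndarray
    states: np.ndarray
    seed: int
    dt: float
    integrator_id: str = "euler-maruyama"
    diverged: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.states = np.atleast_2d(np.asarray(self.states, float))
        if len(self.times) != self.states.shape[0]:
            raise ValueError("times and states length mismatch")

    def stationary_samples(self, burn_in_frac: float = 0.2) -> np.ndarray:
        """States after discarding the initial ``burn_in_frac`` transient."""
        start = int(np.floor(burn_in_frac * self.states.shape[0]))
        return self.states[start:]


def helmholtz_flow(system: NESSSystem, x, parts: bool = False):
    """Evaluate the drift ``f(x) = (Q - Gamma) grad I(x)``.

    With ``parts=True`` return ``(f, dissipative, solenoidal)`` where
    ``dissipative = -Gamma grad I`` and ``solenoidal = Q grad I``.
    """
    g = system.gradient(x)
    sol = system.Q @ g
    dis = -system.Gamma @ g
    f = sol + dis
    if parts:
        return f, dis, sol
    return f


def vector_potential(system: NESSSystem, x) -> np.ndarray:
    """Vector potential ``A(x)`` of the solenoidal flow in three dimensions.

    For ``dim == 3`` the solenoidal term can be written as a curl,
    ``Q grad I(x) = curl A(x)`` with ``A(x) = (-Q32, Q31, -Q21) I(x)``,
    exploiting the antisymmetry of ``Q``.
    """
    if system.dim != 3:
        raise ValueError("the vector-potential form requires dim == 3")
    x = np.asarray(x, float).ravel()
    Q = system.Q
    axis = np.array([-Q[2, 1], Q[2, 0], -Q[1, 0]])
    return axis * system.surprisal(x)


def build_gaussian_ness(H, Q, Gamma, mean=None) -> GaussianNESS:
    """Construct a Gaussian NESS system, validating all invariants.

    Raises ``ValueError`` naming the offending eigenvalue if ``H`` is not
    symmetric positive-definite, or the max-abs asymmetry if ``Q`` is not
    antisymmetric.
    """
    return GaussianNESS(H=H, Q=Q, Gamma=Gamma, mean=mean)


def integrate(
    system: NESSSystem,
    x0,
    dt: float,
    n_steps: int,
    seed: int,
    rng: Optional[np.random.Generator] = None,
    divergence_bound: float = DIVERGENCE_BOUND,
    deterministic: bool = False,
) -> Trajectory:
    """Euler--Maruyama integration of ``dx = f(x) dt + dw``.

    Gaussian increments have covariance ``2 Gamma dt``.  The trajectory is
    truncated with a warning if any coordinate exceeds
    ``divergence_bound``.  Identical ``seed`` yields bit-identical output.
    ``deterministic=True`` suppresses the fluctuations (zero-noise limit,
    for testing the drift in isolation).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    x0 = np.asarray(x0, float).ravel()
    if x0.shape != (system.dim,):
        raise ValueError(f"x0 must have length {system.dim}")
    if rng is None:
        rng = np.random.default_rng(seed)
    noise_sd = (
        np.zeros(system.dim)
        if deterministic
        else np.sqrt(2.0 * np.diag(system.Gamma) * dt)
    )

    states = np.empty((n_steps + 1, system.dim))
    states[0] = x0
    x = x0.copy()
    diverged = False
    t_stop = n_steps
    for k in range(n_steps):
        f = helmholtz_flow(system, x)
        x = x + f * dt + noise_sd * rng.standard_normal(system.dim)
        states[k + 1] = x
        if np.any(np.abs(x) > divergence_bound):
            warnings.warn(
                f"trajectory diverged at step {k + 1} "
                f"(|state| > {divergence_bound:g}); truncating",
                RuntimeWarning,
                stacklevel=2,
            )
            diverged = True
            t_stop = k + 1
            break
    states = states[: t_stop + 1]
    times = dt * np.arange(t_stop + 1)
    return Trajectory(
        times=times, states=states, seed=seed, dt=dt, diverged=diverged
    )
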