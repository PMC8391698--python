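"""The free-energy lemma for Gaussian steady states.

For a system with a Markov blanket, every blanket value ``b`` induces a
conditional expectation of the internal states, ``mu(b) = E[mu | b]`` —
a point on the *internal statistical manifold* — and an exact posterior
``p(eta | b)`` over external states.  A variational density ``q(eta)``,
parameterised by the internal-manifold coordinate, defines the
variational free energy of the particular states ``pi = (mu, b)``:

    F(pi) = E_q[ I(eta, pi) ] - H[q]                 (energy - entropy)
          = I(pi) + KL[ q || p(eta|b) ]              (surprisal + bound)
          = E_q[ I(pi|eta) ] + KL[ q || p(eta) ]     (inaccuracy + complexity)
          >= I(pi)

with ``I`` the surprisal of the joint steady-state density.  The bound
(KL between variational density and posterior) is non-negative and
collapses to zero when ``q`` is the exact posterior; whenever the bound
is constant over the manifold, the gradients of ``F`` and of the
surprisal coincide, so the autonomous gradient flow is the same whether
it is read as flowing on surprisal or on free energy.

All densities here are Gaussian; the identities above are evaluated in
closed form.  The surprisal-plus-bound identity uses ``p(eta|b)`` and is
exact precisely when the blanket condition ``H[mu, eta] = 0`` holds
(then ``p(eta | pi) = p(eta | b)``); the other two forms hold for any
Gaussian joint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg

from bayesmech.nessflow import GaussianNESS, check_spd
from bayesmech.blanket import StatePartition

__all__ = [
    "GaussianVariationalDensity",
    "FreeEnergyDecomposition",
    "conditional_expectation",
    "exact_posterior",
    "exact_posterior_family",
    "free_energy",
    "evidence_bound_profile",
    "gradient_equivalence",
    "desired_steady_state_flow",
]


def _idx(seq: Sequence[int]) -> list:
    return list(seq)


def _marginal(system: GaussianNESS, idx: Sequence[int]):
    Sigma = system.covariance
    idx = _idx(idx)
    return system.mean[idx], Sigma[np.ix_(idx, idx)]


def _conditional(system: GaussianNESS, target: Sequence[int], given: Sequence[int], given_value):
    """Gaussian conditional mean and covariance of target given observed."""
    Sigma = system.covariance
    t, g = _idx(target), _idx(given)
    given_value = np.asarray(given_value, float).ravel()
    if given_value.shape != (len(g),):
        raise ValueError(f"conditioning value must have length {len(g)}")
    S_tt = Sigma[np.ix_(t, t)]
    S_tg = Sigma[np.ix_(t, g)]
    S_gg = Sigma[np.ix_(g, g)]
    try:
        solve = linalg.solve(S_gg, (given_value - system.mean[g]), assume_a="pos")
        gain = linalg.solve(S_gg, S_tg.T, assume_a="pos").T
    except linalg.LinAlgError as exc:
        raise ValueError("singular conditioning covariance") from exc
    mean = system.mean[t] + S_tg @ solve
    cov = S_tt - gain @ S_tg.T
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def gaussian_kl(m0, S0, m1, S1) -> float:
    """KL divergence KL[N(m0,S0) || N(m1,S1)] in nats (closed form)."""
    m0, m1 = np.asarray(m0, float).ravel(), np.asarray(m1, float).ravel()
    S0, S1 = np.atleast_2d(S0), np.atleast_2d(S1)
    k = m0.size
    S1_inv = linalg.inv(S1)
    d = m1 - m0
    _, ld1 = np.linalg.slogdet(S1)
    _, ld0 = np.linalg.slogdet(S0)
    return 0.5 * (np.trace(S1_inv @ S0) + d @ S1_inv @ d - k + ld1 - ld0)


def gaussian_neg_logpdf(x, m, S) -> float:
    """Surprisal of x under N(m, S)."""
    x, m = np.asarray(x, float).ravel(), np.asarray(m, float).ravel()
    S = np.atleast_2d(S)
    k = x.size
    d = x - m
    _, ld = np.linalg.slogdet(S)
    return 0.5 * (d @ linalg.solve(S, d, assume_a="pos") + ld + k * np.log(2 * np.pi))


@dataclass
class GaussianVariationalDensity:
    """Gaussian variational family over external states.

    ``params_of(coord, b_value) -> (mean, cov)`` maps the internal-manifold
    coordinate (the conditional expectation of the internal states given
    the blanket) to the parameters of a Gaussian over the external
    states.  The blanket value is supplied alongside the coordinate for
    families defined through the blanket (e.g. the exact posterior);
    honest parameterisations use the coordinate only.

    ``exact=True`` marks the family as the exact posterior, enabling
    closed-form shortcuts (zero bound, surprisal gradients).
    """

    params_of: Callable[[np.ndarray, np.ndarray], Tuple[np.ndarray, np.ndarray]]
    family: str = "gaussian"
    exact: bool = False

    def params(self, coord, b_value):
        m, S = self.params_of(np.asarray(coord, float), np.asarray(b_value, float))
        m = np.asarray(m, float).ravel()
        S = np.atleast_2d(np.asarray(S, float))
        check_spd(S, "variational covariance")
        return m, S

    @classmethod
    def fixed(cls, mean, cov) -> "GaussianVariationalDensity":
        """A blanket-independent density with constant parameters."""
        return cls(params_of=lambda coord, b: (mean, cov))


@dataclass
class FreeEnergyDecomposition:
    """All terms of the variational free energy, in nats."""

    energy: float
    entropy: float
    surprisal: float
    bound: float
    inaccuracy: float
    complexity: float
    F: float

    def identity_defects(self) -> Dict[str, float]:
        """Absolute defects of the three equivalent expressions for F."""
        return {
            "energy_entropy": abs(self.F - (self.energy - self.entropy)),
            "surprisal_bound": abs(self.F - (self.surprisal + self.bound)),
            "inaccuracy_complexity": abs(self.F - (self.inaccuracy + self.complexity)),
        }


def conditional_expectation(system: GaussianNESS, part: StatePartition, b_value) -> np.ndarray:
    """Conditional expectation of internal states given the blanket, E[mu|b].

    This is the internal-manifold coordinate: the point on the internal
    statistical manifold associated with blanket value ``b_value``.
    Linear in ``b_value`` for Gaussian systems.
    """
    mean, _ = _conditional(system, part.mu, part.b, b_value)
    return mean


def exact_posterior(system: GaussianNESS, part: StatePartition, b_value):
    """Exact Gaussian posterior p(eta | b): returns (mean, cov)."""
    return _conditional(system, part.eta, part.b, b_value)


def exact_posterior_family(system: GaussianNESS, part: StatePartition) -> GaussianVariationalDensity:
    """The exact posterior as a variational family (zero evidence bound)."""

    def params(coord, b_value):
        return exact_posterior(system, part, b_value)

    return GaussianVariationalDensity(params_of=params, exact=True)


def _split_pi(part: StatePartition, pi_value):
    """Split a particular-state vector (ordered by sorted pi indices)."""
    pi_value = np.asarray(pi_value, float).ravel()
    pi = list(part.pi)
    if pi_value.shape != (len(pi),):
        raise ValueError(f"pi_value must have length {len(pi)}")
    pos = {g: k for k, g in enumerate(pi)}
    b_value = pi_value[[pos[i] for i in part.b]]
    mu_value = pi_value[[pos[i] for i in part.mu]]
    return pi_value, b_value, mu_value, pos


def free_energy(
    system: GaussianNESS,
    part: StatePartition,
    pi_value,
    q: GaussianVariationalDensity,
    heuristic_raw_internal: bool = False,
) -> FreeEnergyDecomposition:
    """Evaluate the variational free energy and all its decompositions.

    ``pi_value`` holds the particular states in the order of the sorted
    ``pi`` index set.  The variational density is evaluated at the
    internal-manifold coordinate ``E[mu|b]`` implied by the blanket part
    of ``pi_value`` (with ``heuristic_raw_internal=True`` the raw
    internal values are used instead — a heuristic the lemma does not
    license, provided for comparison only).
    """
    pi_value, b_value, mu_value, pos = _split_pi(part, pi_value)
    coord = mu_value if heuristic_raw_internal else conditional_expectation(system, part, b_value)
    mq, Sq = q.params(coord, b_value)
    eta = list(part.eta)
    if mq.shape != (len(eta),):
        raise ValueError("variational mean has wrong dimension for external states")

    H = system.H
    mean = system.mean
    # assemble the expectation point: external coords at the variational
    # mean, particular coords at pi_value
    xbar = np.array(mean, float)
    for k, i in enumerate(eta):
        xbar[i] = mq[k]
    for i, k in pos.items():
        xbar[i] = pi_value[k]

    # energy: E_q[I(x)] = I(xbar) + 1/2 tr(H_ee Sq)
    energy = system.surprisal(xbar) + 0.5 * np.trace(H[np.ix_(eta, eta)] @ Sq)
    # entropy of q
    _, ldq = np.linalg.slogdet(Sq)
    entropy = 0.5 * (len(eta) * (1.0 + np.log(2 * np.pi)) + ldq)
    # surprisal of particular states (marginal)
    m_pi, S_pi = _marginal(system, part.pi)
    surprisal = gaussian_neg_logpdf(pi_value, m_pi, S_pi)
    # evidence bound: KL between q and exact posterior given the blanket
    post_m, post_S = exact_posterior(system, part, b_value)
    bound = gaussian_kl(mq, Sq, post_m, post_S)
    # inaccuracy: E_q[-ln p(pi | eta)]; p(pi|eta) is Gaussian with mean
    # linear in eta, so the expectation has the quadratic closed form
    Sigma = system.covariance
    pi_idx = list(part.pi)
    S_pp = Sigma[np.ix_(pi_idx, pi_idx)]
    S_pe = Sigma[np.ix_(pi_idx, eta)]
    S_ee = Sigma[np.ix_(eta, eta)]
    A = S_pe @ linalg.inv(S_ee)
    cond_cov = S_pp - A @ S_pe.T
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    cond_mean_at_mq = mean[pi_idx] + A @ (mq - mean[eta])
    P = linalg.inv(cond_cov)
    d = pi_value - cond_mean_at_mq
    _, ld_c = np.linalg.slogdet(cond_cov)
    inaccuracy = 0.5 * (
        d @ P @ d
        + np.trace(A.T @ P @ A @ Sq)
        + ld_c
        + len(pi_idx) * np.log(2 * np.pi)
    )
    # complexity: KL between q and the marginal over external states
    m_eta, S_eta = _marginal(system, part.eta)
    complexity = gaussian_kl(mq, Sq, m_eta, S_eta)

    F = energy - entropy
    return FreeEnergyDecomposition(
        energy=float(energy),
        entropy=float(entropy),
        surprisal=float(surprisal),
        bound=float(bound),
        inaccuracy=float(inaccuracy),
        complexity=float(complexity),
        F=float(F),
    )


def evidence_bound_profile(
    system: GaussianNESS,
    part: StatePartition,
    q: GaussianVariationalDensity,
    b_grid,
) -> Dict[str, object]:
    """Evidence bound c(b) = KL[q || p(eta|b)] over a grid of blanket values.

    Returns the per-point values together with max, min, and the
    constancy defect max - min (the quantity that must be small for the
    free-energy and surprisal gradient flows to coincide).
    """
    b_grid = np.atleast_2d(np.asarray(b_grid, float))
    if b_grid.shape[1] != len(part.b):
        raise ValueError(f"grid rows must have length {len(part.b)}")
    values = np.empty(b_grid.shape[0])
    for k, b_value in enumerate(b_grid):
        coord = conditional_expectation(system, part, b_value)
        mq, Sq = q.params(coord, b_value)
        pm, pS = exact_posterior(system, part, b_value)
        values[k] = gaussian_kl(mq, Sq, pm, pS)
    return {
        "values": values,
        "max": float(values.max()),
        "min": float(values.min()),
        "constancy_defect": float(values.max() - values.min()),
    }


def _alpha_positions_in_pi(part: StatePartition):
    pi = list(part.pi)
    pos = {g: k for k, g in enumerate(pi)}
    return [pos[i] for i in part.alpha]


def surprisal_gradient_alpha(system: GaussianNESS, part: StatePartition, pi_value) -> np.ndarray:
    """Closed-form gradient of the particular-state surprisal over the
    autonomous coordinates, rows of Sigma_pipi^{-1} (pi - m_pi)."""
    pi_value = np.asarray(pi_value, float).ravel()
    m_pi, S_pi = _marginal(system, part.pi)
    g = linalg.solve(S_pi, pi_value - m_pi, assume_a="pos")
    return g[_alpha_positions_in_pi(part)]


def gradient_equivalence(
    system: GaussianNESS,
    part: StatePartition,
    q: GaussianVariationalDensity,
    pi_value,
    fd_step: float = 1e-5,
) -> Dict[str, np.ndarray]:
    """Compare autonomous gradients of surprisal and free energy.

    Returns closed-form ``grad_surprisal``, central-finite-difference
    ``grad_F``, their difference ``grad_bound`` (the gradient of the
    evidence bound), and a direct finite-difference gradient of the
    bound as a cross-check.  When the bound is constant over the
    manifold the difference vanishes and the two gradient flows are
    identical.
    """
    if fd_step <= 0:
        raise ValueError("fd_step must be positive")
    pi_value = np.asarray(pi_value, float).ravel()
    alpha_pos = _alpha_positions_in_pi(part)
    grad_surprisal = surprisal_gradient_alpha(system, part, pi_value)

    def F_at(p):
        return free_energy(system, part, p, q).F

    def c_at(p):
        return free_energy(system, part, p, q).bound

    grad_F = np.empty(len(alpha_pos))
    grad_c_fd = np.empty(len(alpha_pos))
    for k, j in enumerate(alpha_pos):
        h = fd_step * max(1.0, abs(pi_value[j]))
        e = np.zeros_like(pi_value)
        e[j] = h
        grad_F[k] = (F_at(pi_value + e) - F_at(pi_value - e)) / (2 * h)
        grad_c_fd[k] = (c_at(pi_value + e) - c_at(pi_value - e)) / (2 * h)
    return {
        "grad_surprisal": grad_surprisal,
        "grad_F": grad_F,
        "grad_bound": grad_F - grad_surprisal,
        "grad_bound_fd": grad_c_fd,
        "max_difference": float(np.max(np.abs(grad_F - grad_surprisal))),
    }


def desired_steady_state_flow(
    system: GaussianNESS,
    part: StatePartition,
    pi_value,
    q: GaussianVariationalDensity,
    Q_alpha: Optional[np.ndarray] = None,
    Gamma_alpha: Optional[np.ndarray] = None,
    fd_step: float = 1e-5,
) -> np.ndarray:
    """Autonomous flow engineered from a generative model.

    Returns ``f_alpha = (Q_aa - Gamma_aa) grad_alpha F(mu, b)``: a
    gradient flow on variational free energy under the supplied
    generative (desired steady-state) model.  Integrating this flow with
    matched noise drives the particular states toward the generative
    model's marginal.  With the exact-posterior family, F reduces to the
    particular-state surprisal and the flow to the surprisal gradient
    flow (closed form).
    """
    n_alpha = len(part.alpha)
    alpha_idx = list(part.alpha)
    if Q_alpha is None:
        Q_alpha = np.zeros((n_alpha, n_alpha))
    if Gamma_alpha is None:
        Gamma_alpha = system.Gamma[np.ix_(alpha_idx, alpha_idx)]
    Q_alpha = np.asarray(Q_alpha, float)
    Gamma_alpha = np.asarray(Gamma_alpha, float)

    if q.exact:
        grad = surprisal_gradient_alpha(system, part, pi_value)
    else:
        rec = gradient_equivalence(system, part, q, pi_value, fd_step=fd_step)
        grad = rec["grad_F"]
    return (Q_alpha - Gamma_alpha) @ grad


def integrate_desired_flow(
    system: GaussianNESS,
    part: StatePartition,
    q: GaussianVariationalDensity,
    x0,
    dt: float,
    n_steps: int,
    seed: int,
    Q_alpha: Optional[np.ndarray] = None,
    Gamma_alpha: Optional[np.ndarray] = None,
):
    """Euler--Maruyama integration of the engineered particular-state flow.

    Requires the sensory set to be empty (alpha = pi), so that the
    engineered autonomous flow closes over the particular states.
    Noise increments have covariance ``2 Gamma_alpha dt``.
    """
    if part.s:
        raise ValueError("engineered-flow integration requires an empty sensory set")
    alpha_idx = list(part.alpha)
    n_alpha = len(alpha_idx)
    if Gamma_alpha is None:
        Gamma_alpha = system.Gamma[np.ix_(alpha_idx, alpha_idx)]
    Gamma_alpha = np.asarray(Gamma_alpha, float)
    rng = np.random.default_rng(seed)
    noise_sd = np.sqrt(2.0 * np.diag(Gamma_alpha) * dt)
    x = np.asarray(x0, float).ravel().copy()
    out = np.empty((n_steps + 1, n_alpha))
    out[0] = x
    for k in range(n_steps):
        f = desired_steady_state_flow(
            system, part, x, q, Q_alpha=Q_alpha, Gamma_alpha=Gamma_alpha
        )
        x = x + f * dt + noise_sd * rng.standard_normal(n_alpha)
        out[k + 1] = x
    return out
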