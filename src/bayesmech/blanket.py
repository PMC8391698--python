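"""Markov blanket partitions under sparse coupling.

A state vector is partitioned into external (eta), sensory (s), active (a)
and internal (mu) states.  The blanket is b = s u a; autonomous states are
alpha = a u mu; particular states are pi = mu u b.  For a Gaussian steady
state with precision (Hessian) H and constant solenoidal matrix Q, two
distinct conditions interact:

* the *flow constraint* (condition 1): autonomous states are uncoupled
  from external states — the Jacobian blocks J[mu, eta] and J[a, eta] of
  J = (Q - Gamma) H vanish;
* the *blanket condition* (condition 2): internal and external states are
  conditionally independent given the blanket — the Hessian block
  H[mu, eta] vanishes.

Neither implies the other in general.  Both hold simultaneously under a
sparse functional form in which the Hessian blocks H[eta,a], H[eta,mu],
H[s,mu] vanish and the solenoidal blocks Q[eta,a], Q[eta,mu], Q[s,a],
Q[s,mu] vanish — i.e. solenoidal coupling between autonomous and
non-autonomous states is precluded.  Under that structure the implied
Jacobian zeros are J[eta,mu], J[s,mu], J[a,eta], J[mu,eta], via

    J[eta,mu] = Q[eta,a] H[a,mu]   + Q[eta,mu] H[mu,mu]
    J[s,mu]   = Q[s,a]   H[a,mu]   + Q[s,mu]   H[mu,mu]
    J[a,eta]  = -Q[s,a]^T H[eta,s]^T - Q[eta,a]^T  H[eta,eta]
    J[mu,eta] = -Q[s,mu]^T H[eta,s]^T - Q[eta,mu]^T H[eta,eta]

and the flow of autonomous states is a function of particular states only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg

from bayesmech.nessflow import GaussianNESS, helmholtz_flow

__all__ = [
    "StatePartition",
    "BlanketReport",
    "check_conditional_independence",
    "check_flow_constraint",
    "check_sparse_form",
    "autonomous_flow",
    "find_admissible_partitions",
]

DEFAULT_TOL = 1e-8


@dataclass(frozen=True)
class StatePartition:
    """Index sets for a 4-way partition of state coordinates.

    ``eta`` external, ``s`` sensory, ``a`` active, ``mu`` internal.  The
    sets must be pairwise disjoint and cover ``0..dim-1``; ``eta`` and
    ``mu`` must be nonempty, and the blanket ``b = s u a`` must be
    nonempty (either of ``s`` or ``a`` alone may be empty).
    """

    eta: Tuple[int, ...]
    s: Tuple[int, ...]
    a: Tuple[int, ...]
    mu: Tuple[int, ...]

    def __init__(self, eta, s, a, mu):
        object.__setattr__(self, "eta", tuple(sorted(int(i) for i in eta)))
        object.__setattr__(self, "s", tuple(sorted(int(i) for i in s)))
        object.__setattr__(self, "a", tuple(sorted(int(i) for i in a)))
        object.__setattr__(self, "mu", tuple(sorted(int(i) for i in mu)))
        self._validate()

    def _validate(self):
        groups = [self.eta, self.s, self.a, self.mu]
        flat = [i for g in groups for i in g]
        if len(set(flat)) != len(flat):
            overlap = sorted({i for i in flat if flat.count(i) > 1})
            raise ValueError(f"partition index sets overlap at {overlap}")
        if sorted(flat) != list(range(len(flat))):
            raise ValueError("partition must cover 0..dim-1 exactly")
        if not self.eta:
            raise ValueError("external set must be nonempty")
        if not self.mu:
            raise ValueError("internal set must be nonempty")
        if not self.b:
            raise ValueError("blanket (sensory u active) must be nonempty")

    @property
    def dim(self) -> int:
        return len(self.eta) + len(self.s) + len(self.a) + len(self.mu)

    @property
    def b(self) -> Tuple[int, ...]:
        """Blanket states: sensory u active."""
        return tuple(sorted(self.s + self.a))

    @property
    def alpha(self) -> Tuple[int, ...]:
        """Autonomous states: active u internal."""
        return tuple(sorted(self.a + self.mu))

    @property
    def pi(self) -> Tuple[int, ...]:
        """Particular states: internal u blanket."""
        return tuple(sorted(self.mu + self.b))

    @classmethod
    def from_string(cls, text: str) -> "StatePartition":
        """Parse ``"eta=0,1;s=2;a=3;mu=4,5"`` (empty sets allowed)."""
        sets = {"eta": [], "s": [], "a": [], "mu": []}
        for chunk in text.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            key, _, vals = chunk.partition("=")
            key = key.strip()
            if key not in sets:
                raise ValueError(f"unknown partition label {key!r}")
            if vals.strip():
                sets[key] = [int(v) for v in vals.split(",") if v.strip()]
        return cls(**sets)

    def to_string(self) -> str:
        return ";".join(
            f"{k}={','.join(map(str, v))}"
            for k, v in (("eta", self.eta), ("s", self.s), ("a", self.a), ("mu", self.mu))
        )


@dataclass
class BlanketReport:
    """Quantified result of the blanket / flow-constraint checks."""

    hessian_blocks: Dict[str, float]
    q_blocks: Dict[str, float]
    jacobian_blocks: Dict[str, float]
    tol: float
    passes: Dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "hessian_blocks": self.hessian_blocks,
            "q_blocks": self.q_blocks,
            "jacobian_blocks": self.jacobian_blocks,
            "tol": self.tol,
            "passes": self.passes,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @property
    def all_pass(self) -> bool:
        return all(self.passes.values())


def _block(M: np.ndarray, rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
    if not rows or not cols:
        return np.zeros((0, 0))
    return M[np.ix_(rows, cols)]


def _maxabs(M: np.ndarray) -> float:
    return float(np.max(np.abs(M))) if M.size else 0.0


def check_conditional_independence(
    H: np.ndarray, part: StatePartition, tol: float = DEFAULT_TOL
):
    """Test the blanket condition H[mu, eta] = 0.

    For a Gaussian density with precision ``H`` this is exactly the
    conditional independence of internal and external states given the
    blanket.  Returns ``(passed, diagnostics)`` where diagnostics names
    the largest violating entry.
    """
    H = np.asarray(H, float)
    if H.shape != (part.dim, part.dim):
        raise ValueError(f"H must be {part.dim}x{part.dim}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    B = _block(H, part.mu, part.eta)
    m = _maxabs(B)
    passed = m < tol
    diag = {"max_abs": m, "tol": tol}
    if not passed:
        i, j = np.unravel_index(np.argmax(np.abs(B)), B.shape)
        diag["worst_entry"] = (part.mu[i], part.eta[j])
        diag["worst_value"] = float(B[i, j])
    return passed, diag


def check_flow_constraint(
    system: GaussianNESS, part: StatePartition, tol: float = DEFAULT_TOL
):
    """Test the flow constraint: autonomous states uncoupled from external.

    True iff the constant-Jacobian blocks J[mu, eta] and J[a, eta] of
    ``J = (Q - Gamma) H`` both vanish to ``tol``.
    """
    J = system.jacobian
    m_mu = _maxabs(_block(J, part.mu, part.eta))
    m_a = _maxabs(_block(J, part.a, part.eta))
    passed = (m_mu < tol) and (m_a < tol)
    return passed, {"max_abs_J_mu_eta": m_mu, "max_abs_J_a_eta": m_a, "tol": tol}


#: Hessian blocks required to vanish for the sparse functional form
_H_ZERO_BLOCKS = [("eta", "a"), ("eta", "mu"), ("s", "mu")]
#: solenoidal blocks precluded (no autonomous <-> non-autonomous coupling)
_Q_ZERO_BLOCKS = [("eta", "a"), ("eta", "mu"), ("s", "a"), ("s", "mu")]
#: Jacobian zero blocks implied by the sparse form
_J_ZERO_BLOCKS = [("eta", "mu"), ("s", "mu"), ("a", "eta"), ("mu", "eta")]


def check_sparse_form(
    H: np.ndarray,
    Q: np.ndarray,
    part: StatePartition,
    tol: float = DEFAULT_TOL,
    Gamma: Optional[np.ndarray] = None,
) -> BlanketReport:
    """Full report on the sparse blanket-compatible functional form.

    Checks the mandated Hessian zero blocks, the precluded solenoidal
    blocks, and the implied Jacobian zero blocks of J = (Q - Gamma) H
    (Gamma defaults to the identity; diagonal Gamma never enters
    off-diagonal partition blocks, so the Jacobian zeros are
    Gamma-independent).  Additionally flags the special case of no
    solenoidal coupling between any two different kinds of states
    (``condition3``).  Violations are reported, never raised.
    """
    H = np.asarray(H, float)
    Q = np.asarray(Q, float)
    dim = part.dim
    if H.shape != (dim, dim) or Q.shape != (dim, dim):
        raise ValueError(f"H and Q must be {dim}x{dim}")
    if Gamma is None:
        Gamma = np.eye(dim)
    sets = {"eta": part.eta, "s": part.s, "a": part.a, "mu": part.mu}

    h_blocks = {
        f"H_{r}_{c}": _maxabs(_block(H, sets[r], sets[c])) for r, c in _H_ZERO_BLOCKS
    }
    q_blocks = {
        f"Q_{r}_{c}": _maxabs(_block(Q, sets[r], sets[c])) for r, c in _Q_ZERO_BLOCKS
    }
    J = (Q - Gamma) @ H
    j_blocks = {
        f"J_{r}_{c}": _maxabs(_block(J, sets[r], sets[c])) for r, c in _J_ZERO_BLOCKS
    }

    cond2 = h_blocks["H_eta_mu"] < tol
    cond1 = j_blocks["J_mu_eta"] < tol and j_blocks["J_a_eta"] < tol
    sparse7 = all(v < tol for v in h_blocks.values())
    sparse8 = all(v < tol for v in q_blocks.values())
    # condition 3: no solenoidal coupling between any two different kinds
    off_kind = 0.0
    labels = list(sets)
    for i, r in enumerate(labels):
        for c in labels[i + 1:]:
            off_kind = max(off_kind, _maxabs(_block(Q, sets[r], sets[c])))
    passes = {
        "condition1_flow": cond1,
        "condition2_blanket": cond2,
        "sparse_form_eq_hessian": sparse7,
        "sparse_form_eq_solenoidal": sparse8,
        "sparse_form": sparse7 and sparse8 and all(v < tol for v in j_blocks.values()),
        "condition3_block_diagonal_Q": off_kind < tol,
    }
    return BlanketReport(
        hessian_blocks=h_blocks,
        q_blocks=q_blocks,
        jacobian_blocks=j_blocks,
        tol=tol,
        passes=passes,
    )


def autonomous_flow(
    system: GaussianNESS,
    part: StatePartition,
    x,
    tol: float = DEFAULT_TOL,
) -> Dict[str, np.ndarray]:
    """Block flow over (eta, s, alpha) for a sparse-form system.

    Requires the sparse functional form to hold at ``tol``; the alpha
    component is computed from particular states only and equals the
    corresponding rows of the full drift exactly.  Returns a dict with
    keys ``"eta"``, ``"s"``, ``"alpha"``.
    """
    report = check_sparse_form(system.H, system.Q, part, tol=tol, Gamma=system.Gamma)
    if not report.passes["sparse_form"]:
        failing = [
            k
            for d in (report.hessian_blocks, report.q_blocks, report.jacobian_blocks)
            for k, v in d.items()
            if v >= tol
        ]
        raise ValueError(
            f"system does not satisfy the sparse blanket form at tol={tol}: "
            f"nonzero blocks {failing}"
        )
    x = np.asarray(x, float).ravel()
    if x.shape != (system.dim,):
        raise ValueError(f"state must have length {system.dim}")

    Q, Gam, H, mean = system.Q, system.Gamma, system.H, system.mean
    eta, s, alpha, pi = part.eta, list(part.s), list(part.alpha), list(part.pi)
    QG = Q - Gam
    full_grad = H @ (x - mean)

    # alpha flow from particular states only: under the sparse form
    # Q[alpha, s] = 0 and H[alpha, eta] = 0, so
    # f_alpha = (Q - Gamma)[alpha, alpha] H[alpha, pi] (x_pi - mean_pi)
    grad_alpha = H[np.ix_(alpha, pi)] @ (x[pi] - mean[pi])
    f_alpha = QG[np.ix_(alpha, alpha)] @ grad_alpha

    f_eta = QG[np.ix_(list(eta), range(system.dim))] @ full_grad
    f_s = QG[np.ix_(s, range(system.dim))] @ full_grad if s else np.zeros(0)
    return {"eta": f_eta, "s": f_s, "alpha": f_alpha}


def _pairwise_constraints():
    """Forbidden unordered label pairs for H and Q couplings."""
    h_forbidden = {frozenset(p) for p in _H_ZERO_BLOCKS}
    q_forbidden = {frozenset(p) for p in _Q_ZERO_BLOCKS}
    return h_forbidden, q_forbidden


def find_admissible_partitions(
    H: np.ndarray,
    Q: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_dim: int = 12,
) -> List[Tuple[StatePartition, BlanketReport]]:
    """Exhaustively enumerate partitions satisfying the sparse form.

    Recursive search over the 4^dim labelings with pairwise-constraint
    pruning: assigning state ``i`` a label is abandoned as soon as it
    couples (via H or Q above ``tol``) to an already-labeled state in a
    forbidden pair.  Results are deduplicated and returned in a
    deterministic order.  ``dim > max_dim`` raises (use a heuristic
    screen first for larger systems).
    """
    H = np.asarray(H, float)
    Q = np.asarray(Q, float)
    dim = H.shape[0]
    if dim > max_dim:
        raise ValueError(
            f"exhaustive search limited to dim <= {max_dim}; got {dim}"
        )
    h_forbidden, q_forbidden = _pairwise_constraints()
    labels = ("eta", "s", "a", "mu")
    hc = np.abs(H) > tol
    qc = np.abs(Q) > tol

    results = []
    assign = [None] * dim

    def compatible(i, lab):
        for j in range(i):
            pair = frozenset((lab, assign[j]))
            if len(pair) == 1:
                continue
            if hc[i, j] and pair in h_forbidden:
                return False
            if qc[i, j] and pair in q_forbidden:
                return False
        return True

    def recurse(i):
        if i == dim:
            counts = {lab: assign.count(lab) for lab in labels}
            if counts["eta"] == 0 or counts["mu"] == 0:
                return
            if counts["s"] + counts["a"] == 0:
                return
            part = StatePartition(
                eta=[k for k in range(dim) if assign[k] == "eta"],
                s=[k for k in range(dim) if assign[k] == "s"],
                a=[k for k in range(dim) if assign[k] == "a"],
                mu=[k for k in range(dim) if assign[k] == "mu"],
            )
            report = check_sparse_form(H, Q, part, tol=tol)
            if report.passes["sparse_form"]:
                results.append((part, report))
            return
        for lab in labels:
            if compatible(i, lab):
                assign[i] = lab
                recurse(i + 1)
                assign[i] = None

    recurse(0)
    seen = set()
    unique = []
    for part, rep in sorted(results, key=lambda pr: pr[0].to_string()):
        key = part.to_string()
        if key not in seen:
            seen.add(key)
            unique.append((part, rep))
    return unique
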