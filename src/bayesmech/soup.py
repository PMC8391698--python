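"""A primordial soup of coupled stochastic Lorenz macromolecules.

Each macromolecule carries three electrochemical states evolving as a
stochastic Lorenz system, and a planar position and velocity evolving
under stochastic Newtonian dynamics.  The electrochemical states of each
pair are diffusively coupled with a strength that falls off with the
distance between the pair (a Gaussian kernel), and each molecule feels a
force along the axis to its neighbours proportional to the difference in
their electrochemical states, plus weak damping and a weak harmonic
tether to each molecule's rest site on a rod-shaped lattice, which keeps
the particle cohesive so the distance kernel stays active.

The analysis pipeline identifies a Markovian partition of the molecules
from their time-averaged geometry and coupling graph, extracts the
maximally correlated linear combinations (canonical variates) of the
internal electrochemical states and the external motion, fits a
polynomial synchronisation manifold from the internal variate to the
external variate, and forms event-related averages by time-locking to
the strongest expressions of the first canonical variate.  The
generalised synchronisation so revealed is what gives the internal
states the appearance of inferring (representing) the external states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, stats

from bayesmech.blanket import StatePartition

__all__ = [
    "SoupConfig",
    "SoupState",
    "SoupPartition",
    "SyncManifold",
    "ERPResult",
    "simulate_soup",
    "isolated_chem_trajectory",
    "partition_soup",
    "cca_internal_external",
    "cca",
    "permutation_null_cca",
    "fit_sync_manifold",
    "select_events",
    "timelock_average",
    "erp_timelock",
]


@dataclass(frozen=True)
class SoupConfig:
    """Parameters of the soup simulation.

    Times are in Lorenz model time units.  ``analysis_window`` is the
    terminal span retained for the synchronisation analyses.
    """

    n_molecules: int = 9
    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    chem_rate: float = 1.0          # time-scale factor on the Lorenz drift
    coupling_scale: float = 2.0     # peak diffusive coupling strength
    coupling_length: float = 1.5    # kernel length scale (distance units)
    force_gain: float = 0.02        # Newtonian force per unit chem difference
    damping: float = 0.5            # velocity damping rate
    confinement: float = 0.2        # harmonic restoring rate toward rest sites
    chem_noise: float = 0.5         # sd scale of electrochemical fluctuations
    motion_noise: float = 0.1       # sd scale of velocity fluctuations
    mixing: Tuple[float, float, float] = (0.0, 0.0, 1.0)  # chem -> force projection
    dt: float = 0.005
    t_total: float = 576.0
    analysis_window: float = 512.0
    seed: int = 0
    divergence_bound: float = 1e6

    def __post_init__(self):
        for name in ("coupling_length", "dt", "t_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("coupling_scale", "force_gain", "damping", "confinement",
                     "chem_noise", "motion_noise", "chem_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if self.analysis_window > self.t_total:
            raise ValueError("analysis window exceeds total simulated time")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    def mini(self, seed: Optional[int] = None) -> "SoupConfig":
        """A nine-molecule short-horizon configuration for quick runs."""
        return replace(
            self,
            n_molecules=9,
            t_total=64.0,
            analysis_window=48.0,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class SoupState:
    """Simulated soup trajectories (time-major arrays)."""

    times: np.ndarray                 # (T,)
    positions: np.ndarray             # (T, n, 2)
    velocities: np.ndarray            # (T, n, 2)
    chem: np.ndarray                  # (T, n, 3)
    config: SoupConfig
    diverged: bool = False

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]

    def analysis_slice(self) -> slice:
        """Index slice of the terminal analysis window."""
        t_start = self.times[-1] - self.config.analysis_window
        start = int(np.searchsorted(self.times, t_start))
        return slice(start, len(self.times))


@dataclass
class SoupPartition:
    """Per-molecule role labels and their derivation rule."""

    labels: Tuple[str, ...]           # each in {internal, active, sensory, external}
    derivation: Dict[str, object]

    def molecules(self, role: str) -> List[int]:
        return [i for i, lab in enumerate(self.labels) if lab == role]

    def to_state_partition(self, states_per_molecule: int = 3) -> StatePartition:
        """Map molecule labels to a flat coordinate partition.

        Coordinate block ``i*states_per_molecule .. (i+1)*spm - 1`` belongs
        to molecule ``i``; roles map internal->mu, active->a, sensory->s,
        external->eta.
        """
        role_to_set = {"internal": [], "active": [], "sensory": [], "external": []}
        for i, lab in enumerate(self.labels):
            role_to_set[lab].extend(
                range(i * states_per_molecule, (i + 1) * states_per_molecule)
            )
        return StatePartition(
            eta=role_to_set["external"],
            s=role_to_set["sensory"],
            a=role_to_set["active"],
            mu=role_to_set["internal"],
        )


@dataclass
class SyncManifold:
    """Canonical variates and the fitted synchronisation manifold."""

    canonical_correlations: np.ndarray
    internal_loadings: np.ndarray       # (p_int, k)
    external_loadings: np.ndarray       # (p_ext, k)
    internal_variates: np.ndarray       # (T, k)
    external_variates: np.ndarray       # (T, k)
    poly_order: int = 5
    poly_coefficients: Optional[np.ndarray] = None
    ci_level: float = 0.90
    residual_sd: Optional[float] = None
    x_center: float = 0.0
    x_scale: float = 1.0

    def predict(self, internal_variate, with_interval: bool = False):
        """Evaluate the fitted polynomial manifold (and optionally the
        pointwise prediction interval half-widths)."""
        if self.poly_coefficients is None:
            raise ValueError("manifold has not been fitted")
        x = (np.asarray(internal_variate, float) - self.x_center) / self.x_scale
        X = np.vander(x, self.poly_order + 1, increasing=True)
        yhat = X @ self.poly_coefficients
        if not with_interval:
            return yhat
        XtX_inv = self._xtx_inv
        lev = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
        dof = max(self._n_fit - (self.poly_order + 1), 1)
        tq = stats.t.ppf(0.5 * (1 + self.ci_level), dof)
        half = tq * self.residual_sd * np.sqrt(1.0 + lev)
        return yhat, half


@dataclass
class ERPResult:
    """Event-related averages of time-locked epochs."""

    event_times: np.ndarray
    window: Tuple[int, int]           # samples before / after each event
    epochs: np.ndarray                # (n_events, W, channels)
    average: np.ndarray               # (W, channels)
    time_axis: np.ndarray             # (W,) relative times
    rescale: Optional[str] = None


def _lorenz_drift(c: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    """Lorenz vector field applied row-wise to an (n, 3) array."""
    x, y, z = c[:, 0], c[:, 1], c[:, 2]
    return np.stack([sigma * (y - x), x * (rho - z) - y, x * y - beta * z], axis=1)


def _initial_positions(n: int, spacing: float) -> np.ndarray:
    """Deterministic rod layout: a line of molecules centred at the origin."""
    x = (np.arange(n) - (n - 1) / 2.0) * spacing
    return np.column_stack([x, np.zeros(n)])


def _molecule_streams(seed: int, n: int) -> List[np.random.Generator]:
    """Independent per-molecule noise streams derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_soup(config: SoupConfig) -> SoupState:
    """Integrate the coupled soup with Euler--Maruyama.

    Per-molecule noise comes from independent child streams of the
    configured seed, so the decoupled limit reproduces isolated runs
    stream-for-stream (see :func:`isolated_chem_trajectory`).  A blow-up
    beyond ``divergence_bound`` truncates the run with a warning.
    """
    cfg = config
    n, n_steps, dt = cfg.n_molecules, cfg.n_steps, cfg.dt
    rngs = _molecule_streams(cfg.seed, n)
    # per-molecule draw order: initial chem perturbation, chem noise block,
    # motion noise block -- isolated runs replay the same prefix
    c0 = np.empty((n, 3))
    chem_noise = np.empty((n_steps, n, 3))
    motion_noise = np.empty((n_steps, n, 2))
    for i, rng in enumerate(rngs):
        c0[i] = np.array([1.0, 1.0, 25.0]) + rng.standard_normal(3)
        chem_noise[:, i, :] = rng.standard_normal((n_steps, 3))
        motion_noise[:, i, :] = rng.standard_normal((n_steps, 2))

    p_rest = _initial_positions(n, cfg.coupling_length)
    p = p_rest.copy()
    v = np.zeros((n, 2))
    c = c0.copy()
    w = np.asarray(cfg.mixing, float)

    T = n_steps + 1
    positions = np.empty((T, n, 2))
    velocities = np.empty((T, n, 2))
    chem = np.empty((T, n, 3))
    positions[0], velocities[0], chem[0] = p, v, c

    sq_chem = cfg.chem_noise * np.sqrt(dt)
    sq_mot = cfg.motion_noise * np.sqrt(dt)
    two_l2 = 2.0 * cfg.coupling_length**2
    diverged = False
    t_stop = n_steps

    for k in range(n_steps):
        if n > 1 and (cfg.coupling_scale > 0 or cfg.force_gain > 0):
            diff = p[None, :, :] - p[:, None, :]          # (i, j, 2): i -> j
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            K = cfg.coupling_scale * np.exp(-d2 / two_l2)
            np.fill_diagonal(K, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = diff / np.sqrt(d2)[:, :, None]
            unit[~np.isfinite(unit)] = 0.0
        else:
            K = None

        dc = cfg.chem_rate * _lorenz_drift(c, cfg.sigma, cfg.rho, cfg.beta)
        if K is not None and cfg.coupling_scale > 0:
            dc = dc + K @ c - K.sum(axis=1)[:, None] * c
        force = -cfg.damping * v - cfg.confinement * (p - p_rest)
        if K is not None and cfg.force_gain > 0:
            sc = c @ w
            s_diff = sc[:, None] - sc[None, :]            # chem_i - chem_j
            force = force + cfg.force_gain * np.einsum(
                "ij,ijk->ik", K * s_diff, unit
            )

        c = c + dc * dt + sq_chem * chem_noise[k]
        v = v + force * dt + sq_mot * motion_noise[k]
        p = p + v * dt
        positions[k + 1], velocities[k + 1], chem[k + 1] = p, v, c
        if (
            np.max(np.abs(c)) > cfg.divergence_bound
            or np.max(np.abs(p)) > cfg.divergence_bound
        ):
            warnings.warn(
                f"soup diverged at step {k + 1}; truncating", RuntimeWarning,
                stacklevel=2,
            )
            diverged = True
            t_stop = k + 1
            break

    sl = slice(0, t_stop + 1)
    return SoupState(
        times=dt * np.arange(t_stop + 1),
        positions=positions[sl],
        velocities=velocities[sl],
        chem=chem[sl],
        config=cfg,
        diverged=diverged,
    )


def isolated_chem_trajectory(config: SoupConfig, molecule: int) -> np.ndarray:
    """Electrochemical trajectory of one molecule with coupling removed.

    Replays the same per-molecule noise stream the coupled simulator
    uses, so with ``coupling_scale = 0`` this matches molecule ``molecule``
    of :func:`simulate_soup` exactly.  Returns an (n_steps+1, 3) array.
    """
    cfg = config
    rng = _molecule_streams(cfg.seed, cfg.n_molecules)[molecule]
    c = np.array([1.0, 1.0, 25.0]) + rng.standard_normal(3)
    noise = rng.standard_normal((cfg.n_steps, 3))
    out = np.empty((cfg.n_steps + 1, 3))
    out[0] = c
    sq = cfg.chem_noise * np.sqrt(cfg.dt)
    for k in range(cfg.n_steps):
        dc = cfg.chem_rate * _lorenz_drift(
            c[None, :], cfg.sigma, cfg.rho, cfg.beta
        )[0]
        c = c + dc * cfg.dt + sq * noise[k]
        out[k + 1] = c
    return out


def partition_soup(
    state: SoupState,
    rule: str = "radial-adjacency",
    n_internal: int = 1,
    adjacency_factor: float = 1.5,
) -> SoupPartition:
    """Label molecules internal / active / sensory / external.

    The default rule uses time-averaged positions over the analysis
    window: molecules are adjacent when their mean separation is below
    ``adjacency_factor * coupling_length``; the ``n_internal`` most
    central molecules (grown as a connected set from the innermost one)
    are internal, their graph boundary is active, the boundary's
    boundary is sensory, and everything else is external.
    """
    if rule != "radial-adjacency":
        raise ValueError(f"unknown partition rule {rule!r}")
    n = state.n_molecules
    if n < 4:
        raise ValueError("partitioning requires at least 4 molecules")
    sl = state.analysis_slice()
    mean_pos = state.positions[sl].mean(axis=0)          # (n, 2)
    diff = mean_pos[None, :, :] - mean_pos[:, None, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.max(dist) < 1e-12:
        raise ValueError("degenerate geometry: all molecules coincident")
    cutoff = adjacency_factor * state.config.coupling_length
    adj = (dist < cutoff) & ~np.eye(n, dtype=bool)

    radius = np.sqrt(np.einsum("ik,ik->i", mean_pos, mean_pos))
    order = np.argsort(radius, kind="stable")
    internal = [int(order[0])]
    while len(internal) < n_internal:
        candidates = [
            int(j)
            for j in order
            if j not in internal and adj[list(internal)][:, j].any()
        ]
        if not candidates:
            break
        internal.append(candidates[0])
    internal_set = set(internal)
    active = {
        int(j)
        for i in internal_set
        for j in np.flatnonzero(adj[i])
        if j not in internal_set
    }
    sensory = {
        int(j)
        for i in active
        for j in np.flatnonzero(adj[i])
        if j not in internal_set | active
    }
    labels = []
    for i in range(n):
        if i in internal_set:
            labels.append("internal")
        elif i in active:
            labels.append("active")
        elif i in sensory:
            labels.append("sensory")
        else:
            labels.append("external")
    return SoupPartition(
        labels=tuple(labels),
        derivation={
            "rule": rule,
            "n_internal": n_internal,
            "adjacency_factor": adjacency_factor,
            "cutoff": cutoff,
        },
    )


def cca(X: np.ndarray, Y: np.ndarray, reg: float = 1e-10):
    """Canonical correlation analysis by SVD of the whitened cross-covariance.

    Returns ``(correlations, a, b)`` with loadings as columns; signs fixed
    so the first nonzero entry of each loading is positive.  Near-singular
    within-set covariances are regularised with a relative ridge and a
    warning.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)

    def inv_sqrt(C, name):
        vals, vecs = linalg.eigh(C)
        tiny = vals < reg * vals.max()
        if np.any(tiny):
            warnings.warn(
                f"{name} covariance is rank deficient; regularising "
                f"{int(tiny.sum())} directions",
                RuntimeWarning,
                stacklevel=3,
            )
            vals = np.maximum(vals, reg * vals.max())
        return vecs @ np.diag(vals**-0.5) @ vecs.T

    Wx = inv_sqrt(Cxx, "internal")
    Wy = inv_sqrt(Cyy, "external")
    U, svals, Vt = linalg.svd(Wx @ Cxy @ Wy)
    k = min(X.shape[1], Y.shape[1])
    corr = np.clip(svals[:k], 0.0, 1.0)
    a = Wx @ U[:, :k]
    b = Wy @ Vt[:k].T
    for j in range(k):
        for vec_pair in ((a, b),):
            av = a[:, j]
            nz = np.flatnonzero(np.abs(av) > 1e-12)
            if nz.size and av[nz[0]] < 0:
                a[:, j] = -a[:, j]
                b[:, j] = -b[:, j]
    return corr, a, b


def permutation_null_cca(
    X: np.ndarray, Y: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Null distribution of the first canonical correlation.

    Randomly permutes the rows of ``Y`` relative to ``X`` ``n_perm``
    times, destroying any temporal alignment while preserving the
    marginal structure of each side.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for k in range(n_perm):
        out[k] = cca(X, Y[rng.permutation(Y.shape[0])])[0][0]
    return out


def cca_internal_external(
    state: SoupState,
    partition: SoupPartition,
    targets: str = "velocity",
) -> SyncManifold:
    """Canonical correlation between internal chemistry and external motion.

    ``targets`` selects the external-side channels: ``"velocity"``
    (default), ``"position"`` or ``"both"``.  Computed over the terminal
    analysis window; deterministic given its inputs.
    """
    internal = partition.molecules("internal")
    external = partition.molecules("external")
    if not internal or not external:
        raise ValueError("need at least one internal and one external molecule")
    sl = state.analysis_slice()
    X = state.chem[sl][:, internal, :].reshape(sl.stop - sl.start, -1)
    parts = []
    if targets in ("velocity", "both"):
        parts.append(state.velocities[sl][:, external, :])
    if targets in ("position", "both"):
        parts.append(state.positions[sl][:, external, :])
    if not parts:
        raise ValueError(f"unknown targets {targets!r}")
    Y = np.concatenate(parts, axis=2).reshape(sl.stop - sl.start, -1)
    corr, a, b = cca(X, Y)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    return SyncManifold(
        canonical_correlations=corr,
        internal_loadings=a,
        external_loadings=b,
        internal_variates=Xc @ a,
        external_variates=Yc @ b,
    )


def fit_sync_manifold(
    manifold: SyncManifold,
    internal_variate: Optional[np.ndarray] = None,
    external_variate: Optional[np.ndarray] = None,
    order: int = 5,
    ci: float = 0.90,
) -> SyncManifold:
    """Fit the polynomial synchronisation manifold.

    Least-squares polynomial (default order 5) predicting the external
    canonical variate from the internal one, with pointwise prediction
    intervals at level ``ci``.  The abscissa is internally standardised
    for conditioning; an ill-conditioned design triggers a regularised
    fit with a warning.
    """
    x = (
        manifold.internal_variates[:, 0]
        if internal_variate is None
        else np.asarray(internal_variate, float).ravel()
    )
    y = (
        manifold.external_variates[:, 0]
        if external_variate is None
        else np.asarray(external_variate, float).ravel()
    )
    n = x.size
    if n < order + 2:
        raise ValueError(f"need at least {order + 2} samples for order {order}")
    center = float(x.mean())
    scale = float(x.std()) or 1.0
    xs = (x - center) / scale
    X = np.vander(xs, order + 1, increasing=True)
    XtX = X.T @ X
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        warnings.warn(
            f"ill-conditioned polynomial design (cond={cond:.2e}); "
            "applying ridge regularisation",
            RuntimeWarning,
            stacklevel=2,
        )
        XtX = XtX + 1e-8 * np.trace(XtX) / XtX.shape[0] * np.eye(XtX.shape[0])
    coef = linalg.solve(XtX, X.T @ y, assume_a="pos")
    resid = y - X @ coef
    dof = max(n - (order + 1), 1)
    s = float(np.sqrt(resid @ resid / dof))
    out = replace(
        manifold,
        poly_order=order,
        poly_coefficients=coef,
        ci_level=ci,
        residual_sd=s,
        x_center=center,
        x_scale=scale,
    )
    out._xtx_inv = linalg.inv(XtX)
    out._n_fit = n
    return out


def select_events(
    variate: np.ndarray, n_events: int, exclusion: int
) -> np.ndarray:
    """Greedy selection of the largest local maxima with an exclusion radius.

    Returns sorted sample indices; fewer than ``n_events`` may be
    returned (with a warning) if the signal has too few separable peaks.
    """
    v = np.asarray(variate, float).ravel()
    order = np.argsort(v)[::-1]
    chosen: List[int] = []
    for idx in order:
        if 0 < idx < v.size - 1 and v[idx] >= v[idx - 1] and v[idx] >= v[idx + 1]:
            if all(abs(idx - c) >= exclusion for c in chosen):
                chosen.append(int(idx))
                if len(chosen) == n_events:
                    break
    if len(chosen) < n_events:
        warnings.warn(
            f"only {len(chosen)} separable events found (requested {n_events})",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.array(sorted(chosen), dtype=int)


def timelock_average(
    signal: np.ndarray, events: Sequence[int], pre: int, post: int
):
    """Extract epochs ``[event - pre, event + post)`` and their mean.

    ``signal`` is (T,) or (T, channels).  Events too close to either end
    are dropped.  Returns ``(epochs, average)`` with epochs shaped
    (n_events, pre + post, channels).
    """
    sig = np.asarray(signal, float)
    if sig.ndim == 1:
        sig = sig[:, None]
    T = sig.shape[0]
    keep = [e for e in events if e - pre >= 0 and e + post <= T]
    if not keep:
        raise ValueError("no events with a full epoch inside the signal")
    epochs = np.stack([sig[e - pre : e + post] for e in keep])
    return epochs, epochs.mean(axis=0)


def erp_timelock(
    state: SoupState,
    partition: SoupPartition,
    manifold: SyncManifold,
    n_events: int = 6,
    window: Tuple[float, float] = (1.0, 3.0),
) -> ERPResult:
    """Event-related averages time-locked to peaks of the first canonical
    variate.

    Selects the ``n_events`` largest local maxima of the internal
    canonical variate (greedy, exclusion radius = the window length),
    then averages epochs of the internal electrochemical states together
    with the external-motion canonical variate.  Channels are the
    internal chem coordinates followed by the external variate.
    """
    dt = state.config.dt
    pre = int(round(window[0] / dt))
    post = int(round(window[1] / dt))
    if pre + post < 2:
        raise ValueError("window too short for the sampling step")
    sl = state.analysis_slice()
    variate = manifold.internal_variates[:, 0]
    events = select_events(variate, n_events, exclusion=pre + post)
    internal = partition.molecules("internal")
    chem = state.chem[sl][:, internal, :].reshape(len(variate), -1)
    channels = np.column_stack([chem, manifold.external_variates[:, 0]])
    usable = [e for e in events if e - pre >= 0 and e + post <= len(variate)]
    epochs, average = timelock_average(channels, usable, pre, post)
    event_times = state.times[sl][usable]
    return ERPResult(
        event_times=event_times,
        window=(pre, post),
        epochs=epochs,
        average=average,
        time_axis=dt * (np.arange(pre + post) - pre),
    )
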