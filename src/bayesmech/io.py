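"""Configuration and file I/O: system specs, fixtures, trajectories, manifests.

System specs are JSON or YAML mappings with keys ``dim``, ``H``
(row-major nested lists), ``Q``, ``Gamma`` (diagonal as a flat list, or a
full matrix), and optional ``mean``.  Floats round-trip at 17 significant
digits.  Every CLI run writes a :class:`RunManifest` alongside its
outputs so any result can be regenerated from version + seed + config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import yaml

from bayesmech import __version__ as _pkg_version
from bayesmech.nessflow import GaussianNESS, Trajectory, build_gaussian_ness
from bayesmech.soup import SoupConfig, SoupState

__all__ = [
    "load_system_spec",
    "save_system_spec",
    "load_soup_config",
    "save_soup_config",
    "save_trajectory",
    "load_trajectory",
    "save_soup_state",
    "load_soup_state",
    "make_fixture",
    "RunManifest",
]

log = logging.getLogger("bayesmech")

FIXTURE_KINDS = (
    "gaussian-blanket",
    "gaussian-counterexample-c1",
    "gaussian-counterexample-c2",
    "soup-mini",
)


def _parse(path: Union[str, Path]) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    # fall back: try YAML (a superset of JSON)
    return yaml.safe_load(text)


def load_system_spec(path: Union[str, Path]) -> GaussianNESS:
    """Load and validate a Gaussian system spec.

    Raises ``ValueError`` naming the violated invariant (asymmetric Q,
    indefinite H, non-diagonal Gamma, dimension mismatch).
    """
    data = _parse(path)
    if not isinstance(data, dict):
        raise ValueError(f"system spec {path} did not parse to a mapping")
    try:
        dim = int(data["dim"])
        H = np.asarray(data["H"], float)
        Q = np.asarray(data["Q"], float)
        Gamma = np.asarray(data["Gamma"], float)
    except KeyError as exc:
        raise ValueError(f"system spec missing required key {exc}") from exc
    if H.shape != (dim, dim):
        raise ValueError(f"H has shape {H.shape}, expected ({dim}, {dim})")
    if Gamma.ndim == 1:
        Gamma = np.diag(Gamma)
    mean = np.asarray(data.get("mean", np.zeros(dim)), float)
    return build_gaussian_ness(H=H, Q=Q, Gamma=Gamma, mean=mean)


def save_system_spec(system: GaussianNESS, path: Union[str, Path]) -> None:
    """Serialise a Gaussian system spec (YAML or JSON by extension)."""
    path = Path(path)
    data = {
        "dim": int(system.dim),
        "H": system.H.tolist(),
        "Q": system.Q.tolist(),
        "Gamma": np.diag(system.Gamma).tolist(),
        "mean": system.mean.tolist(),
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_soup_config(path: Union[str, Path]) -> SoupConfig:
    data = _parse(path)
    if "mixing" in data:
        data["mixing"] = tuple(data["mixing"])
    return SoupConfig(**data)


def save_soup_config(config: SoupConfig, path: Union[str, Path]) -> None:
    data = dataclasses.asdict(config)
    data["mixing"] = list(data["mixing"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def save_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory to HDF5 (datasets /times, /states) or CSV."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=traj.times)
            f.create_dataset("states", data=traj.states)
            f.attrs["seed"] = traj.seed
            f.attrs["dt"] = traj.dt
            f.attrs["integrator_id"] = traj.integrator_id
    else:
        header = "time," + ",".join(f"x{i}" for i in range(traj.states.shape[1]))
        arr = np.column_stack([traj.times, traj.states])
        np.savetxt(path, arr, delimiter=",", header=header, comments="")


def load_trajectory(path: Union[str, Path]) -> Trajectory:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return Trajectory(
                times=f["times"][()],
                states=f["states"][()],
                seed=int(f.attrs["seed"]),
                dt=float(f.attrs["dt"]),
                integrator_id=str(f.attrs["integrator_id"]),
            )
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    times = arr[:, 0]
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return Trajectory(times=times, states=arr[:, 1:], seed=-1, dt=dt)


def save_soup_state(state: SoupState, path: Union[str, Path]) -> None:
    """HDF5 layout: /times, /positions, /velocities, /chem (time-major)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=state.times)
        f.create_dataset("positions", data=state.positions)
        f.create_dataset("velocities", data=state.velocities)
        f.create_dataset("chem", data=state.chem)
        cfg = dataclasses.asdict(state.config)
        cfg["mixing"] = list(cfg["mixing"])
        f.attrs["config_json"] = json.dumps(cfg)
        f.attrs["diverged"] = state.diverged


def load_soup_state(path: Union[str, Path]) -> SoupState:
    import h5py

    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config_json"])
        cfg["mixing"] = tuple(cfg["mixing"])
        return SoupState(
            times=f["times"][()],
            positions=f["positions"][()],
            velocities=f["velocities"][()],
            chem=f["chem"][()],
            config=SoupConfig(**cfg),
            diverged=bool(f.attrs["diverged"]),
        )


# ---------------------------------------------------------------------------
# deterministic fixtures

def blanket_fixture_matrices():
    """A 4-state (eta, s, a, mu) system satisfying the sparse blanket form.

    Chain-structured precision (eta-s, s-a, a-mu couplings only) with
    solenoidal coupling within the permitted blocks (eta<->s, a<->mu).
    """
    H = np.array(
        [
            [2.0, 0.5, 0.0, 0.0],
            [0.5, 2.0, 0.3, 0.0],
            [0.0, 0.3, 2.0, 0.3],
            [0.0, 0.0, 0.3, 2.0],
        ]
    )
    Q = np.zeros((4, 4))
    Q[0, 1], Q[1, 0] = 0.4, -0.4       # eta <-> s (permitted)
    Q[2, 3], Q[3, 2] = 0.25, -0.25     # a <-> mu (permitted)
    Gamma = np.eye(4)
    return H, Q, Gamma


def counterexample_c1_matrices():
    """Flow constraint holds but the blanket condition fails.

    The precision couples internal and external states (H[mu,eta] != 0),
    yet a tuned solenoidal entry cancels the Jacobian coupling so the
    autonomous flow is still uncoupled from external states.
    """
    H = np.array(
        [
            [2.0, 0.5, 0.0, 0.4],
            [0.5, 2.0, 0.3, 0.0],
            [0.0, 0.3, 2.0, 0.3],
            [0.4, 0.0, 0.3, 2.0],
        ]
    )
    Q = np.zeros((4, 4))
    # J[mu,eta] = Q[3,0] H[0,0] - H[3,0]  -> zero when Q[3,0] = H[3,0]/H[0,0]
    Q[3, 0] = H[3, 0] / H[0, 0]
    Q[0, 3] = -Q[3, 0]
    Gamma = np.eye(4)
    return H, Q, Gamma


def counterexample_c2_matrices():
    """Blanket condition holds but the flow constraint fails.

    H[mu,eta] = 0 yet a solenoidal eta<->mu coupling drags the external
    gradient into the internal flow: J[mu,eta] = -Q[eta,mu]^T H[eta,eta].
    """
    H = np.array(
        [
            [2.0, 0.5, 0.0, 0.0],
            [0.5, 2.0, 0.3, 0.0],
            [0.0, 0.3, 2.0, 0.3],
            [0.0, 0.0, 0.3, 2.0],
        ]
    )
    Q = np.zeros((4, 4))
    Q[0, 3], Q[3, 0] = 0.3, -0.3       # eta <-> mu (precluded by the sparse form)
    Gamma = np.eye(4)
    return H, Q, Gamma


FIXTURE_PARTITION = "eta=0;s=1;a=2;mu=3"


def soup_mini_config(seed: int = 0) -> SoupConfig:
    """Nine molecules, short horizon: completes in well under a minute."""
    return SoupConfig().mini(seed=seed)


def make_fixture(kind: str, seed: int, outdir: Union[str, Path]) -> List[Path]:
    """Write a deterministic, documented test fixture to ``outdir``.

    Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    if kind == "gaussian-blanket":
        H, Q, Gamma = blanket_fixture_matrices()
    elif kind == "gaussian-counterexample-c1":
        H, Q, Gamma = counterexample_c1_matrices()
    elif kind == "gaussian-counterexample-c2":
        H, Q, Gamma = counterexample_c2_matrices()
    elif kind == "soup-mini":
        cfg = soup_mini_config(seed=seed)
        path = outdir / "soup-mini.yaml"
        save_soup_config(cfg, path)
        written.append(path)
        return written
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    system = build_gaussian_ness(H, Q, Gamma)
    path = outdir / f"{kind}.yaml"
    save_system_spec(system, path)
    (outdir / f"{kind}.partition.txt").write_text(FIXTURE_PARTITION + "\n")
    written.extend([path, outdir / f"{kind}.partition.txt"])
    return written


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    config_hash: str
    seed: Optional[int]
    version: str = _pkg_version
    timestamp: float = field(default_factory=time.time)
    outputs: List[str] = field(default_factory=list)

    @classmethod
    def for_run(cls, command: str, config_obj, seed, outputs) -> "RunManifest":
        blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
        return cls(
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seed=seed,
            outputs=[str(p) for p in outputs],
        )

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
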