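"""Energy minimization, Langevin dynamics, and slab box manipulation.

The integrator is BAOAB Langevin (velocity Verlet in the zero-friction
limit) with a Verlet/cell neighbor list.  Coordinates are evolved unwrapped;
distances always use the minimum image, so frames can be wrapped for density
work or differenced directly for displacement work.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from ccphase import _kernels
from ccphase.forcefield import (
    ForceFieldParams,
    InteractionMatrix,
    static_complementary_pairs,
    total_energy_forces,
)
from ccphase.topology import SystemTopology

KB = _kernels.KB

__all__ = [
    "Configuration",
    "Trajectory",
    "IntegratorParams",
    "EngineBlowupError",
    "sample_velocities",
    "minimize",
    "integrate_langevin",
    "resize_box",
    "wrap_chains",
]


class EngineBlowupError(RuntimeError):
    """Integration produced a per-step displacement beyond a quarter box."""


@dataclass
class Configuration:
    """Positions (nm), velocities (nm/ps) and periodic box of one system state."""

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    topology: SystemTopology

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        n = self.topology.n_beads
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("array lengths inconsistent with topology")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(), self.velocities.copy(), self.box.copy(), self.topology
        )


@dataclass
class Trajectory:
    """Saved frames of one production run (times ps, unwrapped positions nm)."""

    frames: np.ndarray  # (F, n, 3)
    times: np.ndarray  # (F,)
    kinetic_temperature: np.ndarray  # (F,)
    box: np.ndarray
    topology: SystemTopology
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def final_configuration(self, velocities=None) -> Configuration:
        v = velocities if velocities is not None else np.zeros_like(self.frames[-1])
        return Configuration(self.frames[-1].copy(), v, self.box.copy(), self.topology)


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin integration settings (dt ps, friction 1/ps, temperature K)."""

    dt: float = 0.01
    friction: float = 1.0
    temperature: float = 310.0
    n_steps: int = 100_000
    save_interval: int = 500
    seed: int = 0
    thermostat_interval: int = 5

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _params_hash(ff: ForceFieldParams, ip: IntegratorParams) -> str:
    return hashlib.sha256(f"{ff!r}|{ip!r}".encode()).hexdigest()[:16]


def sample_velocities(topology: SystemTopology, temperature: float, seed: int) -> np.ndarray:
    """Maxwell-Boltzmann velocities (zero total momentum), nm/ps."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature / topology.masses)[:, None]
    v = rng.standard_normal((topology.n_beads, 3)) * sigma
    v -= np.average(v, axis=0, weights=topology.masses)
    return v


def minimize(
    config: Configuration,
    matrix: InteractionMatrix | None = None,
    params: ForceFieldParams | None = None,
    max_steps: int = 500,
    force_tol: float = 10.0,
) -> Configuration:
    """L-BFGS energy minimization; returns a new configuration.

    Guaranteed not to increase the energy (falls back to the input if the
    optimizer cannot improve it); deterministic for given inputs.
    ``force_tol`` is the max |force| component (kJ/mol/nm) at convergence.
    """
    params = params or ForceFieldParams()
    matrix = matrix or InteractionMatrix.default(params)
    topology = config.topology
    box = config.box
    x0 = config.positions.ravel().copy()

    def fun(x):
        e, f = total_energy_forces(x.reshape(-1, 3), box, topology, matrix, params)
        if not np.isfinite(e):
            raise FloatingPointError("non-finite energy during minimization")
        return e, -f.ravel()

    e0, _ = fun(x0)
    res = _scipy_minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": force_tol, "ftol": 1e-12},
    )
    x_best, e_best = (res.x, res.fun) if res.fun <= e0 else (x0, e0)
    out = config.copy()
    out.positions = x_best.reshape(-1, 3)
    return out


def integrate_langevin(
    config: Configuration,
    params: IntegratorParams,
    matrix: InteractionMatrix | None = None,
    ff: ForceFieldParams | None = None,
    com_removal_interval: int = 100,
    initialize_velocities: bool = False,
) -> Trajectory:
    """Run Langevin dynamics; mutates ``config`` to the final state.

    Reproducible bit-for-bit for a given seed.  Raises
    :class:`EngineBlowupError` if any bead moves more than a quarter box in
    one step.
    """
    ff = ff or ForceFieldParams()
    matrix = matrix or InteractionMatrix.default(ff)
    top = config.topology
    if initialize_velocities:
        config.velocities = sample_velocities(top, params.temperature, params.seed + 7)

    frames, times, kin, status = _kernels.run_langevin(
        config.positions,
        config.velocities,
        config.box,
        top.masses,
        params.n_steps,
        params.dt,
        params.friction,
        KB * params.temperature,
        params.save_interval,
        params.seed % (2 ** 31 - 1),
        top.chain_id,
        top.type_id,
        top.registry,
        top.coil_len,
        top.coil_seg,
        top.seg_start,
        top.seg_len,
        static_complementary_pairs(top, matrix),
        matrix.rule_matrix,
        matrix.eps_matrix,
        ff.sigma_sticky,
        ff.cutoff_sticky,
        ff.sigma_rep,
        ff.epsilon_rep,
        ff.gate_cos,
        ff.r_floor_sticky,
        ff.r_floor_rep,
        top.bonds,
        ff.bond_r0,
        ff.bond_k,
        top.angles,
        ff.coil_angle_k,
        ff.neighbor_skin,
        com_removal_interval,
        params.thermostat_interval,
    )
    if status != 0:
        raise EngineBlowupError(
            f"blow-up after {len(times)} saved frames "
            f"(dt={params.dt}, T={params.temperature})"
        )
    return Trajectory(
        frames=frames,
        times=times,
        kinetic_temperature=kin,
        box=config.box.copy(),
        topology=top,
        metadata={
            "temperature": params.temperature,
            "seed": params.seed,
            "dt": params.dt,
            "friction": params.friction,
            "params_hash": _params_hash(ff, params),
        },
    )


def wrap_chains(config: Configuration) -> Configuration:
    """Translate each chain by lattice vectors so its COM lies in the box.

    Chains stay intact (whole-chain translations only).
    """
    out = config.copy()
    top = config.topology
    for c in range(top.n_chains):
        sl = top.chain_slice(c)
        com = out.positions[sl].mean(axis=0)
        shift = np.floor(com / out.box) * out.box
        out.positions[sl] -= shift
    return out


def resize_box(
    config: Configuration,
    axis: int = 2,
    scale: float | None = None,
    target_length: float | None = None,
    affine: bool = True,
) -> Configuration:
    """Rescale one box dimension.

    ``affine=True`` (compression stages): chain centers of mass are rescaled
    along the axis, internal geometry untouched, so bonds never stretch.
    ``affine=False`` (slab expansion): the box alone is rescaled after
    wrapping whole chains inside, leaving coordinates fixed and creating
    vacuum on either side of the dense region.
    """
    if (scale is None) == (target_length is None):
        raise ValueError("give exactly one of scale or target_length")
    if scale is None:
        scale = float(target_length) / float(config.box[axis])
    if scale <= 0:
        raise ValueError("scale must be positive")

    out = wrap_chains(config)
    top = config.topology
    if affine:
        for c in range(top.n_chains):
            sl = top.chain_slice(c)
            com = out.positions[sl, axis].mean()
            out.positions[sl, axis] += (scale - 1.0) * com
    out.box = out.box.copy()
    out.box[axis] *= scale
    return out
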