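"""Force field: sticky coil-coil attraction, excluded volume, bonded terms.

The model is a sticker--spacer associative polymer at C-alpha resolution.
Complementary coil beads attract through a truncated-shifted 12-6 potential
(sigma = 0.570 nm, epsilon = 7.5 kJ/mol per bead pair); everything else
repels through a WCA core.  Attraction is *registry- and orientation-gated*:
a bead at registry i only attracts the complementary bead (parallel: same
registry; antiparallel: mirrored registry) and only while the two coil axes
point the right way (within a 60-degree band), which keeps dimer interfaces
in-register and lets parallel- vs antiparallel-pairing homodimers frustrate
the wrong contacts.

Units: nm, ps, kJ/mol, amu, K (GROMACS convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ccphase import _kernels
from ccphase.constructs import COIL_LIBRARY
from ccphase.topology import COIL_TYPE_NAMES, SystemTopology

KB = _kernels.KB

__all__ = [
    "ForceFieldParams",
    "InteractionMatrix",
    "static_complementary_pairs",
    "sticky_pair_energy",
    "excluded_volume_energy",
    "total_energy_forces",
    "CALIBRATION_TEMPERATURE",
    "ITC_KD_MOLAR",
    "calibrated_pair_scales",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants (lengths nm, energies kJ/mol).

    ``sigma_sticky``/``epsilon_sticky`` set the complementary coil-bead
    attraction; the rest are conventional coarse-grained choices: a WCA
    repulsive core on every non-complementary pair, stiff harmonic bonds at
    the C-alpha spacing, and a cosine bending term (minimum at 180 degrees)
    on coil-internal triplets that keeps coil segments rod-like while
    leaving linkers fully flexible.
    """

    sigma_sticky: float = 0.570
    epsilon_sticky: float = 7.5
    cutoff_sticky: float = 2.5 * 0.570
    sigma_rep: float = 0.57
    epsilon_rep: float = 1.0
    bond_r0: float = 0.38
    bond_k: float = 4000.0
    coil_angle_theta0: float = math.pi
    coil_angle_k: float = 100.0
    gate_cos: float = 0.5  # orientation gate: |axis angle| <= 60 deg
    r_floor_sticky: float = 0.50  # constant-force continuation below this
    r_floor_rep: float = 0.44
    neighbor_skin: float = 0.3

    def __post_init__(self):
        if min(self.sigma_sticky, self.sigma_rep, self.bond_r0) <= 0:
            raise ValueError("lengths must be positive")
        if min(self.epsilon_sticky, self.epsilon_rep, self.bond_k, self.coil_angle_k) < 0:
            raise ValueError("energy scales must be non-negative")
        if self.cutoff_sticky < self.sigma_sticky:
            raise ValueError("cutoff_sticky must be >= sigma_sticky")

    @property
    def cutoff_rep(self) -> float:
        """WCA cutoff: the 12-6 minimum, 2^(1/6) sigma_rep."""
        return 2.0 ** (1.0 / 6.0) * self.sigma_rep

    @property
    def sticky_shift(self) -> float:
        """Energy subtracted at cutoff_sticky (per unit epsilon)."""
        x6 = (self.sigma_sticky / self.cutoff_sticky) ** 6
        return 4.0 * (x6 * x6 - x6)

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# affinity calibration
# ---------------------------------------------------------------------------

#: ITC dissociation constants of the isolated coil pairs (molar).
ITC_KD_MOLAR = {
    ("S1h", "S2h"): 2.3e-3,
    ("S3h", "S4h"): 0.34e-3,
    ("P5f", "P6f"): 5.9e-6,
    ("P13f", "P14f"): 2.3e-6,
}

#: Model temperature (K) at which single coil pairs bind reversibly with
#: occupancies in the measurable range; fixed by the dimer-equilibrium
#: calibration in :func:`ccphase.slab.calibrate_temperature_scale`.
CALIBRATION_TEMPERATURE = 625.0

#: Per-pair epsilon scale factors, fitted so that each pair's simulated
#: dissociation constant at the calibration temperature tracks its ITC
#: measurement (S1h-S2h anchors the temperature scale at scale 1; binding
#: free energy is strongly sublinear in total contact energy, so these are
#: fitted by two-chain simulation rather than derived analytically).
#: Homodimeric coils, which have no measured affinity, keep scale 1.
FITTED_PAIR_SCALES = {
    ("S1h", "S2h"): 1.00,
    ("S3h", "S4h"): 1.10,
    ("P5f", "P6f"): 1.12,
    ("P13f", "P14f"): 1.16,
}


def calibrated_pair_scales() -> dict:
    """Fitted per-pair epsilon scale factors (see FITTED_PAIR_SCALES)."""
    return dict(FITTED_PAIR_SCALES)


class InteractionMatrix:
    """Symmetric coil-pair specificity table with orientations and strengths.

    Entries are ``"none"`` or ``("attract", orientation)`` with orientation
    ``"parallel"`` / ``"antiparallel"``.  Internally stored as dense arrays
    over :data:`ccphase.topology.COIL_TYPE_NAMES` for the kernels:
    ``rule_matrix`` (0 none, 1 parallel, 2 antiparallel) and ``eps_matrix``
    (absolute per-bead epsilon, kJ/mol).
    """

    def __init__(self, rule_matrix: np.ndarray, eps_matrix: np.ndarray):
        nt = len(COIL_TYPE_NAMES)
        if rule_matrix.shape != (nt, nt) or eps_matrix.shape != (nt, nt):
            raise ValueError("matrix shape mismatch")
        if not np.array_equal(rule_matrix, rule_matrix.T):
            raise ValueError("rule matrix must be symmetric")
        if not np.allclose(eps_matrix, eps_matrix.T):
            raise ValueError("epsilon matrix must be symmetric")
        self.rule_matrix = rule_matrix.astype(np.int64)
        self.eps_matrix = eps_matrix.astype(np.float64)
        self._index = {n: i for i, n in enumerate(COIL_TYPE_NAMES)}

    @classmethod
    def default(cls, params: ForceFieldParams | None = None,
                scales: dict | None = None) -> "InteractionMatrix":
        """Matrix from the coil library: designed partners attract in their
        designed orientation, everything else is orthogonal."""
        params = params or ForceFieldParams()
        if scales is None:
            scales = calibrated_pair_scales()
        nt = len(COIL_TYPE_NAMES)
        rule = np.zeros((nt, nt), dtype=np.int64)
        eps = np.zeros((nt, nt), dtype=np.float64)
        for i, a in enumerate(COIL_TYPE_NAMES):
            coil = COIL_LIBRARY[a]
            for b in coil.partners:
                j = list(COIL_TYPE_NAMES).index(b)
                orient = coil.orientation[b]
                rule[i, j] = 1 if orient == "parallel" else 2
                rule[j, i] = rule[i, j]
                s = scales.get((a, b), scales.get((b, a), 1.0))
                eps[i, j] = params.epsilon_sticky * s
                eps[j, i] = eps[i, j]
        return cls(rule, eps)

    def entry(self, a: str, b: str):
        r = self.rule_matrix[self._index[a], self._index[b]]
        if r == 0:
            return "none"
        return ("attract", "parallel" if r == 1 else "antiparallel")

    def epsilon(self, a: str, b: str) -> float:
        return float(self.eps_matrix[self._index[a], self._index[b]])


# ---------------------------------------------------------------------------
# reference (scalar) energy functions
# ---------------------------------------------------------------------------


def _capped_lj(r: float, sigma: float, eps: float, shift: float,
               r_floor: float) -> float:
    """12-6 energy with the cutoff shift and the constant-force cap."""
    rr = max(r, r_floor)
    x6 = (sigma / rr) ** 6
    u = 4.0 * eps * (x6 * x6 - x6) - shift
    if r < r_floor:
        frad = 24.0 * eps * (2.0 * x6 * x6 - x6) / r_floor
        u += frad * (r_floor - r)
    return u


def sticky_pair_energy(
    r: float,
    reg_i: int,
    reg_j: int,
    L_i: int,
    L_j: int,
    pair_rule,
    params: ForceFieldParams,
    epsilon: float | None = None,
    axis_dot: float | None = None,
) -> float:
    """Sticky energy of one bead pair (truncated-shifted 12-6), kJ/mol.

    Zero beyond the cutoff, for orthogonal pairs, for non-complementary
    registries (parallel: equal; antiparallel: mirrored, equal lengths), and
    when ``axis_dot`` (cosine between the two coil axes, if given) fails the
    orientation gate.  The unshifted minimum is ``-epsilon`` at
    ``2^(1/6) sigma_sticky``; the returned value includes the cutoff shift.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    if pair_rule == "none" or pair_rule is None:
        return 0.0
    _, orientation = pair_rule
    if orientation == "parallel":
        if reg_i != reg_j:
            return 0.0
        required_sign = 1.0
    else:
        if L_i != L_j or reg_j != L_j + 1 - reg_i:
            return 0.0
        required_sign = -1.0
    if axis_dot is not None and required_sign * axis_dot < params.gate_cos:
        return 0.0
    if r >= params.cutoff_sticky:
        return 0.0
    eps = params.epsilon_sticky if epsilon is None else epsilon
    return _capped_lj(r, params.sigma_sticky, eps, eps * params.sticky_shift,
                      params.r_floor_sticky)


def excluded_volume_energy(r: float, params: ForceFieldParams) -> float:
    """WCA repulsion (12-6 truncated at its minimum, shifted to zero)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if r >= params.cutoff_rep:
        return 0.0
    return _capped_lj(r, params.sigma_rep, params.epsilon_rep,
                      -params.epsilon_rep, params.r_floor_rep)


# ---------------------------------------------------------------------------
# system energy/forces
# ---------------------------------------------------------------------------


def static_complementary_pairs(topology: SystemTopology,
                               matrix: InteractionMatrix) -> np.ndarray:
    """All bead pairs (i < j) that can ever feel the sticky attraction.

    A pair qualifies when the coil types attract, the registries are
    complementary under the pair's orientation, and the beads sit on
    distinct segments.  The result depends only on the topology and the
    rule matrix, so it is cached on the topology.
    """
    key = matrix.rule_matrix.tobytes()
    cache = getattr(topology, "_sticky_pairs_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    t = topology.type_id
    reg = topology.registry
    L = topology.coil_len
    seg = topology.coil_seg
    idx = np.arange(topology.n_beads)
    out = []
    nt = matrix.rule_matrix.shape[0]
    for ti in range(nt):
        for tj in range(ti, nt):
            o = matrix.rule_matrix[ti, tj]
            if o == 0:
                continue
            I = idx[t == ti]
            J = idx[t == tj]
            if len(I) == 0 or len(J) == 0:
                continue
            Ri = reg[I][:, None]
            Rj = reg[J][None, :]
            if o == 1:
                m = Ri == Rj
            else:
                m = (L[I][:, None] == L[J][None, :]) & (
                    Rj == L[I][:, None] + 1 - Ri
                )
            m &= seg[I][:, None] != seg[J][None, :]
            if ti == tj:
                m &= I[:, None] < J[None, :]
            ii, jj = np.nonzero(m)
            a, b = I[ii], J[jj]
            out.append(np.column_stack([np.minimum(a, b), np.maximum(a, b)]))
    pairs = (
        np.vstack(out).astype(np.int32)
        if out
        else np.zeros((0, 2), dtype=np.int32)
    )
    topology._sticky_pairs_cache = (key, pairs)
    return pairs


def total_energy_forces(
    positions: np.ndarray,
    box,
    topology: SystemTopology,
    matrix: InteractionMatrix | None = None,
    params: ForceFieldParams | None = None,
    neighbor: str = "cell",
):
    """Total potential energy (kJ/mol) and per-bead forces (kJ/mol/nm).

    ``neighbor="cell"`` uses the production cell/Verlet pair search;
    ``neighbor="all"`` enumerates every pair (oracle path for tests).
    Forces are the exact negative gradient of the returned energy away from
    the orientation-gate and cap boundaries.
    """
    params = params or ForceFieldParams()
    matrix = matrix or InteractionMatrix.default(params)
    box = np.asarray(box, dtype=np.float64)
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    if pos.shape[0] != topology.n_beads:
        raise ValueError("positions inconsistent with topology")
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite positions")
    if neighbor == "all":
        big = 0.5 * math.sqrt(float(np.sum(box ** 2))) + 1.0
        list_cut_s = list_cut_w = big
    else:
        list_cut_s = params.cutoff_sticky
        list_cut_w = params.cutoff_rep
    energy, forces = _kernels.energy_forces_fresh(
        pos,
        box,
        topology.chain_id,
        topology.type_id,
        topology.registry,
        topology.coil_len,
        topology.coil_seg,
        topology.seg_start,
        topology.seg_len,
        static_complementary_pairs(topology, matrix),
        matrix.rule_matrix,
        matrix.eps_matrix,
        params.sigma_sticky,
        params.cutoff_sticky,
        params.sigma_rep,
        params.epsilon_rep,
        params.gate_cos,
        params.r_floor_sticky,
        params.r_floor_rep,
        topology.bonds,
        params.bond_r0,
        params.bond_k,
        topology.angles,
        params.coil_angle_k,
        list_cut_s,
        list_cut_w,
    )
    return energy, forces
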