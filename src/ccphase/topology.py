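"""Flat multi-chain system topology used by the force field and engine.

All per-bead properties are packed into contiguous numpy arrays so the
numba kernels can index them directly.  Bead order is chain-major: all beads
of chain 0, then chain 1, ...; within a chain, N-terminus first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ccphase.constructs import (
    COIL_LIBRARY,
    ConstructSpec,
    build_chain,
)

__all__ = ["SystemTopology", "build_system_topology", "COIL_TYPE_NAMES"]

#: Global coil-type index used by the interaction matrices.
COIL_TYPE_NAMES: tuple = tuple(COIL_LIBRARY)
COIL_TYPE_INDEX: dict = {n: i for i, n in enumerate(COIL_TYPE_NAMES)}

BEAD_MASS_AMU = 110.0  # average residue mass; dynamics contrasts are relative


@dataclass
class SystemTopology:
    """Per-bead and per-segment arrays for a multi-chain system.

    Attributes
    ----------
    chain_id : (n,) int32
        Chain membership of each bead.
    type_id : (n,) int32
        Coil-type index into :data:`COIL_TYPE_NAMES`, or -1 for linker beads.
    registry : (n,) int32
        1-based N→C index within the coil segment, 0 for linker beads.
    coil_len : (n,) int32
        Length (beads) of the coil segment a bead belongs to, 0 for linkers.
    coil_seg : (n,) int32
        Global coil-segment index, -1 for linker beads.
    seg_start, seg_len : (n_coil_segments,) int32
        First bead and bead count of every coil segment.
    seg_chain, seg_type : (n_coil_segments,) int32
        Owning chain and coil-type index of every coil segment.
    bonds : (m, 2) int32; angles : (k, 3) int32
        Consecutive-bead bonds; coil-internal angle triplets.
    """

    chain_id: np.ndarray
    type_id: np.ndarray
    registry: np.ndarray
    coil_len: np.ndarray
    coil_seg: np.ndarray
    seg_start: np.ndarray
    seg_len: np.ndarray
    seg_chain: np.ndarray
    seg_type: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    masses: np.ndarray
    chain_construct: list  # ConstructSpec per chain
    chain_start: np.ndarray  # first bead of each chain, plus final sentinel

    @property
    def n_beads(self) -> int:
        return len(self.chain_id)

    @property
    def n_chains(self) -> int:
        return len(self.chain_construct)

    @property
    def n_coil_segments(self) -> int:
        return len(self.seg_start)

    def chain_slice(self, c: int) -> slice:
        return slice(int(self.chain_start[c]), int(self.chain_start[c + 1]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "constructs": [s.name for s in self.chain_construct],
                "chain_start": self.chain_start.tolist(),
                "chain_id": self.chain_id.tolist(),
                "type_id": self.type_id.tolist(),
                "type_names": list(COIL_TYPE_NAMES),
                "registry": self.registry.tolist(),
                "coil_seg": self.coil_seg.tolist(),
                "bonds": self.bonds.tolist(),
                "angles": self.angles.tolist(),
            }
        )


def build_system_topology(components: list) -> SystemTopology:
    """Assemble a :class:`SystemTopology` from (ConstructSpec, copy_number) pairs."""
    chain_id, type_id, registry, coil_len, coil_seg = [], [], [], [], []
    seg_start, seg_len, seg_chain, seg_type = [], [], [], []
    bonds, angles = [], []
    chain_construct: list[ConstructSpec] = []
    chain_start = [0]

    offset = 0
    chain = 0
    seg_counter = 0
    for spec, copies in components:
        bc = build_chain(spec)
        n = bc.n_beads
        for _ in range(copies):
            chain_construct.append(spec)
            chain_id.extend([chain] * n)
            # per-bead coil metadata
            bead = offset
            for ordinal, (cls, nm) in enumerate(spec.segments):
                if cls == "coil":
                    L = COIL_LIBRARY[nm].residues
                    t = COIL_TYPE_INDEX[nm]
                    seg_start.append(bead)
                    seg_len.append(L)
                    seg_chain.append(chain)
                    seg_type.append(t)
                    for r in range(1, L + 1):
                        type_id.append(t)
                        registry.append(r)
                        coil_len.append(L)
                        coil_seg.append(seg_counter)
                    # rod-keeping angles on coil-internal triplets
                    for a in range(bead, bead + L - 2):
                        angles.append((a, a + 1, a + 2))
                    bead += L
                    seg_counter += 1
                else:
                    from ccphase.constructs import LINKER_LIBRARY

                    L = LINKER_LIBRARY[nm].residues
                    type_id.extend([-1] * L)
                    registry.extend([0] * L)
                    coil_len.extend([0] * L)
                    coil_seg.extend([-1] * L)
                    bead += L
            for a in range(offset, offset + n - 1):
                bonds.append((a, a + 1))
            offset += n
            chain += 1
            chain_start.append(offset)

    return SystemTopology(
        chain_id=np.asarray(chain_id, dtype=np.int32),
        type_id=np.asarray(type_id, dtype=np.int32),
        registry=np.asarray(registry, dtype=np.int32),
        coil_len=np.asarray(coil_len, dtype=np.int32),
        coil_seg=np.asarray(coil_seg, dtype=np.int32),
        seg_start=np.asarray(seg_start, dtype=np.int32),
        seg_len=np.asarray(seg_len, dtype=np.int32),
        seg_chain=np.asarray(seg_chain, dtype=np.int32),
        seg_type=np.asarray(seg_type, dtype=np.int32),
        bonds=np.asarray(bonds, dtype=np.int32).reshape(-1, 2),
        angles=(
            np.asarray(angles, dtype=np.int32).reshape(-1, 3)
            if angles
            else np.zeros((0, 3), dtype=np.int32)
        ),
        masses=np.full(offset, BEAD_MASS_AMU, dtype=np.float64),
        chain_construct=chain_construct,
        chain_start=np.asarray(chain_start, dtype=np.int64),
    )
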