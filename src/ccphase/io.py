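"""Trajectory and topology serialization.

Trajectories go to extended XYZ (one block per frame; the comment line
carries ``Lattice=...`` and ``Time=...``), topologies to JSON keyed by the
construct strings, which the library can rebuild exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ccphase.constructs import parse_construct
from ccphase.engine import Trajectory
from ccphase.topology import SystemTopology, build_system_topology

__all__ = ["write_xyz", "read_xyz", "save_topology", "load_topology"]


def write_xyz(path, traj: Trajectory) -> None:
    """Write all frames as extended XYZ (species = segment type name)."""
    top = traj.topology
    labels = []
    for cls, nm, reg in zip(
        (("coil" if t >= 0 else "linker") for t in top.type_id),
        _bead_names(top),
        top.registry,
    ):
        labels.append(nm)
    n = top.n_beads
    bx, by, bz = traj.box
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(
                f'Lattice="{bx:.8g} 0 0 0 {by:.8g} 0 0 0 {bz:.8g}" '
                f"Time={traj.times[f]:.8g} "
                f'Properties=species:S:1:pos:R:3\n'
            )
            for i in range(n):
                x, y, z = traj.frames[f, i]
                fh.write(f"{labels[i]} {x:.8f} {y:.8f} {z:.8f}\n")


def _bead_names(top: SystemTopology):
    from ccphase.topology import COIL_TYPE_NAMES

    out = []
    bead = 0
    for c, spec in enumerate(top.chain_construct):
        for cls, nm in spec.segments:
            from ccphase.constructs import COIL_LIBRARY, LINKER_LIBRARY

            L = COIL_LIBRARY[nm].residues if cls == "coil" else LINKER_LIBRARY[nm].residues
            out.extend([nm] * L)
            bead += L
    return out


def read_xyz(path, topology: SystemTopology) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`."""
    frames, times = [], []
    box = None
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            n = int(line.strip())
            comment = fh.readline()
            lat = comment.split('Lattice="')[1].split('"')[0].split()
            box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
            t = float(comment.split("Time=")[1].split()[0])
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append(pos)
            times.append(t)
    return Trajectory(
        frames=np.array(frames),
        times=np.array(times),
        kinetic_temperature=np.full(len(times), np.nan),
        box=box,
        topology=topology,
        metadata={"source": str(path)},
    )


def save_topology(path, topology: SystemTopology) -> None:
    Path(path).write_text(topology.to_json())


def load_topology(path) -> SystemTopology:
    """Rebuild a topology from its JSON export (constructs are re-parsed)."""
    data = json.loads(Path(path).read_text())
    components = [(parse_construct(name), 1) for name in data["constructs"]]
    top = build_system_topology(components)
    if top.n_beads != len(data["chain_id"]):
        raise ValueError("topology JSON inconsistent with construct library")
    return top
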