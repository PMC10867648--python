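"""Plain-text trajectory I/O in a LAMMPS-dump-compatible dialect.

Frames are stored as::

    ITEM: TIMESTEP
    <t>
    ITEM: NUMBER OF ATOMS
    <n>
    ITEM: BOX BOUNDS pp pp pp
    <xlo> <xhi>
    <ylo> <yhi>
    <zlo> <zhi>
    ITEM: ATOMS id mol x y z
    <id> <mol> <x> <y> <z>

``mol`` is the 1-based chain index; beads are ordered along the backbone by
id.  Externally produced dumps in the same dialect can be read back.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .circuit_topology import ChainSystem
from .polymer_sim import Trajectory

__all__ = ["write_dump", "read_dump"]


def write_dump(path: str | Path, traj: Trajectory | ChainSystem) -> None:
    """Write a trajectory (or a single conformation) to a dump file."""
    if isinstance(traj, ChainSystem):
        traj = Trajectory([traj], [0.0])
    with open(path, "w") as fh:
        for system, t in zip(traj.frames, traj.times):
            _write_frame(fh, system, t)


def _write_frame(fh, system: ChainSystem, t: float) -> None:
    n = system.n_beads
    fh.write("ITEM: TIMESTEP\n")
    fh.write(f"{t:.10g}\n")
    fh.write("ITEM: NUMBER OF ATOMS\n")
    fh.write(f"{n}\n")
    if system.box is not None:
        fh.write("ITEM: BOX BOUNDS pp pp pp\n")
        for k in range(3):
            fh.write(f"0 {system.box[k]:.10g}\n")
    else:
        fh.write("ITEM: BOX BOUNDS ff ff ff\n")
        pos = np.concatenate(system.chains)
        for k in range(3):
            fh.write(f"{pos[:, k].min():.10g} {pos[:, k].max():.10g}\n")
    fh.write("ITEM: ATOMS id mol x y z\n")
    bead_id = 1
    for mol, chain in enumerate(system.chains, start=1):
        for r in chain:
            fh.write(f"{bead_id} {mol} {r[0]:.10g} {r[1]:.10g} {r[2]:.10g}\n")
            bead_id += 1


def read_dump(path: str | Path) -> Trajectory:
    """Read every frame of a dump file."""
    frames: list[ChainSystem] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        t = float(lines[i + 1])
        assert lines[i + 2].startswith("ITEM: NUMBER OF ATOMS")
        n = int(lines[i + 3])
        assert lines[i + 4].startswith("ITEM: BOX BOUNDS")
        periodic = "pp" in lines[i + 4]
        bounds = [tuple(map(float, lines[i + 5 + k].split())) for k in range(3)]
        header = lines[i + 8].split()
        assert header[:2] == ["ITEM:", "ATOMS"]
        cols = header[2:]
        idx = {name: cols.index(name) for name in ("id", "mol", "x", "y", "z")}
        rows = []
        for k in range(n):
            parts = lines[i + 9 + k].split()
            rows.append(
                (
                    int(parts[idx["id"]]),
                    int(parts[idx["mol"]]),
                    float(parts[idx["x"]]),
                    float(parts[idx["y"]]),
                    float(parts[idx["z"]]),
                )
            )
        rows.sort()
        chains: dict[int, list[list[float]]] = {}
        for _id, mol, x, y, z in rows:
            chains.setdefault(mol, []).append([x, y, z])
        box = (
            np.array([hi - lo for lo, hi in bounds]) if periodic else None
        )
        frames.append(
            ChainSystem(
                [np.array(chains[mol]) for mol in sorted(chains)], box=box
            )
        )
        times.append(t)
        i += 9 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(frames, times)
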