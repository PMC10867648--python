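"""Structural order parameters of multichain conformations.

Two scalars track the amorphous-to-bundle transition: the mass-weighted
radius of gyration of the whole aggregate,

    Rg^2 = (1/M_tot) sum_i m_i |r_i - r_CM|^2,

normalized by the ideal random-walk value Rg_theta = b sqrt((N-1)/6), and the
end-to-end orientation correlation

    CR = 2/(M(M-1)) sum_{i<j} (R^_i . R^_j)^2,

which is 1/3 for uncorrelated chain orientations and 1 for an aligned
bundle (a nematic-like order parameter; squaring makes it head-tail
symmetric).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .circuit_topology import ChainSystem

__all__ = [
    "ObservablesRecord",
    "DEFAULT_BOND_LENGTH",
    "unwrap_chains",
    "radius_of_gyration",
    "rg_normalized",
    "end_to_end_correlation",
    "measure",
]

#: equilibrium backbone bond length of the bead-spring chains (sigma)
DEFAULT_BOND_LENGTH = 0.965


@dataclass(frozen=True)
class ObservablesRecord:
    Rg: float
    Rg_tilde: float
    CR: float
    b: float
    Rg_theta: float


def unwrap_chains(system: ChainSystem) -> ChainSystem:
    """Undo periodic wrapping along each backbone (bond-by-bond walk)."""
    if system.box is None:
        return system
    chains = []
    for c in system.chains:
        out = c.copy()
        for i in range(1, len(out)):
            d = out[i] - out[i - 1]
            d -= system.box * np.round(d / system.box)
            out[i] = out[i - 1] + d
        chains.append(out)
    return ChainSystem(chains, [m.copy() for m in system.masses], box=None)


def radius_of_gyration(system: ChainSystem) -> float:
    """Mass-weighted Rg of all beads about the global centre of mass."""
    system = unwrap_chains(system)
    pos = np.concatenate(system.chains, axis=0)
    mass = np.concatenate(system.masses)
    total = mass.sum()
    com = (mass[:, None] * pos).sum(axis=0) / total
    return float(np.sqrt((mass * ((pos - com) ** 2).sum(axis=1)).sum() / total))


def rg_normalized(Rg: float, N: int, b: float = DEFAULT_BOND_LENGTH) -> float:
    """Rg over the entropic random-walk radius b*sqrt((N-1)/6)."""
    if N < 2:
        raise ValueError("need at least 2 beads per chain")
    if b <= 0:
        raise ValueError("bond length must be positive")
    return Rg / (b * np.sqrt((N - 1) / 6.0))


def end_to_end_correlation(system: ChainSystem) -> float:
    """Mean squared cosine between chain end-to-end directions."""
    system = unwrap_chains(system)
    if system.n_chains < 2:
        raise ValueError("need at least 2 chains")
    units = []
    for c in system.chains:
        v = c[-1] - c[0]
        norm = np.linalg.norm(v)
        if norm == 0.0:
            warnings.warn("chain with zero end-to-end vector excluded from CR")
            continue
        units.append(v / norm)
    if len(units) < 2:
        raise ValueError("fewer than 2 chains with nonzero end-to-end vectors")
    M = len(units)
    acc = 0.0
    for u, v in itertools.combinations(units, 2):
        acc += float(np.dot(u, v)) ** 2
    return 2.0 * acc / (M * (M - 1))


def measure(system: ChainSystem, b: float = DEFAULT_BOND_LENGTH) -> ObservablesRecord:
    """Rg, normalized Rg and CR for one conformation."""
    N = len(system.chains[0])
    Rg = radius_of_gyration(system)
    return ObservablesRecord(
        Rg=Rg,
        Rg_tilde=rg_normalized(Rg, N, b),
        CR=end_to_end_correlation(system),
        b=b,
        Rg_theta=b * float(np.sqrt((N - 1) / 6.0)),
    )
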