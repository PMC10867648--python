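"""Primitive path analysis: contour contraction with fixed chain ends.

Chain ends are pinned, all intrachain interactions except the FENE backbone
springs are switched off, and interchain excluded volume (a purely repulsive
truncated LJ/WCA pair term) is kept so strands cannot pass through each
other.  Energy minimization then contracts each chain onto its primitive
path: straight segments between entanglement points.

The minimizer is damped steepest descent with a hard cap on the displacement
per step; the cap (well below the bead diameter) is what guarantees no
strand passage during the contraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit_topology import ChainSystem

__all__ = ["PPAConfig", "PPAResult", "primitive_paths"]


@dataclass(frozen=True)
class PPAConfig:
    fene_K: float = 30.0
    fene_R0: float = 1.5
    wca_epsilon: float = 1.0
    #: force tolerance: converged when the max bead force is below this
    force_tol: float = 1e-4
    max_iterations: int = 100_000
    #: displacement cap per step (sigma); the no-crossing guarantee
    max_step: float = 0.01


@dataclass
class PPAResult:
    system: ChainSystem
    converged: bool
    iterations: int
    max_force: float


def _ppa_forces(pos: np.ndarray, sizes: list[int], box: np.ndarray | None,
                cfg: PPAConfig, pairs: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    F = np.zeros_like(pos)
    # FENE backbone (intrachain; the only intrachain term)
    offset = 0
    R02 = cfg.fene_R0**2
    for n in sizes:
        i = np.arange(offset, offset + n - 1)
        j = i + 1
        d = pos[j] - pos[i]
        if box is not None:
            d -= box * np.round(d / box)
        r2 = np.einsum("ij,ij->i", d, d)
        x = np.clip(r2 / R02, 0.0, 0.999999)
        fb = -cfg.fene_K / (1.0 - x)
        fvec = fb[:, None] * d
        np.add.at(F, j, fvec)
        np.add.at(F, i, -fvec)
        offset += n
    # interchain WCA (repulsive-only, cutoff 2^(1/6) sigma)
    ii, jj = pairs
    if len(ii):
        d = pos[jj] - pos[ii]
        if box is not None:
            d -= box * np.round(d / box)
        r2 = np.einsum("ij,ij->i", d, d)
        rc2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2
        mask = r2 < rc2
        if mask.any():
            d_c = d[mask]
            inv2 = 1.0 / r2[mask]
            sr6 = inv2**3
            fmag = 24.0 * cfg.wca_epsilon * (2.0 * sr6**2 - sr6) * inv2
            fvec = fmag[:, None] * d_c
            np.add.at(F, jj[mask], fvec)
            np.add.at(F, ii[mask], -fvec)
    return F


def primitive_paths(system: ChainSystem, config: PPAConfig = PPAConfig()) -> PPAResult:
    """Contract the chain contours onto their primitive paths.

    Endpoints are bitwise unchanged; each accepted step moves no bead more
    than ``max_step``.  Returns the best iterate with ``converged=False`` if
    the force tolerance is not reached within ``max_iterations``.
    """
    sizes = [len(c) for c in system.chains]
    splits = np.cumsum(sizes)[:-1]
    pos = np.concatenate(system.chains).astype(float)
    box = system.box

    # endpoint mask
    fixed = np.zeros(len(pos), dtype=bool)
    offset = 0
    for n in sizes:
        fixed[offset] = True
        fixed[offset + n - 1] = True
        offset += n

    # interchain pair list
    ids = np.concatenate([np.full(n, k) for k, n in enumerate(sizes)])
    ii, jj = np.triu_indices(len(pos), k=1)
    inter = ids[ii] != ids[jj]
    pairs = (ii[inter], jj[inter])

    gamma = 0.002  # descent step scale (sigma^2/eps)
    max_force = np.inf
    it = 0
    for it in range(1, config.max_iterations + 1):
        F = _ppa_forces(pos, sizes, box, config, pairs)
        F[fixed] = 0.0
        max_force = float(np.sqrt((F**2).sum(axis=1)).max())
        if max_force < config.force_tol:
            break
        step = gamma * F
        norms = np.sqrt((step**2).sum(axis=1))
        big = norms > config.max_step
        if big.any():
            step[big] *= (config.max_step / norms[big])[:, None]
        pos += step

    chains = list(np.split(pos, splits))
    out = ChainSystem(chains, [m.copy() for m in system.masses],
                      None if box is None else box.copy())
    return PPAResult(
        system=out,
        converged=max_force < config.force_tol,
        iterations=it,
        max_force=max_force,
    )
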