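"""Minimal Kremer--Grest bead-spring simulator (LJ + FENE + bending, NVT).

Reduced units throughout: monomer mass m, bead diameter sigma and cohesive
strength epsilon set to 1, so the time unit is tau = sigma*sqrt(m/eps) and
temperature is in eps/kB.  The model:

* full Lennard-Jones between all bead pairs (cutoff 2.5 sigma, potential
  shifted to zero at the cutoff) -- the attractive tail drives aggregation;
* FENE backbone springs, U = -K R0^2/2 ln(1 - (r/R0)^2), with the standard
  K = 30 eps/sigma^2, R0 = 1.5 sigma.  Together with the LJ repulsion this
  puts the mean bond length near 0.965 sigma at T = 1;
* bending energy kappa*kB*T*(1 - cos theta) per successive bond pair, with
  kappa the stiffness that drives the amorphous -> bundle transition;
* Langevin thermostat integrated with the BAOAB splitting (one force
  evaluation per step); with the thermostat off the scheme reduces to plain
  velocity Verlet (NVE) for conservation checks.

Δt = 0.01 tau by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit_topology import ChainSystem

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "FENEViolation",
    "init_system",
    "potential_energy",
    "forces",
    "run_nvt",
    "bond_lengths",
    "kinetic_energy_per_bead",
]


class FENEViolation(RuntimeError):
    """A backbone bond reached the FENE divergence radius (timestep too large)."""


@dataclass(frozen=True)
class SimulationConfig:
    M: int = 4
    N: int = 10
    T: float = 1.0
    rho: float = 0.01
    kappa: float = 0.0
    dt: float = 0.01
    steps: int = 10_000
    seed: int = 0
    lj_epsilon: float = 1.0
    lj_cutoff: float = 2.5
    fene_K: float = 30.0
    fene_R0: float = 1.5
    langevin_damping: float = 1.0
    frame_stride: int = 1_000
    thermostat: bool = True

    def __post_init__(self):
        if self.dt <= 0 or self.rho <= 0 or self.kappa < 0:
            raise ValueError("invalid simulation parameters")

    @property
    def box_side(self) -> float:
        return (self.M * self.N / self.rho) ** (1.0 / 3.0)


@dataclass
class Trajectory:
    """Time-ordered conformations with timestamps (tau units)."""

    frames: list[ChainSystem]
    times: list[float]

    def __len__(self) -> int:
        return len(self.frames)


# -- initial conformation ----------------------------------------------------


def init_system(config: SimulationConfig, max_retries: int = 200) -> ChainSystem:
    """Non-overlapping self-avoiding random-walk chains in the periodic box.

    Bond length 0.97 sigma; no bead pair closer than 0.9 sigma (minimum
    image).  Deterministic for a given seed; the stiffness plays no role at
    initialization.
    """
    rng = np.random.default_rng(config.seed)
    L = config.box_side
    box = np.array([L, L, L])

    def too_close(p: np.ndarray, others: np.ndarray) -> bool:
        if len(others) == 0:
            return False
        d = others - p
        d -= box * np.round(d / box)
        return bool((np.einsum("ij,ij->i", d, d) < 0.9**2).any())

    chains: list[np.ndarray] = []
    for _ in range(config.M):
        for _attempt in range(max_retries):
            start = rng.uniform(0, L, size=3)
            pts = [start]
            if chains and too_close(start, np.concatenate(chains)):
                continue
            ok = True
            for _ in range(config.N - 1):
                grown = False
                for _try in range(60):
                    v = rng.normal(size=3)
                    v *= 0.97 / np.linalg.norm(v)
                    cand = pts[-1] + v
                    obstacles = [np.array(pts[:-1])] if len(pts) > 1 else []
                    if chains:
                        obstacles.append(np.concatenate(chains))
                    obs = (
                        np.concatenate(obstacles)
                        if obstacles
                        else np.empty((0, 3))
                    )
                    if not too_close(cand, obs):
                        pts.append(cand)
                        grown = True
                        break
                if not grown:
                    ok = False
                    break
            if ok:
                chains.append(np.array(pts))
                break
        else:
            raise RuntimeError(
                "chain placement failed; density too high for SAW insertion"
            )
    return ChainSystem(chains, box=box)


# -- energies and forces -----------------------------------------------------


def _pair_indices(n_beads_per_chain: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(i, j) arrays of all bead pairs, plus bond pair arrays."""
    total = sum(n_beads_per_chain)
    ii, jj = np.triu_indices(total, k=1)
    bonds_i, bonds_j = [], []
    offset = 0
    for n in n_beads_per_chain:
        bonds_i.extend(range(offset, offset + n - 1))
        bonds_j.extend(range(offset + 1, offset + n))
        offset += n
    return ii, jj, np.array(bonds_i), np.array(bonds_j)


def _lj_shift(config: SimulationConfig) -> float:
    sr6 = (1.0 / config.lj_cutoff) ** 6
    return 4.0 * config.lj_epsilon * (sr6**2 - sr6)


def _compute(pos: np.ndarray, sizes: list[int], box: np.ndarray | None,
             config: SimulationConfig, cache: dict) -> tuple[float, float, float, np.ndarray]:
    """Potential energies (lj, fene, bend) and total forces."""
    key = tuple(sizes)
    if cache.get("key") != key:
        cache["key"] = key
        cache["pairs"] = _pair_indices(sizes)
        cache["shift"] = _lj_shift(config)
    ii, jj, bi, bj = cache["pairs"]
    F = np.zeros_like(pos)

    # Lennard-Jones, all pairs within cutoff, shifted
    d = pos[jj] - pos[ii]
    if box is not None:
        d -= box * np.round(d / box)
    r2 = np.einsum("ij,ij->i", d, d)
    mask = r2 < config.lj_cutoff**2
    d_c = d[mask]
    r2_c = r2[mask]
    inv2 = 1.0 / r2_c
    sr6 = inv2**3
    sr12 = sr6**2
    e_lj = float(np.sum(4.0 * config.lj_epsilon * (sr12 - sr6) - cache["shift"]))
    # f = 24 eps (2 sr12 - sr6) / r^2 * d  (force on j)
    fmag = 24.0 * config.lj_epsilon * (2.0 * sr12 - sr6) * inv2
    fvec = fmag[:, None] * d_c
    np.add.at(F, jj[mask], fvec)
    np.add.at(F, ii[mask], -fvec)

    # FENE bonds
    db = pos[bj] - pos[bi]
    if box is not None:
        db -= box * np.round(db / box)
    rb2 = np.einsum("ij,ij->i", db, db)
    R02 = config.fene_R0**2
    if np.any(rb2 >= R02):
        raise FENEViolation("bond extension reached R0")
    x = rb2 / R02
    e_fene = float(np.sum(-0.5 * config.fene_K * R02 * np.log1p(-x)))
    fb = -config.fene_K / (1.0 - x)  # dU/dr / r, force on j is fb*db... sign below
    fvec = fb[:, None] * db
    np.add.at(F, bj, fvec)
    np.add.at(F, bi, -fvec)

    # bending: kappa kB T (1 - cos theta) per successive bond pair
    e_bend = 0.0
    if config.kappa > 0.0:
        if "angles" not in cache:
            # triplet index arrays across all chains
            a0, a1, a2 = [], [], []
            offset = 0
            for n in sizes:
                if n >= 3:
                    a0.extend(range(offset, offset + n - 2))
                    a1.extend(range(offset + 1, offset + n - 1))
                    a2.extend(range(offset + 2, offset + n))
                offset += n
            cache["angles"] = (np.array(a0), np.array(a1), np.array(a2))
        a0, a1, a2 = cache["angles"]
        if len(a0):
            k = config.kappa * config.T
            b1 = pos[a1] - pos[a0]
            b2 = pos[a2] - pos[a1]
            if box is not None:
                b1 -= box * np.round(b1 / box)
                b2 -= box * np.round(b2 / box)
            n1 = np.sqrt(np.einsum("ij,ij->i", b1, b1))
            n2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
            cos = np.clip(np.einsum("ij,ij->i", b1, b2) / (n1 * n2), -1.0, 1.0)
            e_bend = float(np.sum(k * (1.0 - cos)))
            # dU/dcos = -k; gradient of cos wrt the three beads
            g1 = (b2 / (n1 * n2)[:, None]) - (cos / (n1**2))[:, None] * b1
            g2 = (b1 / (n1 * n2)[:, None]) - (cos / (n2**2))[:, None] * b2
            F0 = -k * g1
            F2 = k * g2
            F1 = -(F0 + F2)
            np.add.at(F, a0, F0)
            np.add.at(F, a1, F1)
            np.add.at(F, a2, F2)
    return e_lj, e_fene, e_bend, F


def potential_energy(system: ChainSystem, config: SimulationConfig) -> tuple[float, float, float]:
    """(LJ, FENE, bending) energies of a conformation."""
    pos = np.concatenate(system.chains)
    sizes = [len(c) for c in system.chains]
    e_lj, e_fene, e_bend, _ = _compute(pos, sizes, system.box, config, {})
    return e_lj, e_fene, e_bend


def forces(system: ChainSystem, config: SimulationConfig) -> np.ndarray:
    pos = np.concatenate(system.chains)
    sizes = [len(c) for c in system.chains]
    return _compute(pos, sizes, system.box, config, {})[3]


def bond_lengths(system: ChainSystem) -> np.ndarray:
    """All backbone bond lengths (minimum image)."""
    out = []
    for c in system.chains:
        d = np.diff(c, axis=0)
        if system.box is not None:
            d -= system.box * np.round(d / system.box)
        out.append(np.linalg.norm(d, axis=1))
    return np.concatenate(out)


def kinetic_energy_per_bead(vel: np.ndarray) -> float:
    return float(0.5 * np.mean(np.einsum("ij,ij->i", vel, vel)))


# -- integration -------------------------------------------------------------


def run_nvt(
    system: ChainSystem,
    config: SimulationConfig,
    velocities: np.ndarray | None = None,
    collect_bonds: bool = False,
) -> Trajectory:
    """BAOAB Langevin dynamics (velocity Verlet when the thermostat is off).

    Frames (deep copies, chain-split, with the box) are emitted every
    ``frame_stride`` steps and at the final step.  Deterministic for a given
    seed.  Raises :class:`FENEViolation` with a diagnostic if a bond reaches
    the FENE bound.
    """
    sizes = [len(c) for c in system.chains]
    splits = np.cumsum(sizes)[:-1]
    pos = np.concatenate(system.chains).astype(float)
    box = system.box
    rng = np.random.default_rng(config.seed + 1)
    if velocities is None:
        vel = rng.normal(scale=math.sqrt(config.T), size=pos.shape)
        vel -= vel.mean(axis=0)
    else:
        vel = velocities.astype(float).copy()

    cache: dict = {}
    gamma = 1.0 / config.langevin_damping
    c1 = math.exp(-gamma * config.dt)
    c2 = math.sqrt(max(0.0, (1.0 - c1 * c1) * config.T))

    def snapshot() -> ChainSystem:
        chains = np.split(pos.copy(), splits)
        return ChainSystem(list(chains), [m.copy() for m in system.masses],
                           None if box is None else box.copy())

    frames = [snapshot()]
    times = [0.0]
    bond_samples: list[np.ndarray] = []
    ke_samples: list[float] = []

    try:
        _, _, _, F = _compute(pos, sizes, box, config, cache)
    except FENEViolation as err:
        raise FENEViolation(f"initial conformation invalid: {err}") from err

    half = 0.5 * config.dt
    for step in range(1, config.steps + 1):
        vel += half * F
        pos += half * vel
        if config.thermostat:
            vel = c1 * vel + c2 * rng.normal(size=vel.shape)
        pos += half * vel
        try:
            _, _, _, F = _compute(pos, sizes, box, config, cache)
        except FENEViolation as err:
            raise FENEViolation(
                f"bond blew past R0 at step {step} (t={step*config.dt:.2f} tau); "
                "reduce dt or check the initial conformation"
            ) from err
        vel += half * F
        if collect_bonds and step % 10 == 0:
            snap = snapshot()
            bond_samples.append(bond_lengths(snap))
            ke_samples.append(kinetic_energy_per_bead(vel))
        if step % config.frame_stride == 0 or step == config.steps:
            frames.append(snapshot())
            times.append(step * config.dt)

    traj = Trajectory(frames, times)
    if collect_bonds:
        traj.bond_samples = bond_samples  # type: ignore[attr-defined]
        traj.ke_samples = ke_samples  # type: ignore[attr-defined]
    traj.final_velocities = vel  # type: ignore[attr-defined]
    return traj
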