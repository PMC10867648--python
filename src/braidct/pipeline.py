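"""Orchestration: simulate -> equilibrate -> PPA -> contacts/CT -> braid.

The stiffness sweep drives the full analysis across a kappa grid with
replicated, independently seeded runs and returns a tidy per-replica table
plus ensemble means.  Replica counts and equilibration durations are
desk-scale by default and scale up through the config.

Equilibration uses a sliding-window stationarity criterion on the rescaled
radius of gyration and the end-to-end correlation CR rather than a fixed
duration: the run proceeds in chunks until consecutive window means agree
within tolerance (or a hard time cap is hit).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .braid_algebra import BraidWord, compute_invariants
from .braid_extraction import extract_braid, find_projection_frame
from .circuit_topology import (
    ChainSystem,
    Contact,
    ContactConfig,
    MOTIF_LABELS,
    motif_fractions,
)
from .observables import measure, unwrap_chains
from .polymer_sim import SimulationConfig, Trajectory, init_system, run_nvt
from .ppa import PPAConfig, primitive_paths

logger = logging.getLogger("braidct")

__all__ = [
    "EquilibrationConfig",
    "equilibrate",
    "analyze_conformation",
    "run_replica",
    "run_sweep",
    "braided_string",
    "parse_braided_string",
]


@dataclass(frozen=True)
class EquilibrationConfig:
    """Stationarity-based equilibration schedule (times in tau)."""

    chunk_tau: float = 100.0
    min_chunks: int = 4
    max_tau: float = 2000.0
    cr_tol: float = 0.05
    rg_tol: float = 0.08
    sample_tau: float = 100.0  # extra sampling after stationarity


def _config_hash(*objs) -> str:
    text = "|".join(repr(o) for o in objs)
    return hashlib.md5(text.encode()).hexdigest()[:10]


def equilibrate(
    config: SimulationConfig,
    equil: EquilibrationConfig = EquilibrationConfig(),
    system: ChainSystem | None = None,
) -> tuple[ChainSystem, np.ndarray]:
    """Run NVT dynamics until R~g and CR are stationary.

    Returns the final conformation and velocities.  Stationarity: the means
    of CR and R~g over the last two chunks agree within tolerance after at
    least ``min_chunks`` chunks; a hard cap at ``max_tau`` bounds the run.
    """
    if system is None:
        system = init_system(config)
    chunk_steps = max(1, int(round(equil.chunk_tau / config.dt)))
    vel = None
    window: list[tuple[float, float]] = []
    t = 0.0
    chunk_idx = 0
    while t < equil.max_tau:
        cfg = replace(
            config,
            steps=chunk_steps,
            seed=config.seed + 7919 * chunk_idx,
            frame_stride=chunk_steps,
        )
        traj = run_nvt(system, cfg, velocities=vel)
        system = traj.frames[-1]
        vel = traj.final_velocities
        rec = measure(system)
        window.append((rec.Rg_tilde, rec.CR))
        t += equil.chunk_tau
        chunk_idx += 1
        if len(window) >= equil.min_chunks:
            (rg0, cr0), (rg1, cr1) = window[-2], window[-1]
            if abs(rg1 - rg0) < equil.rg_tol and abs(cr1 - cr0) < equil.cr_tol:
                break
    return system, vel


def analyze_conformation(
    system: ChainSystem,
    contact_config: ContactConfig = ContactConfig(),
    ppa_config: PPAConfig = PPAConfig(),
    log_base: float = 3.0,
    run_ppa: bool = True,
) -> dict:
    """Observables, motif census and braid invariants of one conformation."""
    system = unwrap_chains(system)
    rec = measure(system)
    census = motif_fractions(system, contact_config)
    if run_ppa:
        ppa_res = primitive_paths(system, ppa_config)
        reduced = ppa_res.system
        ppa_converged = ppa_res.converged
    else:
        reduced = system
        ppa_converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        word = extract_braid(reduced)
    inv = compute_invariants(word, log_base=log_base)
    out = {
        "Rg": rec.Rg,
        "Rg_tilde": rec.Rg_tilde,
        "CR": rec.CR,
        "n_contacts": census.n_contacts,
        "n_pairs": census.n_pairs,
        "n_pairs_skipped": census.n_pairs_skipped,
        "interchain_sum": census.interchain_sum(),
        "writhe": inv.writhe,
        "length": inv.minimal_length,
        "complexity": inv.complexity,
        "tn_class": inv.isotopy_class,
        "ppa_converged": ppa_converged,
        "raw_word": word.to_string(),
    }
    for label in MOTIF_LABELS:
        out[label] = census.fractions[label]
    return out


def run_replica(
    config: SimulationConfig,
    contact_config: ContactConfig = ContactConfig(),
    equil: EquilibrationConfig = EquilibrationConfig(),
    ppa_config: PPAConfig = PPAConfig(),
    log_base: float = 3.0,
    sample_frames: int = 5,
) -> dict:
    """One seeded end-to-end run.

    After stationarity, observables and motif fractions are time-averaged
    over ``sample_frames`` frames spanning ``sample_tau`` (frames with fewer
    than two contacts carry no motif census and are excluded from the
    fraction averages); the braid analysis runs on the final frame.
    """
    system, vel = equilibrate(config, equil)
    frames = [system]
    if equil.sample_tau > 0 and sample_frames > 0:
        steps = max(sample_frames, int(round(equil.sample_tau / config.dt)))
        cfg = replace(config, steps=steps, seed=config.seed + 104729,
                      frame_stride=max(1, steps // sample_frames))
        traj = run_nvt(system, cfg, velocities=vel)
        frames = traj.frames[1:]
        system = frames[-1]

    recs = [measure(unwrap_chains(f)) for f in frames]
    censuses = [motif_fractions(unwrap_chains(f), contact_config) for f in frames]
    ok = [c for c in censuses if c.ok]
    out = analyze_conformation(system, contact_config, ppa_config, log_base)
    out["Rg"] = float(np.mean([r.Rg for r in recs]))
    out["Rg_tilde"] = float(np.mean([r.Rg_tilde for r in recs]))
    out["CR"] = float(np.mean([r.CR for r in recs]))
    out["n_contacts"] = float(np.mean([c.n_contacts for c in censuses]))
    out["n_census_frames"] = len(ok)
    if ok:
        for label in MOTIF_LABELS:
            out[label] = float(np.mean([c.fractions[label] for c in ok]))
        out["interchain_sum"] = float(np.mean([c.interchain_sum() for c in ok]))
    else:
        for label in MOTIF_LABELS:
            out[label] = float("nan")
        out["interchain_sum"] = float("nan")
    out.update(kappa=config.kappa, seed=config.seed)
    return out


def run_sweep(
    kappas,
    replicas: int = 20,
    base_config: SimulationConfig = SimulationConfig(),
    contact_config: ContactConfig = ContactConfig(),
    equil: EquilibrationConfig = EquilibrationConfig(),
    seed: int = 0,
    log_base: float = 3.0,
) -> pd.DataFrame:
    """Stiffness sweep: per-(kappa, replica) records, reproducible from seed.

    Replica seeds derive deterministically from ``seed``; failed replicas
    (e.g. FENE blowups) are logged and excluded, with the count carried in
    the ``failed`` attribute of the returned frame.
    """
    rows = []
    failed = 0
    chash = _config_hash(base_config, contact_config, equil, seed)
    for kappa in kappas:
        for rep in range(replicas):
            rep_seed = (seed * 1_000_003 + int(round(kappa * 10)) * 1013 + rep) % (2**31)
            cfg = replace(base_config, kappa=float(kappa), seed=rep_seed)
            try:
                row = run_replica(cfg, contact_config, equil, log_base=log_base)
            except Exception as err:  # noqa: BLE001 - replica isolation
                logger.warning("replica kappa=%s rep=%d failed: %s", kappa, rep, err)
                failed += 1
                continue
            row.update(replica=rep, config_hash=chash)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["failed"] = failed
    df.attrs["config_hash"] = chash
    return df


def sweep_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Ensemble means and standard deviations per kappa."""
    cols = ["Rg_tilde", "CR", "interchain_sum", "writhe", "length",
            "complexity"] + list(MOTIF_LABELS)
    g = df.groupby("kappa")[cols]
    mean = g.mean().add_suffix("_mean")
    std = g.std(ddof=1).add_suffix("_std")
    return mean.join(std).reset_index()


# -- combined CT + braid string ----------------------------------------------


def braided_string(
    system: ChainSystem,
    contacts: list[Contact],
    word: BraidWord | None = None,
) -> str:
    """Serialize contacts and crossings into one token stream.

    Contact levels (n-tuples over {A, B, ..., O}, one character per strand
    column ordered by x' at the bottom plane) and braid operators (signed
    integers) are interleaved in slicing order along z'.  If ``word`` is
    given it must match the extracted crossing sequence.
    """
    system = unwrap_chains(system)
    frame = find_projection_frame(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        extracted, zpos = extract_braid(system, frame, with_positions=True)
    if word is not None and tuple(word.letters) != tuple(extracted.letters):
        raise ValueError("given word is inconsistent with the conformation")
    M = system.n_chains
    # strand columns: chains ordered by x' of their lower endpoint
    chains_f = [frame.to_frame(c) for c in system.chains]
    low_x = []
    for cf in chains_f:
        low = cf[0] if cf[0, 2] <= cf[-1, 2] else cf[-1]
        low_x.append(low[0])
    column = {chain: col for col, chain in enumerate(np.argsort(low_x))}

    if len(contacts) > 24:
        raise ValueError("too many contacts for letter serialization")
    events: list[tuple[float, int, str]] = []  # (z, order, token)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    # name contacts in order of their lowest site z'
    def site_z(site):
        ch, bead = site
        return float(chains_f[ch][bead, 2])

    ordered = sorted(contacts, key=lambda c: min(site_z(s) for s in c.sites))
    for letter, contact in zip(letters, ordered):
        if contact.intrachain:
            for site in contact.sites:
                row = ["O"] * M
                row[column[site[0]]] = letter
                events.append((site_z(site), 0, "".join(row)))
        else:
            z = float(np.mean([site_z(s) for s in contact.sites]))
            row = ["O"] * M
            for site in contact.sites:
                row[column[site[0]]] = letter
            events.append((z, 0, "".join(row)))
    for k, z in zip(extracted.letters, zpos):
        events.append((float(z), 1, str(k)))
    events.sort(key=lambda e: (e[0], e[1]))
    return " ".join(tok for _, _, tok in events)


def parse_braided_string(text: str) -> tuple[list[str], tuple[int, ...]]:
    """Split a combined string back into contact levels and braid letters."""
    levels: list[str] = []
    letters: list[int] = []
    for tok in text.split():
        if tok.lstrip("+-").isdigit():
            letters.append(int(tok))
        else:
            if set(tok) - set("ABCDEFGHIJKLMNOPQRSTUVWXYZO"):
                raise ValueError(f"bad token {tok!r}")
            levels.append(tok)
    return levels, tuple(letters)
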