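"""Deterministic conformation generators with known topological ground truth.

Every stage of the pipeline is testable without external data:

* :func:`make_braided_bundle` realizes a prescribed braid word as smooth
  strand exchanges between two parallel anchor planes;
* :func:`make_motif_system` builds a bead arrangement whose two detected
  contacts classify into a requested circuit-topology motif;
* :func:`make_random_walks` draws ideal freely-jointed chains.
"""

from __future__ import annotations

import numpy as np

from .braid_algebra import BraidWord
from .circuit_topology import ChainSystem, Contact, MotifClass

__all__ = ["make_braided_bundle", "make_motif_system", "make_random_walks"]

#: lateral spacing between bundle strands (sigma)
_SPACING = 1.5
#: front/back excursion of exchanging strands (sigma); makes over/under
#: unambiguous in projection
_DEPTH = 0.5


def _easing(t: np.ndarray) -> np.ndarray:
    """Smooth 0->1 ramp (cosine easing)."""
    return 0.5 * (1.0 - np.cos(np.pi * t))


def make_braided_bundle(
    word: BraidWord,
    M: int | None = None,
    N: int = 40,
    pitch: float = 4.0,
    seed: int = 0,
) -> ChainSystem:
    """Strand bundle realizing the crossings of ``word`` in order.

    ``M`` strands run from the z=0 plane to the top plane; each braid letter
    occupies a z-window of height ``pitch`` in which the two strands at the
    affected positions exchange x with cosine easing, the strand passing
    over excursing to +y and the one passing under to -y.  Chains are
    resampled to ``N`` beads by arclength.  A small seeded jitter of the
    anchor endpoints keeps the endpoint-plane construction non-degenerate.
    """
    if M is None:
        M = word.n
    if M != word.n:
        raise ValueError("braid index of the word must equal the strand count")
    rng = np.random.default_rng(seed)
    n_steps_per_window = 40
    n_letters = max(1, len(word.letters))
    H = pitch * (n_letters + 1)

    # dense strand paths, tracked by current position
    strand_of_position = list(range(M))
    paths: list[list[np.ndarray]] = [
        [np.array([_SPACING * p, 0.0, 0.0])] for p in range(M)
    ]

    def advance(z0: float, z1: float, exchange: int | None, sign: int = 1):
        """March all strands from z0 to z1; positions i,i+1 exchange if set."""
        ts = np.linspace(0.0, 1.0, n_steps_per_window + 1)[1:]
        for t in ts:
            z = z0 + t * (z1 - z0)
            for p, s in enumerate(strand_of_position):
                x = _SPACING * p
                y = 0.0
                if exchange is not None and p in (exchange, exchange + 1):
                    e = _easing(np.array([t]))[0]
                    if p == exchange:  # left strand moves right
                        x = _SPACING * (exchange + e)
                        y = (_DEPTH if sign > 0 else -_DEPTH) * np.sin(np.pi * t)
                    else:  # right strand moves left
                        x = _SPACING * (exchange + 1 - e)
                        y = (-_DEPTH if sign > 0 else _DEPTH) * np.sin(np.pi * t)
                paths[s].append(np.array([x, y, z]))
        if exchange is not None:
            i = exchange
            strand_of_position[i], strand_of_position[i + 1] = (
                strand_of_position[i + 1],
                strand_of_position[i],
            )

    z = 0.0
    advance(z, z + 0.5 * pitch, None)
    z += 0.5 * pitch
    for letter in word.letters:
        advance(z, z + pitch, abs(letter) - 1, 1 if letter > 0 else -1)
        z += pitch
    advance(z, H, None)

    chains = []
    for s in range(M):
        path = np.array(paths[s])
        # arclength resampling to N beads
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, arc[-1], N)
        pts = np.column_stack(
            [np.interp(targets, arc, path[:, k]) for k in range(3)]
        )
        # seeded jitter at the anchors (y, then x for the top) so endpoint
        # planes are never exactly collinear
        pts[0, 1] += 0.05 * rng.standard_normal()
        pts[-1, 1] += 0.05 * rng.standard_normal()
        pts[0, 2] -= 0.005 * rng.random()
        pts[-1, 2] += 0.005 * rng.random()
        chains.append(pts)
    return ChainSystem(chains)


# -- motif fixtures ----------------------------------------------------------


def _straight(y: float, z: float, n: int = 8, dx: float = 1.0) -> np.ndarray:
    return np.column_stack(
        [dx * np.arange(n), np.full(n, y), np.full(n, z)]
    )


def make_motif_system(label: MotifClass | str) -> tuple[ChainSystem, list[Contact]]:
    """A hand-built conformation realizing the requested motif.

    Returns the system together with the two contacts its contact detection
    (default cutoffs) is expected to find; every arrangement keeps all other
    bead pairs outside the 1.4 sigma cutoff.  Chains are widely separated
    (y-spacing 10 sigma) except at the contact sites, which are bent towards
    each other to within 1.2 sigma.
    """
    if isinstance(label, MotifClass):
        label = label.label
    far = 10.0
    n = 10

    if label in ("S", "P", "X"):
        # one chain folded so two bead pairs touch; realized directly by
        # bead placement on a single chain of 12 beads
        c = _straight(0.0, 0.0, n=12, dx=1.0)
        if label == "S":  # AABB: contacts (0,3) and (6,9)
            pairs = [(0, 3), (6, 9)]
        elif label == "P":  # ABBA: contacts (0,9) and (3,6)
            pairs = [(0, 9), (3, 6)]
        else:  # X, ABAB: contacts (0,6) and (3,9)
            pairs = [(0, 6), (3, 9)]
        # fold in 3D: move partner beads close in the z direction
        for (a, b) in pairs:
            c[b] = c[a] + np.array([0.0, 0.0, 1.2])
        sysm = ChainSystem([c])
        contacts = [Contact((0, a), (0, b)) for a, b in pairs]
        return sysm, contacts

    if label == "I2":
        c1 = _straight(0.0, 0.0, n=n)
        c1[4] = c1[0] + np.array([0.0, 0.0, 1.2])  # loop on chain 0: beads 0-4
        c2 = _straight(far, 0.0, n=n)
        c2[4] = c2[0] + np.array([0.0, 0.0, 1.2])
        return ChainSystem([c1, c2]), [Contact((0, 0), (0, 4)), Contact((1, 0), (1, 4))]

    if label == "T2":
        # chain 0 carries a loop (beads 0 and 4) and bead 2 bridges to chain 1
        c1 = _straight(0.0, 0.0, n=n)
        c1[4] = c1[0] + np.array([0.0, 0.0, 1.2])
        c2 = _straight(far, 0.0, n=n)
        c2[5] = c1[2] + np.array([0.0, 0.0, -1.2])
        return ChainSystem([c1, c2]), [Contact((0, 0), (0, 4)), Contact((0, 2), (1, 5))]

    if label == "I3":
        c1 = _straight(0.0, 0.0, n=n)
        c1[4] = c1[0] + np.array([0.0, 0.0, 1.2])  # loop on chain 0
        c2 = _straight(far, 0.0, n=n)
        c3 = _straight(2 * far, 0.0, n=n)
        c3[5] = c2[5] + np.array([0.0, 1.2, 0.0])
        return ChainSystem([c1, c2, c3]), [Contact((0, 0), (0, 4)), Contact((1, 5), (2, 5))]

    if label == "L2":
        c1 = _straight(0.0, 0.0, n=n)
        c2 = _straight(far, 0.0, n=n)
        c2[2] = c1[2] + np.array([0.0, 1.2, 0.0])
        c2[7] = c1[7] + np.array([0.0, 1.2, 0.0])
        return ChainSystem([c1, c2]), [Contact((0, 2), (1, 2)), Contact((0, 7), (1, 7))]

    if label == "T3":
        c1 = _straight(0.0, 0.0, n=n)
        c2 = _straight(far, 0.0, n=n)
        c3 = _straight(2 * far, 0.0, n=n)
        c2[2] = c1[2] + np.array([0.0, 1.2, 0.0])   # contact chains 0-1
        c3[7] = c1[7] + np.array([0.0, 1.2, 0.0])   # contact chains 0-2
        return ChainSystem([c1, c2, c3]), [Contact((0, 2), (1, 2)), Contact((0, 7), (2, 7))]

    if label == "I4":
        c1 = _straight(0.0, 0.0, n=n)
        c2 = _straight(far, 0.0, n=n)
        c3 = _straight(2 * far, 0.0, n=n)
        c4 = _straight(3 * far, 0.0, n=n)
        c2[2] = c1[2] + np.array([0.0, 1.2, 0.0])
        c4[7] = c3[7] + np.array([0.0, 1.2, 0.0])
        return ChainSystem([c1, c2, c3, c4]), [
            Contact((0, 2), (1, 2)),
            Contact((2, 7), (3, 7)),
        ]

    raise ValueError(f"unknown motif label {label!r}")


# -- ideal chains ------------------------------------------------------------


def make_random_walks(M: int, N: int, b: float = 0.965, seed: int = 0) -> ChainSystem:
    """Freely-jointed chains with fixed bond length ``b`` (ideal statistics)."""
    if b <= 0:
        raise ValueError("bond length must be positive")
    rng = np.random.default_rng(seed)
    chains = []
    for i in range(M):
        steps = rng.normal(size=(N - 1, 3))
        steps *= b / np.linalg.norm(steps, axis=1)[:, None]
        start = rng.uniform(-5, 5, size=3) + np.array([0.0, 20.0 * i, 0.0])
        chains.append(np.vstack([start, start + np.cumsum(steps, axis=0)]))
    return ChainSystem(chains)
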