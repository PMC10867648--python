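"""Multichain circuit topology: contacts and the nine two-contact motifs.

A contact is a bonded pair of sites (chain, bead).  Any two contacts with
four distinct sites fall into one of nine topological motifs depending on
how the sites distribute over chains and interleave along them:

* one chain: series ``S`` (AABB), parallel ``P`` (ABBA), cross ``X`` (ABAB);
* two chains: independent ``I2`` (two separate loops), loop ``L2`` (both
  contacts bridge the same two chains; parallel or cross subtype), tandem
  ``T2`` (a loop plus a bridge anchored on the loop chain; umbrella or arc
  subtype);
* three chains: independent ``I3``, tandem ``T3``;
* four chains: independent ``I4``.

The string notation places the participating chains side by side and reads
sites level by level, inserting ghost contacts ``O`` where a chain has no
site at that level (e.g. the umbrella tandem reads ``ABBOAO``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ChainSystem",
    "Contact",
    "MotifClass",
    "MotifString",
    "ContactConfig",
    "MOTIF_LABELS",
    "detect_contacts",
    "classify_pair",
    "string_notation",
    "motif_from_string",
    "motif_fractions",
    "MotifCensus",
]

MOTIF_LABELS = ("S", "P", "X", "I2", "L2", "T2", "I3", "T3", "I4")


@dataclass
class ChainSystem:
    """Ordered 3D bead coordinates of M chains (sigma units).

    Chain orientation runs from bead 0 to bead N-1.  ``masses`` defaults to
    unit mass per bead; ``box`` (if given) is a periodic cubic/orthorhombic
    box with minimum-image distances.
    """

    chains: list[np.ndarray]
    masses: list[np.ndarray] | None = None
    box: np.ndarray | None = None

    def __post_init__(self):
        self.chains = [np.asarray(c, dtype=float) for c in self.chains]
        for c in self.chains:
            if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 2:
                raise ValueError("each chain needs >= 2 beads of 3D coordinates")
            if not np.all(np.isfinite(c)):
                raise ValueError("bead positions must be finite")
        if self.masses is None:
            self.masses = [np.ones(len(c)) for c in self.chains]
        else:
            self.masses = [np.asarray(m, dtype=float) for m in self.masses]
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_beads(self) -> int:
        return sum(len(c) for c in self.chains)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All positions stacked, with the chain index of every bead."""
        pos = np.concatenate(self.chains, axis=0)
        ids = np.concatenate(
            [np.full(len(c), i, dtype=int) for i, c in enumerate(self.chains)]
        )
        return pos, ids

    def displacement(self, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
        """Minimum-image displacement r2 - r1."""
        d = np.asarray(r2) - np.asarray(r1)
        if self.box is not None:
            d -= self.box * np.round(d / self.box)
        return d

    def copy(self) -> "ChainSystem":
        return ChainSystem(
            [c.copy() for c in self.chains],
            [m.copy() for m in self.masses],
            None if self.box is None else self.box.copy(),
        )


@dataclass(frozen=True)
class Contact:
    """A bonded pair of sites; each site is (chain index, bead index)."""

    site1: tuple[int, int]
    site2: tuple[int, int]

    def __post_init__(self):
        s1, s2 = tuple(self.site1), tuple(self.site2)
        if s1 == s2:
            raise ValueError("a contact needs two distinct sites")
        if s2 < s1:
            s1, s2 = s2, s1
        object.__setattr__(self, "site1", s1)
        object.__setattr__(self, "site2", s2)

    @property
    def sites(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.site1, self.site2)

    @property
    def chains(self) -> set[int]:
        return {self.site1[0], self.site2[0]}

    @property
    def intrachain(self) -> bool:
        return self.site1[0] == self.site2[0]


@dataclass(frozen=True)
class MotifClass:
    """One of the nine motif labels, with the degenerate subtype where defined."""

    label: str
    subtype: str | None = None

    def __post_init__(self):
        if self.label not in MOTIF_LABELS:
            raise ValueError(f"unknown motif label {self.label!r}")
        allowed = {"L2": {"parallel", "cross"}, "T2": {"umbrella", "arc"}}
        if self.subtype is not None:
            if self.label not in allowed or self.subtype not in allowed[self.label]:
                raise ValueError(f"subtype {self.subtype!r} invalid for {self.label}")


@dataclass(frozen=True)
class MotifString:
    """Ghost-contact string notation, read in n-tuples of chain characters."""

    text: str
    n_chains: int

    def __post_init__(self):
        if len(self.text) % self.n_chains != 0:
            raise ValueError("string length must be divisible by the chain count")
        counts = {ch: self.text.count(ch) for ch in "AB"}
        if counts["A"] != 2 or counts["B"] != 2:
            raise ValueError("string must contain exactly two A's and two B's")
        if set(self.text) - set("ABO"):
            raise ValueError("string alphabet is {A, B, O}")

    def levels(self) -> list[str]:
        n = self.n_chains
        return [self.text[i : i + n] for i in range(0, len(self.text), n)]


@dataclass(frozen=True)
class ContactConfig:
    """Contact-detection cutoffs (sigma units).

    ``rc`` is the Euclidean cutoff.  ``min_backbone_sep`` excludes intrachain
    pairs closer than that many bonds along the backbone, so that next-nearest
    backbone neighbours can never form the two-bond loop.  If
    ``intrachain_rc`` is set, intrachain pairs additionally use it as their
    (usually tighter) Euclidean cutoff -- the alternative reading of the
    self-interaction cutoff.
    """

    rc: float = 1.4
    min_backbone_sep: int = 3
    intrachain_rc: float | None = None

    def __post_init__(self):
        if self.rc <= 0:
            raise ValueError("rc must be positive")
        if self.min_backbone_sep < 1:
            raise ValueError("min_backbone_sep must be >= 1")


# -- contact detection -------------------------------------------------------


def detect_contacts(
    system: ChainSystem, config: ContactConfig = ContactConfig()
) -> list[Contact]:
    """All site pairs within the cutoff, self-exclusion rule applied.

    Deterministic lexicographic ordering by site.
    """
    pos, ids = system.flat()
    bead_idx = np.concatenate([np.arange(len(c)) for c in system.chains])
    n = len(pos)
    diff = pos[None, :, :] - pos[:, None, :]
    if system.box is not None:
        diff -= system.box * np.round(diff / system.box)
    dist = np.sqrt((diff**2).sum(axis=-1))
    out: list[Contact] = []
    for a in range(n):
        for b in range(a + 1, n):
            same = ids[a] == ids[b]
            cutoff = config.rc
            if same and config.intrachain_rc is not None:
                cutoff = config.intrachain_rc
            if dist[a, b] > cutoff:
                continue
            if same and abs(int(bead_idx[a]) - int(bead_idx[b])) < config.min_backbone_sep:
                continue
            out.append(
                Contact(
                    (int(ids[a]), int(bead_idx[a])), (int(ids[b]), int(bead_idx[b]))
                )
            )
    out.sort(key=lambda c: (c.site1, c.site2))
    return out


# -- motif classification ----------------------------------------------------


def _single_chain_label(c1: Contact, c2: Contact) -> str:
    """S/P/X from the arrangement string of two loops on one chain."""
    sites = sorted(
        [(s[1], "A") for s in c1.sites] + [(s[1], "B") for s in c2.sites]
    )
    pattern = "".join(letter for _, letter in sites)
    if pattern in ("AABB", "BBAA"):
        return "S"
    if pattern in ("ABBA", "BAAB"):
        return "P"
    return "X"  # ABAB / BABA


def _loop_subtype(c1: Contact, c2: Contact) -> str:
    """Parallel vs cross loop for L2 (both contacts bridge chains p, q)."""
    p, q = sorted(c1.chains)

    def site_on(contact: Contact, chain: int) -> int:
        for ch, bead in contact.sites:
            if ch == chain:
                return bead
        raise AssertionError

    a_p, b_p = site_on(c1, p), site_on(c2, p)
    a_q, b_q = site_on(c1, q), site_on(c2, q)
    return "parallel" if (a_p < b_p) == (a_q < b_q) else "cross"


def _tandem_subtype(intra: Contact, inter: Contact) -> str:
    """Umbrella if the bridge anchors inside the loop span, else arc."""
    chain = intra.site1[0]
    lo, hi = sorted((intra.site1[1], intra.site2[1]))
    anchor = next(bead for ch, bead in inter.sites if ch == chain)
    return "umbrella" if lo < anchor < hi else "arc"


def classify_pair(c1: Contact, c2: Contact) -> MotifClass:
    """Motif of a pair of contacts with four distinct sites.

    Implements the chain-sharing decision tree; symmetric under renaming
    the contacts (A <-> B).
    """
    if set(c1.sites) & set(c2.sites):
        raise ValueError("contacts share a site")
    if c1.intrachain or c2.intrachain:
        # order so that the first considered contact is intrachain
        intra, other = (c1, c2) if c1.intrachain else (c2, c1)
        p1 = intra.site1[0]
        if other.intrachain:
            p2 = other.site1[0]
            if p1 == p2:
                return MotifClass(_single_chain_label(c1, c2))
            return MotifClass("I2")
        # other is interchain: tandem or independent-3
        if p1 in other.chains:
            return MotifClass("T2", _tandem_subtype(intra, other))
        return MotifClass("I3")
    shared = c1.chains & c2.chains
    if len(shared) == 0:
        return MotifClass("I4")
    if len(shared) == 1:
        return MotifClass("T3")
    return MotifClass("L2", _loop_subtype(c1, c2))


# -- string notation ---------------------------------------------------------


def string_notation(c1: Contact, c2: Contact, system: ChainSystem | None = None) -> MotifString:
    """Canonical ghost-contact string for a pair of contacts.

    Participating chains are placed left to right (chains carrying more
    sites first), each chain's sites are read top to bottom in backbone
    order, chains with fewer sites are padded with ghost contacts ``O`` at
    the bottom, and the first site in reading order is named ``A``.
    """
    if set(c1.sites) & set(c2.sites):
        raise ValueError("contacts share a site")
    per_chain: dict[int, list[tuple[int, int]]] = {}
    for tag, contact in ((0, c1), (1, c2)):
        for ch, bead in contact.sites:
            per_chain.setdefault(ch, []).append((bead, tag))
    for sites in per_chain.values():
        sites.sort()
    order = sorted(per_chain, key=lambda ch: (-len(per_chain[ch]), ch))
    n_levels = max(len(per_chain[ch]) for ch in order)
    # name the contact that owns the first site in reading order "A"
    first_tag = None
    for level in range(n_levels):
        for ch in order:
            sites = per_chain[ch]
            if level < len(sites) and first_tag is None:
                first_tag = sites[level][1]
    letter = {first_tag: "A", 1 - first_tag: "B"}
    chars = []
    for level in range(n_levels):
        for ch in order:
            sites = per_chain[ch]
            chars.append(letter[sites[level][1]] if level < len(sites) else "O")
    return MotifString("".join(chars), n_chains=len(order))


def motif_from_string(s: MotifString) -> MotifClass:
    """Recover the motif class encoded by a ghost-contact string."""
    n = s.n_chains
    columns: list[list[str]] = [[] for _ in range(n)]
    for level in s.levels():
        for j, ch in enumerate(level):
            if ch in "AB":
                columns[j].append(ch)
    sites: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}
    for j, col in enumerate(columns):
        for k, ch in enumerate(col):
            sites[ch].append((j, k))
    c1 = Contact(*sites["A"])
    c2 = Contact(*sites["B"])
    return classify_pair(c1, c2)


# -- census ------------------------------------------------------------------


@dataclass
class MotifCensus:
    """Class-level motif fractions of all contact pairs in a conformation."""

    fractions: dict[str, float]
    n_contacts: int
    n_pairs: int
    n_pairs_skipped: int

    @property
    def ok(self) -> bool:
        return self.n_pairs > 0

    def interchain_sum(self) -> float:
        """[L2] + [T3] + [I4]: the alignment order parameter."""
        return sum(self.fractions.get(k, 0.0) for k in ("L2", "T3", "I4"))


def motif_fractions(
    system: ChainSystem,
    config: ContactConfig = ContactConfig(),
    contacts: Sequence[Contact] | None = None,
) -> MotifCensus:
    """Classify every unordered pair of detected contacts.

    Pairs sharing a site do not fit the four-site motif alphabet and are
    skipped (counted).  Fractions are over classified pairs and sum to 1
    whenever at least one pair was classified.
    """
    if contacts is None:
        contacts = detect_contacts(system, config)
    counts = {label: 0 for label in MOTIF_LABELS}
    skipped = 0
    total = 0
    for c1, c2 in itertools.combinations(contacts, 2):
        if set(c1.sites) & set(c2.sites):
            skipped += 1
            continue
        counts[classify_pair(c1, c2).label] += 1
        total += 1
    fractions = {
        label: (counts[label] / total if total else 0.0) for label in MOTIF_LABELS
    }
    return MotifCensus(
        fractions=fractions,
        n_contacts=len(contacts),
        n_pairs=total,
        n_pairs_skipped=skipped,
    )
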