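"""Contact detection and the nine-motif classification."""

import itertools

import numpy as np
import pytest

from braidct.circuit_topology import (
    ChainSystem,
    Contact,
    ContactConfig,
    MOTIF_LABELS,
    MotifClass,
    MotifString,
    classify_pair,
    detect_contacts,
    motif_fractions,
    motif_from_string,
    string_notation,
)
from braidct.synthetic_fixtures import make_motif_system, make_random_walks

import oracles


def enumerate_two_contact_placements(max_chains=4, sites_per_chain=4, gap=4):
    """All ways to place two contacts (4 distinct sites) on <= 4 chains.

    Sites are assigned to chains and interleaved in every order; bead
    indices are spaced ``gap`` apart so the backbone-separation rule never
    interferes.  Yields (contact_A, contact_B).
    """
    sites = ["A1", "A2", "B1", "B2"]
    for chain_of in itertools.product(range(max_chains), repeat=4):
        # canonicalize chain usage (first appearance order) to cut duplicates
        used = sorted(set(chain_of))
        relabel = {c: i for i, c in enumerate(used)}
        assignment = tuple(relabel[c] for c in chain_of)
        if assignment != chain_of:
            continue
        per_chain = {}
        for s, c in zip(sites, assignment):
            per_chain.setdefault(c, []).append(s)
        # all orderings of the sites along each chain
        orders = [itertools.permutations(per_chain[c]) for c in sorted(per_chain)]
        for combo in itertools.product(*orders):
            bead = {}
            for c, order in enumerate(combo):
                for k, s in enumerate(order):
                    bead[s] = (c, gap * k)
            yield (
                Contact(bead["A1"], bead["A2"]),
                Contact(bead["B1"], bead["B2"]),
            )


class TestClassifier:
    def test_exhaustive_enumeration_partitions_into_nine_classes(self):
        seen = {}
        count = 0
        for cA, cB in enumerate_two_contact_placements():
            m1 = classify_pair(cA, cB)
            m2 = classify_pair(cB, cA)  # A<->B renaming symmetry
            assert m1.label == m2.label
            chains = len(cA.chains | cB.chains)
            seen.setdefault(m1.label, set()).add(chains)
            count += 1
        assert set(seen) == set(MOTIF_LABELS)
        # chain-count signatures of each class
        assert seen["S"] == seen["P"] == seen["X"] == {1}
        assert seen["I2"] == seen["L2"] == seen["T2"] == {2}
        assert seen["I3"] == seen["T3"] == {3}
        assert seen["I4"] == {4}
        assert count > 100

    def test_single_chain_arrangements(self):
        # AABB / ABBA / ABAB on one chain
        S = classify_pair(Contact((0, 0), (0, 4)), Contact((0, 8), (0, 12)))
        P = classify_pair(Contact((0, 0), (0, 12)), Contact((0, 4), (0, 8)))
        X = classify_pair(Contact((0, 0), (0, 8)), Contact((0, 4), (0, 12)))
        assert (S.label, P.label, X.label) == ("S", "P", "X")

    def test_tandem_and_independent_examples(self):
        # chain 0 carries A,B,A; chain 1 carries the other B site
        t2 = classify_pair(Contact((0, 0), (0, 8)), Contact((0, 4), (1, 0)))
        assert t2 == MotifClass("T2", "umbrella")
        arc = classify_pair(Contact((0, 0), (0, 4)), Contact((0, 8), (1, 0)))
        assert arc == MotifClass("T2", "arc")
        i4 = classify_pair(Contact((0, 0), (1, 0)), Contact((2, 0), (3, 0)))
        assert i4.label == "I4"

    def test_loop_subtypes(self):
        par = classify_pair(Contact((0, 0), (1, 0)), Contact((0, 4), (1, 4)))
        assert par == MotifClass("L2", "parallel")
        cross = classify_pair(Contact((0, 0), (1, 4)), Contact((0, 4), (1, 0)))
        assert cross == MotifClass("L2", "cross")

    def test_shared_site_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(Contact((0, 0), (0, 4)), Contact((0, 0), (1, 0)))


class TestStringNotation:
    def test_umbrella_tandem_reads_abboao(self):
        _, (c1, c2) = make_motif_system("T2")
        assert string_notation(c1, c2).text == "ABBOAO"

    def test_series_reads_aabb(self):
        _, (c1, c2) = make_motif_system("S")
        s = string_notation(c1, c2)
        assert s.text == "AABB" and s.n_chains == 1

    def test_roundtrip_class_recovery(self):
        """Motif recovered from the string equals the direct classification."""
        rng = np.random.default_rng(5)
        checked = 0
        placements = list(enumerate_two_contact_placements())
        size = min(200, len(placements))
        for idx in rng.choice(len(placements), size=size, replace=False):
            cA, cB = placements[idx]
            s = string_notation(cA, cB)
            assert motif_from_string(s).label == classify_pair(cA, cB).label
            checked += 1
        assert checked >= 100

    def test_string_invariants(self):
        _, (c1, c2) = make_motif_system("I4")
        s = string_notation(c1, c2)
        assert s.text.count("A") == 2 and s.text.count("B") == 2
        assert len(s.text) % s.n_chains == 0


class TestDetection:
    def test_interchain_pair_within_cutoff(self):
        chains = [
            np.array([[0.0, 0, 0], [1, 0, 0]]),
            np.array([[0.0, 1.3, 0], [1, 5, 0]]),
        ]
        found = detect_contacts(ChainSystem(chains))
        assert found == [Contact((0, 0), (1, 0))]

    def test_bonded_neighbors_excluded(self):
        chain = np.array([[0.0, 0, 0], [0.965, 0, 0], [1.93, 0, 0], [2.9, 0, 0]])
        assert detect_contacts(ChainSystem([chain])) == []

    def test_matches_brute_force_oracle(self):
        system = make_random_walks(4, 10, b=1.0, seed=3)
        # pull the chains together so contacts exist
        chains = [c - c.mean(axis=0) + 1.2 * k for k, c in enumerate(system.chains)]
        system = ChainSystem(chains)
        got = [(c.site1, c.site2) for c in detect_contacts(system)]
        assert got == oracles.brute_force_contacts(system)

    def test_periodic_minimum_image(self):
        box = np.array([10.0, 10.0, 10.0])
        chains = [
            np.array([[0.2, 0, 0], [1.2, 0, 0]]),
            np.array([[9.5, 0, 0], [8.5, 0, 0]]),  # 0.7 away across the boundary
        ]
        system = ChainSystem(chains, box=box)
        found = detect_contacts(system)
        assert Contact((0, 0), (1, 0)) in found
        got = [(c.site1, c.site2) for c in found]
        assert got == oracles.brute_force_contacts(system)

    def test_intrachain_alternative_cutoff(self):
        chain = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1.2, 0]])
        # bead 0-3 distance ~2.33 > 1.4: no contact either way; tighten the
        # geometry so beads 0 and 3 sit at 1.3
        chain[3] = [0.4, 1.24, 0]
        base = detect_contacts(ChainSystem([chain]))
        assert base == [Contact((0, 0), (0, 3))]
        tight = detect_contacts(
            ChainSystem([chain]), ContactConfig(intrachain_rc=1.0)
        )
        assert tight == []


class TestFractions:
    def test_parallel_chains_interchain_only(self):
        chains = [
            np.column_stack([np.arange(8.0), np.full(8, 1.2 * k), np.zeros(8)])
            for k in range(4)
        ]
        census = motif_fractions(ChainSystem(chains))
        assert census.ok
        assert census.interchain_sum() == pytest.approx(1.0)
        assert sum(census.fractions.values()) == pytest.approx(1.0)

    def test_two_contacts_single_class(self):
        system, contacts = make_motif_system("T3")
        census = motif_fractions(system)
        assert census.n_pairs == 1
        assert census.fractions["T3"] == 1.0

    def test_fewer_than_two_contacts_flagged(self):
        chains = [
            np.array([[0.0, 0, 0], [1, 0, 0]]),
            np.array([[0.0, 50, 0], [1, 50, 0]]),
        ]
        census = motif_fractions(ChainSystem(chains))
        assert not census.ok and census.n_pairs == 0

    def test_rigid_transform_invariance(self):
        system, _ = make_motif_system("L2")
        census0 = motif_fractions(system)
        # rotate + translate
        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        moved = ChainSystem([c @ R.T + np.array([3.0, -2.0, 5.0]) for c in system.chains])
        census1 = motif_fractions(moved)
        assert census0.fractions == census1.fractions
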