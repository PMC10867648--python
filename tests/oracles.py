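"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different routes than the
package: exhaustive enumeration with a faithful free-group action for
minimal braid length, brute-force itinerary enumeration for curve crossing
counts, a numeric polygonal-curve oracle for the loop action, and plain
double loops for contact detection.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- free group + Artin action (independent implementation) ------------------


def freduce(w):
    out = []
    for x in w:
        if out and out[-1] == -x:
            out.pop()
        else:
            out.append(x)
    return out


def artin_apply(letter, n, w):
    """Image of free word w under one braid generator (standard action)."""
    i = abs(letter)
    out = []
    for x in w:
        j = abs(x)
        if letter > 0:
            if j == i:
                piece = [i, i + 1, -i]
            elif j == i + 1:
                piece = [i]
            else:
                piece = [j]
        else:
            if j == i:
                piece = [i + 1]
            elif j == i + 1:
                piece = [-(i + 1), i, i + 1]
            else:
                piece = [j]
        out.extend(piece if x > 0 else [-p for p in reversed(piece)])
    return freduce(out)


def braid_signature(letters, n):
    """Images of all generators; a faithful equality certificate in B_n."""
    sig = []
    for j in range(1, n + 1):
        w = [j]
        for letter in reversed(letters):
            w = artin_apply(letter, n, w)
        sig.append(tuple(w))
    return tuple(sig)


def exhaustive_minimal_length(letters, n, cap=None):
    """Shortest equivalent word by enumeration over all words up to ``cap``.

    Returns None when no equivalent word of length <= cap exists (certifying
    a lower bound of cap+1).
    """
    target = braid_signature(letters, n)
    alphabet = [s * i for i in range(1, n) for s in (1, -1)]
    top = len(letters) if cap is None else cap
    for L in range(0, top + 1):
        for cand in itertools.product(alphabet, repeat=L):
            if braid_signature(cand, n) == target:
                return L
    return None


# -- curve crossing counts by brute itinerary enumeration --------------------


def _upper_excursion(a, b):
    if a == b:
        return []
    if a > b:
        return list(range(a, b, -1))
    return [-j for j in range(a + 1, b + 1)]


def arc_word_of_itinerary(it):
    """Free word of a below-anchored rim arc with the given gap itinerary."""
    w = []
    for k in range(0, len(it) - 1, 2):
        w.extend(_upper_excursion(it[k], it[k + 1]))
    return freduce(w)


def exhaustive_arc_axis_count(word, n, max_len=10):
    """Minimal axis crossings of an arc class by itinerary enumeration."""
    word = freduce(word)
    for L in range(0, max_len + 1, 2):
        for it in itertools.product(range(n + 1), repeat=L):
            if any(it[i] == it[i + 1] for i in range(L - 1)):
                continue
            if arc_word_of_itinerary(list(it)) == word:
                return L
    raise RuntimeError("count exceeds enumeration cap")


# -- numeric polygonal-curve oracle ------------------------------------------
#
# The geometric dictionary compatible with the Artin formulas used by the
# package reads an upper excursion rightward from gap a to gap b as the
# positive ascending product x_{a+1} .. x_b (lower excursions are trivial).


def artin_arc_word(it):
    """Free word of a below-anchored arc, Artin-compatible dictionary."""
    w = []
    for k in range(0, len(it) - 1, 2):
        a, b = it[k], it[k + 1]
        if a < b:
            w.extend(range(a + 1, b + 1))
        else:
            w.extend(-j for j in range(a, b, -1))
    return freduce(w)


def polyline_canonical_arc(n):
    """A polyline whose Artin-dictionary word is x1^-1 x2^-1 (canonical E).

    Crossing sequence: up in gap 1, leftward over p1, down in gap 0, under
    p1 and p2, up in gap 2, leftward over p2, down in gap 1, under the rest.
    (Minimal representatives of arc classes need not be embedded; the
    half-twist maps are homeomorphisms and carry self-overlaps along.)
    """
    pts = [
        (0.45, -0.2), (1.5, -0.2), (1.5, 0.35), (0.7, 0.35), (0.7, -0.35),
        (2.45, -0.35), (2.45, 0.35), (1.6, 0.35), (1.6, -0.45),
        (n + 0.6, -0.45),
    ]
    return np.array(pts, dtype=float)


def _resample(P, dmax=0.01):
    out = [P[0]]
    for p in P[1:]:
        prev = out[-1]
        d = float(np.hypot(*(p - prev)))
        if d > dmax:
            k = int(np.ceil(d / dmax))
            for j in range(1, k + 1):
                out.append(prev + (p - prev) * j / k)
        else:
            out.append(p)
    return np.array(out)


def polyline_twist(P, i, sign, r_out=0.95, r_in=0.55):
    """Smooth half-twist homeomorphism exchanging punctures i and i+1."""
    c = np.array([i + 0.5, 0.0])
    Q = P - c
    r = np.hypot(Q[:, 0], Q[:, 1])
    ramp = np.clip((r_out - r) / (r_out - r_in), 0.0, 1.0)
    ang = sign * np.pi * ramp
    ca, sa = np.cos(ang), np.sin(ang)
    R = np.column_stack([ca * Q[:, 0] - sa * Q[:, 1], sa * Q[:, 0] + ca * Q[:, 1]])
    return R + c


def polyline_itinerary(P, n):
    """Gap indices of the successive axis crossings of the polyline."""
    gaps = []
    y = P[:, 1] + 1e-7  # nudge exact-zero samples off the axis
    for k in range(len(P) - 1):
        if y[k] * y[k + 1] < 0:
            t = y[k] / (y[k] - y[k + 1])
            xc = P[k, 0] + t * (P[k + 1, 0] - P[k, 0])
            gap = int(np.floor(xc))  # punctures at integers 1..n
            gaps.append(min(max(gap, 0), n))
    return gaps


def polyline_arc_word(P, n):
    """Free word of the drawn arc (anchors below the axis)."""
    return artin_arc_word(polyline_itinerary(P, n))


# -- contacts ----------------------------------------------------------------


def brute_force_contacts(system, rc=1.4, min_sep=3):
    """All-pairs contact scan written independently (plain loops)."""
    found = []
    beads = []
    for ci, chain in enumerate(system.chains):
        for bi, r in enumerate(chain):
            beads.append((ci, bi, np.asarray(r)))
    for a in range(len(beads)):
        for b in range(a + 1, len(beads)):
            ca, ia, ra = beads[a]
            cb, ib, rb = beads[b]
            d = rb - ra
            if system.box is not None:
                d = d - system.box * np.round(d / system.box)
            if np.linalg.norm(d) > rc:
                continue
            if ca == cb and abs(ia - ib) < min_sep:
                continue
            found.append(((ca, ia), (cb, ib)))
    return sorted(found)
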