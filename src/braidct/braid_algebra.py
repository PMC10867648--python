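"""Braid words, the Artin moves, and topological braid measures.

A braid on ``n`` strands is a word in the Artin generators sigma_1 ..
sigma_{n-1}; letter ``k`` encodes sigma_|k| (positive: strand |k| passes over
strand |k|+1) with negative ``k`` for the inverse crossing.  Four measures are
provided:

* :func:`writhe` -- signed crossing sum (exponent sum), a braid invariant;
* :func:`minimal_length` / :func:`reduce` -- fewest letters among words
  equivalent under free cancellation, disjoint-strand commutation and the
  braid (Skein) relation, found by bounded breadth-first search over the
  rewriting closure;
* :func:`complexity` -- logarithm of the factor by which the braid stretches
  a canonical curve spanning the punctured disk, measured as the exact
  minimal number of intersections of the image curve with the real axis;
* :func:`tn_classify` -- heuristic Thurston--Nielsen isotopy class
  (finite-order FO, reducible RE, pseudo-Anosov PA).

The curve machinery is exact integer topology, no floating point: a curve on
the n-punctured disk is carried as a word in the free group
pi_1 = F_n = <x_1..x_n> (x_j the loop around puncture j routed below the
axis), braid generators act through the Artin automorphisms, and minimal
crossing numbers with each axis segment ("gap") are obtained from Britton
normal forms of the Bass--Serre splitting of F_n along that segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import deque
from typing import Iterable, Sequence

__all__ = [
    "BraidWord",
    "BraidInvariants",
    "LoopCoordinates",
    "canonical_curve",
    "apply_generator",
    "writhe",
    "reduce_word",
    "minimal_length",
    "complexity",
    "tn_classify",
    "braid_equal",
    "compute_invariants",
]

# -- tolerances / caps (module configuration) --------------------------------

#: per-letter loop-coordinate growth above which a braid is called pA
PA_GROWTH_TOL = 1e-3
#: default number of braid applications in the growth estimate
PA_GROWTH_ITERATIONS = 50
#: abort growth iteration when the curve word exceeds this many letters;
#: exceeding it is itself evidence of super-polynomial stretching
CURVE_WORD_CAP = 200_000
#: visited-state cap for the minimal-length breadth-first search
BFS_STATE_CAP = 300_000


# -- braid words -------------------------------------------------------------


@dataclass(frozen=True)
class BraidWord:
    """A word in the Artin generators of the braid group B_n.

    ``letters`` is a sequence of nonzero integers; letter ``k`` means
    sigma_|k|^{sign(k)} and must satisfy 1 <= |k| <= n-1.  The empty word is
    the identity braid.
    """

    n: int
    letters: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("braid index must be >= 1")
        object.__setattr__(self, "letters", tuple(int(k) for k in self.letters))
        for k in self.letters:
            if k == 0 or abs(k) > self.n - 1:
                raise ValueError(f"letter {k} out of range for braid index {self.n}")

    def __len__(self) -> int:
        return len(self.letters)

    def __mul__(self, other: "BraidWord") -> "BraidWord":
        if other.n != self.n:
            raise ValueError("braid indices differ")
        return BraidWord(self.n, self.letters + other.letters)

    def inverse(self) -> "BraidWord":
        return BraidWord(self.n, tuple(-k for k in reversed(self.letters)))

    def __pow__(self, m: int) -> "BraidWord":
        if m < 0:
            return self.inverse() ** (-m)
        return BraidWord(self.n, self.letters * m)

    @classmethod
    def from_string(cls, text: str, n: int | None = None) -> "BraidWord":
        """Parse a whitespace-separated signed-integer serialization."""
        letters = tuple(int(tok) for tok in text.split())
        if n is None:
            n = max((abs(k) for k in letters), default=1) + 1
        return cls(n, letters)

    def to_string(self) -> str:
        return " ".join(str(k) for k in self.letters)


@dataclass(frozen=True)
class BraidInvariants:
    """The four topological measures of a braid."""

    writhe: int
    minimal_length: int
    complexity: float
    log_base: float
    isotopy_class: str  # "FO", "RE" or "PA"


# -- free group machinery ----------------------------------------------------


def _free_reduce(w: Iterable[int]) -> list[int]:
    out: list[int] = []
    for x in w:
        if out and out[-1] == -x:
            out.pop()
        else:
            out.append(x)
    return out


def _cyc_reduce(w: Sequence[int]) -> list[int]:
    w = _free_reduce(w)
    while len(w) >= 2 and w[0] == -w[-1]:
        w = _free_reduce(w[1:-1])
    return list(w)


def _artin_images(letter: int, n: int) -> dict[int, list[int]]:
    """Images of the free generators under one braid generator.

    sigma_i: x_i -> x_i x_{i+1} x_i^-1, x_{i+1} -> x_i (Artin representation);
    the inverse generator undoes it.
    """
    i = abs(letter)
    img = {j: [j] for j in range(1, n + 1)}
    if letter > 0:
        img[i] = [i, i + 1, -i]
        img[i + 1] = [i]
    else:
        img[i] = [i + 1]
        img[i + 1] = [-(i + 1), i, i + 1]
    return img


def _apply_images(img: dict[int, list[int]], w: Sequence[int]) -> list[int]:
    out: list[int] = []
    for x in w:
        piece = img[abs(x)]
        if x < 0:
            out.extend(-y for y in reversed(piece))
        else:
            out.extend(piece)
    return _free_reduce(out)


def _act(word: BraidWord, w: Sequence[int]) -> list[int]:
    """Image of the curve-class word ``w`` under the braid.

    Convention (calibrated against the worked complexity values): the
    rightmost braid letter acts on the disk first.
    """
    out = list(w)
    for letter in reversed(word.letters):
        out = _apply_images(_artin_images(letter, word.n), out)
        if len(out) > CURVE_WORD_CAP:
            raise OverflowError("curve word exceeded cap (exponential stretching)")
    return out


def _generator_images(word: BraidWord) -> tuple[tuple[int, ...], ...]:
    """Images of all free generators under the braid; a faithful signature."""
    return tuple(tuple(_act(word, [j])) for j in range(1, word.n + 1))


def braid_equal(u: BraidWord, v: BraidWord) -> bool:
    """Exact equality in B_n via the faithful Artin representation."""
    if u.n != v.n:
        return False
    return _generator_images(u) == _generator_images(v)


# -- axis-crossing counts (Bass--Serre slit splittings) ----------------------


def _slit_count(w: Sequence[int], n: int, k: int, closed: bool) -> int:
    """Minimal crossings of the class ``w`` with the axis segment in gap k.

    Gap k lies between punctures p_k and p_{k+1} (gap 0 left of p_1, gap n
    right of p_n).  Cutting the disk along that segment splits
    F_n = V_k * <t>; the crossing number is the number of t-letters in the
    (cyclically, for closed classes) reduced normal form.  For interior k the
    basis rewrite is t = x_k, y = x_{k+1} x_k (so x_{k+1} = y t^-1); for the
    outer gaps t is simply x_1 or x_n.
    """
    rew: list[tuple[object, int]] = []
    if k == 0 or k == n:
        t_gen = 1 if k == 0 else n
        for x in w:
            j, s = abs(x), (1 if x > 0 else -1)
            rew.append(("t", s) if j == t_gen else (j, s))
    else:
        for x in w:
            j, s = abs(x), (1 if x > 0 else -1)
            if j == k:
                rew.append(("t", s))
            elif j == k + 1:
                if s > 0:
                    rew.extend([("y", 1), ("t", -1)])
                else:
                    rew.extend([("t", 1), ("y", -1)])
            else:
                rew.append((j, s))
    out: list[tuple[object, int]] = []
    for g, s in rew:
        if out and out[-1][0] == g and out[-1][1] == -s:
            out.pop()
        else:
            out.append((g, s))
    if closed:
        changed = True
        while changed and len(out) >= 2:
            changed = False
            if out[0][0] == out[-1][0] and out[0][1] == -out[-1][1]:
                out = out[1:-1]
                red: list[tuple[object, int]] = []
                for g, s in out:
                    if red and red[-1][0] == g and red[-1][1] == -s:
                        red.pop()
                    else:
                        red.append((g, s))
                out = red
                changed = True
    return sum(1 for g, _ in out if g == "t")


def _axis_count_arc(w: Sequence[int], n: int) -> int:
    """Total minimal axis crossings of a rim-anchored arc class."""
    w = _free_reduce(w)
    return sum(_slit_count(w, n, k, closed=False) for k in range(n + 1))


def _axis_count_closed(w: Sequence[int], n: int) -> int:
    """Total minimal axis crossings of a free (closed-curve) class."""
    w = _cyc_reduce(w)
    if not w:
        return 0
    return sum(_slit_count(w, n, k, closed=True) for k in range(n + 1))


# -- loop coordinates --------------------------------------------------------


@dataclass(frozen=True)
class LoopCoordinates:
    """Exact curve-diagram state on the n-punctured disk.

    The carried curve is a rim-to-rim arc class, stored as a word in the free
    group on the puncture loops (exact integer topology, arbitrary
    precision).  ``coords`` exposes a derived 2n-4 integer coordinate vector
    in the Dynnikov spirit: the interior per-gap crossing counts
    t_1 .. t_{n-1} followed by the net over-passage counts a_2 .. a_{n-2}.
    """

    n: int
    word: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 punctures")
        object.__setattr__(self, "word", tuple(_free_reduce(self.word)))

    # crossing data ----------------------------------------------------

    def gap_counts(self) -> tuple[int, ...]:
        """Minimal crossings with each of the n+1 axis segments."""
        w = _free_reduce(self.word)
        return tuple(_slit_count(w, self.n, k, closed=False) for k in range(self.n + 1))

    def axis_intersections(self) -> int:
        """Total minimal number of transversal crossings with the real axis."""
        return sum(self.gap_counts())

    @property
    def coords(self) -> tuple[int, ...]:
        if self.n == 2:
            return ()
        gaps = self.gap_counts()
        t_interior = gaps[1 : self.n]
        expsum = {j: 0 for j in range(1, self.n + 1)}
        for x in self.word:
            expsum[abs(x)] += 1 if x > 0 else -1
        over = tuple(-expsum[j] for j in range(2, self.n - 1))
        return tuple(t_interior) + over

    # action -----------------------------------------------------------

    def apply(self, letter: int) -> "LoopCoordinates":
        if letter == 0 or abs(letter) > self.n - 1:
            raise ValueError(f"generator {letter} out of range for {self.n} punctures")
        img = _artin_images(letter, self.n)
        return LoopCoordinates(self.n, tuple(_apply_images(img, self.word)))

    def apply_word(self, word: BraidWord) -> "LoopCoordinates":
        if word.n != self.n:
            raise ValueError("braid index does not match puncture count")
        return LoopCoordinates(self.n, tuple(_act(word, self.word)))


def canonical_curve(n: int) -> LoopCoordinates:
    """The canonical spanning arc E used by the complexity index.

    An arc running from the left rim to the right rim, passing over the first
    two punctures and under the rest; it crosses the real axis exactly twice
    (left of p_1 and right of p_2).  The convention is calibrated so that the
    worked stretching ratios of sigma1 sigma2 and sigma1 sigma2^{-1} are 3
    and 4 (natural-log complexities 1.099 and 1.386).
    """
    if n < 2:
        raise ValueError("need at least 2 punctures")
    word = (-1, -2) if n >= 3 else (-1,)
    return LoopCoordinates(n, word)


def apply_generator(coords: LoopCoordinates, letter: int) -> LoopCoordinates:
    """Image of a curve diagram under a single braid generator."""
    return coords.apply(letter)


# -- writhe ------------------------------------------------------------------


def writhe(word: BraidWord) -> int:
    """Sum of the exponents of the braid letters (net crossing sign)."""
    return sum(1 if k > 0 else -1 for k in word.letters)


# -- minimal length ----------------------------------------------------------


def _greedy_cancel(letters: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(_free_reduce(letters))


def _neighbors(state: tuple[int, ...]) -> Iterable[tuple[int, ...]]:
    L = len(state)
    # free cancellation
    for j in range(L - 1):
        if state[j] == -state[j + 1]:
            yield state[:j] + state[j + 2 :]
    # commutation of distant generators
    for j in range(L - 1):
        a, b = state[j], state[j + 1]
        if abs(abs(a) - abs(b)) >= 2:
            yield state[:j] + (b, a) + state[j + 2 :]
    # braid relation, same-sign triple: s_i^e s_j^e s_i^e = s_j^e s_i^e s_j^e
    for j in range(L - 2):
        a, b, c = state[j], state[j + 1], state[j + 2]
        if a == c and abs(abs(a) - abs(b)) == 1 and (a > 0) == (b > 0):
            yield state[:j] + (b, a, b) + state[j + 3 :]
        # conjugation form: s_i^e s_j^f s_i^-e = s_j^-e s_i^f s_j^e
        if a == -c and abs(abs(a) - abs(b)) == 1:
            i_s = abs(a)
            j_s = abs(b)
            e = 1 if a > 0 else -1
            f = 1 if b > 0 else -1
            yield state[:j] + (-e * j_s, f * i_s, e * j_s) + state[j + 3 :]


def reduce_word(word: BraidWord, max_states: int = BFS_STATE_CAP) -> BraidWord:
    """A word of minimal length equivalent to the input under the braid moves.

    Breadth-first search over the closure of the input under free
    cancellation, commutation of disjoint generators and the braid relation
    (including its conjugated forms).  Exact for the short words arising in
    this package; for very long inputs the search is truncated at
    ``max_states`` visited words and the best word found is returned.
    """
    start = _greedy_cancel(word.letters)
    best = start
    seen = {start}
    queue: deque[tuple[int, ...]] = deque([start])
    while queue and len(seen) < max_states:
        state = queue.popleft()
        for nxt in _neighbors(state):
            if nxt in seen:
                continue
            seen.add(nxt)
            queue.append(nxt)
            if (len(nxt), nxt) < (len(best), best):
                best = nxt
    return BraidWord(word.n, best)


def minimal_length(word: BraidWord, max_states: int = BFS_STATE_CAP) -> int:
    """Length of the reduced (normal-form) word; a braid invariant."""
    return len(reduce_word(word, max_states=max_states))


# -- complexity index --------------------------------------------------------


def complexity(word: BraidWord, log_base: float = 3.0) -> float:
    """Entanglement complexity C = log_base(#betaE / #E).

    #E is the axis-intersection count of the canonical spanning curve and
    #betaE that of its image under the braid.  Base 3 is the pipeline
    default (four-chain systems); pass ``math.e`` for natural-log values.
    Invariant under the braid moves because it only depends on the induced
    mapping class.
    """
    if word.n < 2:
        return 0.0
    if log_base <= 1:
        raise ValueError("log_base must exceed 1")
    E = canonical_curve(word.n)
    base_count = E.axis_intersections()
    image_count = E.apply_word(word).axis_intersections()
    return math.log(image_count / base_count) / math.log(log_base)


# -- Thurston--Nielsen classification ----------------------------------------


def _full_twist(n: int) -> BraidWord:
    """Delta^2, the full twist generating the center of B_n."""
    half = tuple(range(1, n))
    return BraidWord(n, half * n)


def _round_curve_word(a: int, b: int) -> tuple[int, ...]:
    """Free class of the embedded round curve enclosing punctures a..b.

    Under the Artin convention used here the boundary word is the ascending
    product x_1 x_2 ... x_n, and embedded round curves are the ascending
    subproducts (sigma_i fixes x_i x_{i+1} exactly).
    """
    return tuple(range(a, b + 1))


def _conjugacy_key(w: Sequence[int]) -> tuple[int, ...]:
    w = _cyc_reduce(w)
    if not w:
        return ()
    rots = [tuple(w[i:] + w[:i]) for i in range(len(w))]
    wi = [-x for x in reversed(w)]
    rots += [tuple(wi[i:] + wi[:i]) for i in range(len(wi))]
    return min(rots)


def _invariant_round_family(word: BraidWord) -> bool:
    """Search candidate invariant multicurves made of round curves."""
    n = word.n
    singles = [
        (a, b) for a in range(1, n + 1) for b in range(a + 1, n + 1) if b - a + 1 < n
    ]
    families = [[s] for s in singles]
    for i, s in enumerate(singles):
        for t in singles[i + 1 :]:
            # disjoint (nested or separated) round pairs
            if t[0] > s[1] or (t[0] >= s[0] and t[1] <= s[1]) or (s[0] >= t[0] and s[1] <= t[1]):
                families.append([s, t])
    keys = {s: _conjugacy_key(_round_curve_word(*s)) for s in singles}
    for fam in families:
        fam_keys = {keys[s] for s in fam}
        ok = True
        for s in fam:
            img = _act(word, _round_curve_word(*s))
            if _conjugacy_key(img) not in fam_keys:
                ok = False
                break
        if ok:
            return True
    return False


def _growth_rate(word: BraidWord, iterations: int) -> float:
    """Per-letter growth rate of the canonical curve's crossing count."""
    L = max(1, len(word.letters))
    cur = canonical_curve(word.n)
    counts = [cur.axis_intersections()]
    for _ in range(iterations):
        try:
            cur = cur.apply_word(word)
        except OverflowError:
            break
        counts.append(cur.axis_intersections())
        if counts[-1] > 10**9:
            break
    if len(counts) < 2 or counts[-1] <= counts[0]:
        return 1.0
    # fit over the last half of the run to skip transients
    j = len(counts) // 2
    k = len(counts) - 1
    if counts[j] == 0 or k == j:
        return 1.0
    return (counts[k] / counts[j]) ** (1.0 / ((k - j) * L))


def tn_classify(
    word: BraidWord,
    max_power: int | None = None,
    growth_iterations: int = PA_GROWTH_ITERATIONS,
) -> str:
    """Heuristic Thurston--Nielsen class: "FO", "RE" or "PA".

    Finite-order: some small power of the braid is central (a power of the
    full twist).  Reducible: an invariant multicurve is found among round
    curves and their disjoint pairs.  Pseudo-Anosov: the canonical curve's
    crossing count grows exponentially (per-letter rate above 1 + 1e-3).
    The search is heuristic -- exact train-track classification is out of
    scope -- but exact on the standard exemplars.
    """
    n = word.n
    if n > 4:
        raise ValueError("tn_classify supports braid index <= 4")
    if n == 1:
        return "FO"
    if n == 2:
        # B_2 is infinite cyclic, generated by the half twist: every element
        # is periodic (a power of it is a power of the full twist)
        return "FO"
    if max_power is None:
        max_power = 2 * n
    w_writhe = writhe(word)
    center_writhe = n * (n - 1)
    # finite order: beta^k == Delta^{2m}
    power = BraidWord(n)
    for k in range(1, max_power + 1):
        power = power * word
        total = k * w_writhe
        if total % center_writhe == 0:
            m = total // center_writhe
            target = _full_twist(n) ** m
            try:
                if braid_equal(power, target):
                    return "FO"
            except OverflowError:
                # image words explode: powers stretch curves exponentially,
                # so no power is central
                break
    if _invariant_round_family(word):
        return "RE"
    rate = _growth_rate(word, growth_iterations)
    if rate > 1.0 + PA_GROWTH_TOL:
        return "PA"
    return "RE"


# -- convenience -------------------------------------------------------------


def compute_invariants(word: BraidWord, log_base: float = 3.0) -> BraidInvariants:
    """Writhe, minimal length, complexity and TN class in one record."""
    return BraidInvariants(
        writhe=writhe(word),
        minimal_length=minimal_length(word),
        complexity=complexity(word, log_base=log_base),
        log_base=log_base,
        isotopy_class=tn_classify(word),
    )
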