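# Methods

This note records the models, conventions and numerical choices behind
`braidct`, in enough detail to reproduce or challenge any number the
package computes.

## Curve diagrams and the braid measures

Braid invariants are computed on the n-punctured disk with the punctures on
the real axis.  A curve (or rim-to-rim arc) is carried algebraically as a
word in the free group F_n = ⟨x₁…x_n⟩, with x_j the loop around puncture j;
braid generators act through the Artin automorphisms
σᵢ: xᵢ ↦ xᵢx_{i+1}xᵢ⁻¹, x_{i+1} ↦ xᵢ, the rightmost letter of a braid word
acting on the disk first.  All arithmetic is exact (Python integers, no
geometry).

**Crossing counts.**  The minimal number of transversal intersections of a
curve class with the axis segment in gap k (between punctures k and k+1)
equals the number of stable letters in the Britton-reduced normal form of
the class under the Bass–Serre splitting of F_n along that segment
(F_n = V_k ∗ ⟨t⟩ with t = x_k and V_k containing x_{k+1}x_k in place of
x_{k+1}).  Summing over the n+1 gaps gives the axis-intersection count.
This counting was validated against an exhaustive enumeration of gap
itineraries (every transversal curve is a sequence of half-plane
excursions, each determined by its endpoint gaps, so short classes can be
enumerated outright) and against a numeric polygonal-curve oracle that
applies smooth half-twist homeomorphisms to a polyline and reads off its
crossing sequence.  The numeric oracle also fixes the handedness
dictionary: the package's positive generator corresponds to the clockwise
geometric half-twist under the Artin-compatible labeling.

**Canonical curve E.**  The complexity index C(β) = log_b(#βE / #E) needs a
reference curve.  E is the rim-to-rim spanning arc of class x₁⁻¹x₂⁻¹
(passing over the first two punctures and under the rest), with #E = 2.
This convention is pinned by the worked two-letter braids: σ₁σ₂ stretches E
by exactly 3 and σ₁σ₂⁻¹ by exactly 4, reproducing the natural-log
complexities 1.0986 and 1.3863, and iterating σ₁σ₂⁻¹ stretches E by the
golden ratio squared per period — the known dilatation of that
pseudo-Anosov braid.  Averaged over the eight sign patterns σ₁^±σ₂^±σ₃^±
the base-3 complexity per letter is 0.3462, the saturation value of C/L in
the four-chain bundles.  C is a braid invariant by construction (it
depends only on the induced mapping class).  Note the additive convention
differs from a curve with n−1 initial intersections; only the stretch
*ratio* enters C.  The base defaults to 3 (natural log is used for the
two worked values above).

**LoopCoordinates.**  The public coordinate vector of a curve diagram is
2n−4 integers: the interior per-gap crossing counts t₁…t_{n−1} plus the net
over-passage counts of the interior punctures 2…n−2.  These are derived
summaries of the exact internal word state (a Dynnikov-style chart; the
closed-form piecewise-linear update rules are not used — updates go through
the exact free-group action, which is invertible and arbitrary-precision).

**Minimal length.**  `reduce_word` searches the closure of a word under
free cancellation, commutation of distant generators, the braid relation
and its conjugated forms (σᵢ^e σⱼ^f σᵢ^{−e} = σⱼ^{−e} σᵢ^f σⱼ^e for
|i−j| = 1), breadth-first with a visited cap of 3·10⁵ states.  This yields
the true minimum over that rewriting closure; for the short words arising
here it was verified against exhaustive enumeration (equality decided by
the faithful Artin representation).  Geodesic length in braid groups is
expensive in general; the cap makes long adversarial inputs return a
certified upper bound instead.

**Thurston–Nielsen class (heuristic).**  Finite-order: some power
k ≤ max_power (default 2n) of the braid equals a central power of the full
twist Δ² = (σ₁…σ_{n−1})ⁿ, decided exactly through the Artin representation
(the writhe fixes the only candidate power).  Reducible: an invariant
multicurve is found among round curves enclosing consecutive punctures and
their disjoint pairs (conjugacy tested by cyclic reduction).  Otherwise
pseudo-Anosov when the per-letter growth rate of E's crossing count over up
to 50 applications exceeds 1 + 10⁻³ (integer growth of pA braids is
strictly exponential; FO/RE growth is polynomial).  The iteration stops
early once counts pass 10⁹ or the curve word passes 2·10⁵ letters — both
already certify super-polynomial stretching.  The search is heuristic:
reducible braids whose invariant curves are not round (nor pairs of
rounds) would be reported PA; the exemplars relevant here (σ₁σ₂ and σ₁σ₃
on four strands, the figure-eight braid σ₁σ₂⁻¹ on three, δ and Δ² powers)
are all classified correctly, and B₂ is periodic outright.

## Circuit topology

Contacts are bead pairs within r_c = 1.4 σ (minimum image in periodic
boxes).  Intrachain pairs need backbone separation ≥ 3 bonds, so a
two-bond loop can never count as a contact; an alternative reading — a
separate Euclidean cutoff for intrachain pairs — is exposed as
`ContactConfig.intrachain_rc`.  Contacts are non-saturating (a bead may
join several contacts) and every unordered pair of contacts with four
distinct sites is classified; pairs sharing a site are skipped and counted.
Classification follows the chain-sharing decision tree and is symmetric
under renaming the two contacts.  Subtypes: a loop pair on the same two
chains is `parallel` when the two bridges do not interleave-cross
(site order identical on both chains), else `cross`; a tandem is
`umbrella` when the bridge anchors strictly inside the loop span, else
`arc`.  The ghost-contact string places chains with more sites first,
top-aligns each chain's sites, pads with `O` below, and names the first
site in reading order `A`; class-level information survives the
serialization (recovering the motif from the string is tested against the
direct classifier).  Only class-level fractions enter any quantitative
result; subtypes are informational.

## Bead-spring model

Kremer–Grest in reduced units (m = σ = ε = k_B = 1, τ = σ√(m/ε)):

| parameter | default | note |
| --- | --- | --- |
| FENE K, R₀ | 30 ε/σ², 1.5 σ | standard values; the combination with the LJ repulsion sets the mean bond length ≈ 0.965 σ at T = 1 |
| LJ cutoff | 2.5 σ, shifted | attractive tail retained — cohesion drives aggregation |
| bending | κ·k_BT·(1 − cos θ) | κ is the stiffness control parameter |
| Δt | 0.01 τ | |
| thermostat | Langevin, damping 1 τ | BAOAB splitting; one force evaluation per step |
| box | cubic, side (MN/ρ)^{1/3}, periodic | ρ = 0.01 σ⁻³ default |

The LJ acts between all bead pairs including bonded neighbours.  With the
thermostat off the integrator is plain velocity Verlet; energy drift is
below 10⁻⁴ relative over 10⁴ steps at Δt = 0.002 τ (tested).  Initial
conformations are self-avoiding random walks with 0.97 σ bonds and no pair
closer than 0.9 σ.  Exceeding the FENE radius aborts the run with a
diagnostic rather than silently producing NaNs.

Equilibration uses a sliding-window stationarity criterion: the run
proceeds in chunks (default 100 τ) until the chunk means of R̃_g and C_R
each change by less than tolerance (0.08 / 0.05), with a hard cap
(default 2000 τ).  Production analyses time-average observables and motif
fractions over several frames spanning ~100 τ after stationarity; frames
with fewer than two contacts carry no motif census and are excluded from
the fraction averages (aligned bundles occasionally drift apart for a
frame).  The braid analysis runs on the final frame.

## Primitive path analysis

Endpoints pinned; intrachain interactions reduced to the FENE bonds;
interchain excluded volume kept as a purely repulsive WCA term.  The
minimizer is damped steepest descent with per-bead displacement capped at
0.01 σ per step — far below the bead diameter, which is the no-crossing
guarantee — until the maximum force drops below 10⁻⁴ ε/σ or 10⁵ iterations
pass (the best iterate is returned with a flag when unconverged).  Free
chains contract onto the straight segment joining their endpoints
(contour/end-to-end → 1 within 1 %, tested); interlocked chains cannot,
and keep their crossings.

## Braid extraction

The slicing frame follows the endpoint-plane recipe: seed endpoint
(default: chain 0, first bead — exposed, because the projection and hence
the TN class can depend on it), nearest other-chain endpoint (excluding the
seed chain's other end) spans r₁₂, the endpoint nearest the r₁₂ axis
completes the plane Π, the farthest remaining endpoint fixes the parallel
plane Π′, and the axes are z′ ∥ n, x′ ∥ r₁₂, y′ = z′ × x′.  Collinear
endpoint degeneracies fall back deterministically to the farthest-from-axis
endpoint; with only two chains the z′ axis spans the endpoint midpoints.
Chains are sampled at equally spaced z′ levels (default 10 × beads per
chain) by first intersection of the piecewise-linear path; chains
backtracking along z′ for more than 5 % of their contour are flagged.  An
adjacent exchange of the x′ order between consecutive slices emits one
generator — index from the left position, sign from the y′ order at the
exchange (larger y′ passes over).  Slice gaps with simultaneous exchanges
are bisected recursively (depth 12) before falling back to a deterministic
bubble decomposition; exact x′ ties are broken by a 10⁻⁹ σ perturbation.
Projection-induced σᵢσᵢ⁻¹ pairs vanish under word reduction.

The synthetic bundle generator inverts this: each letter of a prescribed
word becomes a cosine-eased exchange of the two affected strands between
two anchor planes, the over-strand excursing to +y′ by 0.5 σ so over/under
is unambiguous, with a small seeded endpoint jitter keeping the frame
construction non-degenerate.  Round trips through extraction recover
writhe, minimal length and complexity for ≥ 95 % of random words (the
occasional miss is a genuinely projection-sensitive geometry and is what
the backtracking flag reports).

## Desk-scale study conditions

The stiffness sweep defaults mirror the study system: M = 4 chains of
N = 10 beads, T = 1, ρ = 0.01, κ from 0 to 12.  Published-scale ensembles
(Δκ = 0.2, 1000 replicas, 2·10⁴ τ equilibration; N = 30 at 3.5·10⁵ τ) are
far beyond a desk run; the package's own analyses use the endpoints of the
κ range with ~6–20 replicas and the stationarity criterion capped at
1500–2000 τ.  What carries over at this scale: C_R rises from ≈ 1/3 to
≈ 0.85–0.9 between κ = 0 and κ = 12, the interchain motif sum
[L2]+[T3]+[I4] reaches 1 in the aligned phase, the ensemble-mean writhe
stays near zero, and the ratio of ensemble means C̄/L̄ of the extracted
braids sits near 1/3 at high κ.  What does not: smooth κ-resolved curves,
the precise saturation constants, and N = 30 plateau phenomenology all
need the full ensembles.  The synthetic fixtures are idealized (exact
bond-free geometry, no thermal roughness), so passing round-trip tests
demonstrates correctness of the extraction pipeline, not robustness to
every thermally wrinkled conformation — that robustness is what the
backtracking and refinement heuristics address, and their failure modes
are flagged, not hidden.

## Known limitations

* The TN classifier is a heuristic (round-curve search plus growth rate);
  exact train-track classification is out of scope.
* `reduce_word` is exact only within its rewriting closure and state cap.
* The complexity convention is calibrated to the worked two-letter values;
  single-letter braids carry position-dependent C (σ₁ vs σ₃), which washes
  out in ensemble means but makes per-word comparisons of unequal strands
  convention-dependent.
* The combined CT+braid string (`braided_string`) is a serialization
  format only; no computation consumes it.
* The simulator is for ~10²–10³ beads: O(N²) pair loops in numpy, no cell
  lists, no pressure control.
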