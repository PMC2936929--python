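# Methods

## Model

A digested protein is `n` residues; each peptic fragment is a 1-based
inclusive interval `(i, j)`; `K` discretized exchange-rate classes (colors)
are numbered `1..K`, by default slow / medium / fast. The data are the
requirements `b_f^k`: how many residues of fragment `f` were measured to
exchange in class `k`. An assignment `π` of classes to residues has error
`e_f^k = |b_f^k − #{l ∈ f : π(l) = k}|`, and all solvers minimize the total
`Σ_{f,k} e_f^k`. The absolute deviations are linearized in the usual way
(`e ≥ Ay − b`, `e ≥ b − Ay`, minimize `Σe`).

Assumptions worth stating explicitly:

* Class counts are trusted as given; rows whose counts do not sum to the
  fragment length are accepted with a warning — the error terms absorb the
  discrepancy. Upstream steps (uptake extraction, deconvolution of uptake
  curves into class counts, back-exchange correction) are out of scope.
* Residues covered by no fragment receive no prediction.
* Unobservable amides (protein N-terminus, each peptide's first residue)
  are assumed already removed from the input; `load_instance` offers both
  removal conventions as opt-in flags (`drop_protein_n_terminus`,
  `drop_first_residue_per_fragment`) because published descriptions of this
  preprocessing are ambiguous, and proline handling is intentionally left
  to the data producer. Neither flag is on by default.

## Parts and equivalence classes

Residues contained in exactly the same set of fragments form a *part*; no
fragment boundary falls inside a part, so permuting colors within a part
changes no error. Parts are computed as maximal **contiguous** runs of
equal per-residue fragment sets. (A purely set-theoretic definition could
merge non-adjacent runs with identical fragment sets; contiguity is a
refinement that preserves the consecutive-ones property of the inclusion
matrix `A`, on which the fragment-graph construction depends, and leaves
the residue-level solution set unchanged.) Solutions are represented as
per-part color counts `y_p^k` with `Σ_k y_p^k = |p|`; one count matrix
stands for `Π_p |p|!/Π_k y_p^k!` residue-level colorings.

Fragments that share no residue belong to independent subproblems
(connected components of the interval-overlap graph, found by a sweep);
component optima add, which the tests and acceptance script verify.

## Exact solvers

**Part-level ILP.** Integer variables `y_p^k ∈ [0, |p|]` with the linking
equalities and error variables; solved by HiGHS through
`scipy.optimize.milp`. A residue-level binary formulation (`x_i^k`) is kept
as a validation reference; both always agree on the optimum.

**Two-color circulation.** For `K = 2`, substituting
`y_p^2 = |p| − y_p^1` and folding the requirements componentwise into
`b_hi = max(b¹, F − b²)`, `b_lo = min(b¹, F − b²)` leaves a one-variable
LP whose total error decomposes as
`Σ_f (b_hi − b_lo) + 2·(surplus/shortage cost)`. Its constraint matrix is
an interval (consecutive-ones) matrix, hence totally unimodular; the dual
is a minimum-cost circulation on the *fragment graph* with `|P|+1` nodes:
per part a forward/backward arc pair encoding `0 ≤ y_p ≤ |p|`, per
fragment spanning part positions `i..j` the arcs `(i, j+1)` and
`(j+1, i)` of unit capacity and cost `±b`. The circulation is solved with
networkx's network simplex (integer data, exact); node potentials are
recovered by Bellman–Ford on the residual network, and `y_p` is the
difference of neighboring potentials. The published dual derivation
carries typesetting-damaged signs, so the network was re-derived from the
primal LP, which is unambiguous; the arc structure matches the published
description. Among multiple optimal `y` the lexicographically smallest
(by part position) is returned, found by fixing parts left to right with a
binary search per part (the value function of a fixed coordinate is
convex, so the smallest optimal value is found by bisection); this makes
every downstream consumer deterministic.

## Heuristic

For `K > 2`, one color `k` is separated against the merged rest
`(b^k, Σ_{k'≠k} b^{k'})` and the two-color solver fixes the residues given
color `k` (at part granularity); those counts are removed from the part
sizes and the remaining colors are assigned recursively. The merged
right-hand side of later stages is recomputed from the remaining colors'
requirements, so no clamping is ever needed — a choice this package makes
where published descriptions are silent on the post-deletion bookkeeping.
All `K!` orderings are tried for `K ≤ 4` (ties broken by the first
permutation in lexicographic order); beyond that a single
requirement-mass-descending order is used. The reported error is always
re-evaluated on the original instance, never the sum of stage objectives.
The heuristic carries no approximation guarantee, but it can never beat
the optimum, and on noise-free data every stage optimum is zero, so it is
exact there.

## Lagrangian relaxation and branch-&-bound

Dualizing the linking constraints `Σ_k y^k = P` with multipliers `λ`
splits the problem into one subproblem per color:
`min Σ_f |a_f·y − b_f^k| + λ·y` over the box — the same interval structure
as the two-color LP, solved as an integral minimum-cost flow whose node
supplies are the differences `λ̄_i = λ_i − λ_{i−1}`. Then
`z(λ) = Σ_k v_k − λ·P ≤ optimum` for every `λ`. Because the subproblems
are integral, the best dual bound equals the LP relaxation of the
part-level ILP, which the tests check.

Numerical exactness: multipliers are quantized to the dyadic grid
`2⁻¹⁶ℤ` so that, after scaling flow volumes by `2¹⁶`, every subproblem is
an integer min-cost flow solved exactly by network simplex. `z(λ̃)` at the
quantized multiplier is still a valid bound for any `λ̃`, and all reported
bounds are exact dyadic rationals, so ceiling-based pruning needs no
floating-point tolerance.

Subgradient schedule (Held–Karp): `λ⁰ = P`, `θ₀ = 2`,
`μ_ℓ = θ·max(UB − z, 1)/‖Σ_k y^k − P‖²` (the floor of 1 keeps the
iteration moving when the bound already touches the upper bound), `θ`
halved after 20 non-improving iterations, stop at `θ < 10⁻³` or 250
iterations at the root; branch-&-bound children warm-start from the
parent's best `λ` and run at most 25 iterations with patience 5. These
constants are this package's tuning — the subgradient literature leaves
them open — chosen so the bound reliably reaches the LP value on the test
tier at modest cost; bound *validity* never depends on them. A vanishing
subgradient proves the relaxed solution feasible and optimal, and it is
returned as such.

Branching follows the windowed-average rule: over the last 10 subproblem
solutions, pick the variable whose average fractional part is closest to
0.5 (ties: lowest part, then color index) and split its domain at the
floor of the average (`≤ v` / `≥ v+1`); integral variables are branched
the same way, which is what makes enumeration of *all* optima possible.

## Enumeration of all optimal solutions

Both enumerators (LP-relaxation-based and Lagrangian) share the same
outer scheme: depth-first over variable boxes, pruning any box whose lower
bound exceeds the error bound, with `"auto"` meaning the optimum is
computed first and enumeration runs at exactly that bound. Two
engineering layers keep this fast without affecting exactness:

* a *cheap interval bound*: per fragment and color the achievable count
  inside a box is an interval, so `Σ max(0, b − hi, lo − b)` lower-bounds
  any completion; boxes are also *shaved* by value forcing (if pinning a
  variable at its domain edge pushes this bound past the error bound, the
  edge value is impossible and the domain shrinks);
* once a box's linking-feasible point count drops below 2·10⁶, the
  expensive bounds stop and an exact depth-first sweep finishes it,
  fixing one part's whole count row per level and pruning prefixes with
  the same interval bound.

Solutions are deduplicated by the serialized count matrix and returned in
row-major lexicographic order, identical across both enumerators — a
cross-solver identity the acceptance suite asserts on 200 instances.

## Consensus and agreement scoring

Over an enumerated solution set: *single* takes the first solution in
canonical order; *majority* apportions each part's `|p|` residue slots to
colors by largest remainder on the (optionally expansion-weighted) summed
counts, ties to the lower color index; *mean* expands each solution's
part counts into sorted per-slot color ordinals, averages per slot, and
rounds half-to-even back to a color. The published comparison never
defines its averaging operationally; these constructions are this
package's concrete choices and are tagged in the output metadata. Default
weighting is one vote per equivalence class, with expansion weighting
available, since "all solutions" is ambiguous between classes and
expanded colorings.

Agreement with per-residue reference rates is scored per part as the
multiset intersection between predicted and reference color counts —
within a part residues are mutually exchangeable, so only counts are
comparable; residues without reference data are excluded from numerator
and denominator. Raw rates in h⁻¹ discretize at slow ≤ 0.1 and
fast ≥ 8, boundaries inclusive toward the extreme classes.

## Synthetic data

The generator emulates the *shape* of real combined digests: consecutive
fragments with Poisson-distributed lengths around a configurable mean,
several overlaid independent digests (the overlap between digests is what
creates small parts), random fragment dropout, planted per-residue classes
drawn from frequencies (0.4, 0.3, 0.3) for slow/medium/fast (a fixed,
configurable choice; no empirical distribution is available), and
requirements counted exactly from the planted coloring. Noise is discrete
count swapping — `noise_moves` times, one unit of count moves between two
classes of a random fragment — because the physical inputs are integer
class counts, making a unit swap the smallest meaningful corruption; each
move perturbs at most two requirement entries by one, so the planted
coloring's error (and the optimum) is at most `2·noise_moves`, a bound the
tests assert.

What the generator does **not** emulate: correlated errors from
back-exchange, rate-class misassignment near discretization boundaries,
missing fragments biased by sequence composition, and real digestion-site
specificity. Passing tests therefore certify the *solvers* (exactness,
completeness, bounds) and the pipeline's behavior under bounded integer
noise, not recovery performance on real spectra.

Two fixed batteries drive tests and the acceptance script: an oracle tier
(n ≤ 12, ≤ 6 fragments, K = 3, mixed noise 0–3) small enough for
exhaustive `3^n` cross-checks, and a digest-scale tier
(n ∈ [74, 152], 18–49 fragments, noise 0–12) matching the size range of
real combined-digest datasets. Problem sizes were chosen so the full
verification battery (200 oracle-tier + 12 scale-tier instances) solves
in minutes on one CPU.

## Integrality-gap witness search

For `K ≥ 3` the constraint matrix is not totally unimodular and instances
exist whose LP relaxation is 0 while the integer optimum is positive. The
package ships a deterministic search for such a witness on the classic
seven-part, four-fragment example layout ((1,3), (2,5), (3,6), (5,7) in
part positions): exhaustive over all consistent right-hand sides at unit
part sizes, then over part sizes up to 2 via the algebra of fractional
patterns (the fractional parts of an exact fractional solution must cancel
within every fragment, which on this layout leaves three free per-part
patterns) with denominators up to 6. The search is certified in both
directions — LP feasibility by an exact LP solve, integral infeasibility
by exhaustive coloring enumeration. On this particular layout the search
space contains **no** witness (the acceptance test for it is accordingly
expected to fail); gap instances for interval-constrained 3-coloring
appear to require richer overlap structure than four fragments provide.
The search machinery itself is exercised and correct, and documents
exactly which space was exhausted.

## Numerical and degenerate-input choices

* All counts, errors and bounds are integers end to end; the only real
  arithmetic is the (dyadic, exact) multiplier algebra and LP relaxation
  values, compared with an absolute tolerance of 10⁻⁶ in branching and
  never in results.
* Empty fragment lists, uncovered residues, length-1 parts, and
  requirement rows exceeding fragment lengths are all legal inputs with
  defined behavior (tested).
* Determinism: identical inputs give byte-identical outputs across runs —
  lexicographic tie-breaks in the flow solver, fixed orderings in the
  heuristic, canonical solution ordering in both enumerators, and no
  wall-clock anywhere in results.

## Known limitations

* The heuristic's stage-fixing can lock in a misassignment on noisy data;
  it reached the optimum on 100 % of the current noisy oracle tier, but no
  ratio is guaranteed.
* Enumeration is exponential in the worst case; the practical limit is the
  number of optimal classes, not `n` (digest-scale instances with ~10⁵
  classes are fine; adversarial inputs with astronomically many optima are
  not meaningfully enumerable by any method).
* Consensus definitions (largest remainder, ordinal rounding) are
  reasonable but not canonical; alternatives would change Table-style
  agreement percentages by a few points either way.
* `K > 4` is supported by all solvers but the heuristic then tries only
  one ordering, and no benchmark tier exercises it.
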