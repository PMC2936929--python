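"""Exact solving and exhaustive enumeration via integer linear programming.

Two formulations of the minimum-total-error problem are provided:

* *basic*: one binary ``x_i^k`` per covered residue and class, with
  ``sum_k x_i^k = 1`` -- its solutions are residue-level colorings.
* *improved*: one integer ``y_p^k`` in ``[0, |p|]`` per part and class,
  with ``sum_k y_p^k = |p|`` -- its solutions are equivalence classes of
  colorings (within-part permutations collapsed), typically far fewer.

Both carry per fragment x class error variables ``e_f^k`` linked by
``e >= A y - b`` and ``e >= b - A y`` so that the LP objective equals the
sum of absolute deviations.

A single optimal solution comes from the HiGHS MILP backend
(:func:`scipy.optimize.milp`).  Enumerating *all* solutions within an error
bound uses a custom branch-&-bound over the count variables with LP
relaxations (HiGHS) for pruning: branching explores both halves of a split
variable domain, infeasible or bound-exceeding relaxations are pruned, and
every fully fixed leaf inside the bound is recorded.  The enumeration logic
is deliberately backend-agnostic (no solver solution pools) so the returned
solution sets are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import (
    CountSolution,
    Instance,
    Partition,
    ResidueAssignment,
    ValidationError,
    compute_parts,
    count_expansions,
    error_from_counts,
    part_matrix,
)

__all__ = ["SolutionSet", "solve_min_error", "enumerate_optimal"]

_EPS = 1e-6


@dataclass
class SolutionSet:
    """All minimum-error (or bounded-error) solutions of an instance.

    ``solutions`` holds part-level :class:`CountSolution` objects for the
    improved formulation or residue-level :class:`ResidueAssignment`
    objects for the basic one; ``multiplicities`` gives the number of
    residue-level colorings each entry represents (always 1 at residue
    level).
    """

    optimum: int
    formulation: str
    solutions: list = field(default_factory=list)
    multiplicities: list[int] = field(default_factory=list)

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    @property
    def n_expanded(self) -> int:
        return int(sum(self.multiplicities))

    def keys(self) -> set[tuple]:
        out = set()
        for s in self.solutions:
            arr = s.y if isinstance(s, CountSolution) else s.colors
            out.add(tuple(map(int, np.ravel(arr))))
        return out


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------


def _improved_matrices(instance: Instance, partition: Partition):
    """Constraint system of the improved (part-level) formulation.

    Variables are ``[y (m*K, color-major), e (F*K)]``; returns the
    inequality system ``A_ub z <= b_ub`` (error links), the linking
    equalities ``A_eq z = P`` and the integer variable count.
    """
    A = part_matrix(instance, partition)
    m = partition.n_parts
    F = instance.n_fragments
    K = instance.K
    n_y = m * K
    n_e = F * K
    blocks_ub = []
    b_ub = []
    for k in range(K):
        Ay = sp.lil_matrix((F, n_y + n_e))
        Ay[:, k * m : (k + 1) * m] = A
        Ie = sp.lil_matrix((F, n_y + n_e))
        Ie[:, n_y + k * F : n_y + (k + 1) * F] = -sp.eye(F)
        blocks_ub.append((Ay + Ie).tocsr())          # A y - e <= b
        b_ub.extend(instance.requirements[:, k])
        blocks_ub.append((-Ay + Ie).tocsr())         # -A y - e <= -b
        b_ub.extend(-instance.requirements[:, k])
    A_ub = sp.vstack(blocks_ub, format="csr") if blocks_ub else sp.csr_matrix((0, n_y + n_e))
    b_ub = np.array(b_ub, dtype=float)

    A_eq = sp.lil_matrix((m, n_y + n_e))
    for k in range(K):
        A_eq[:, k * m : (k + 1) * m] += sp.eye(m)
    A_eq = A_eq.tocsr()
    b_eq = partition.sizes.astype(float)

    c = np.concatenate([np.zeros(n_y), np.ones(n_e)])
    y_upper = np.tile(partition.sizes, K).astype(float)
    e_upper = np.full(n_e, np.inf)
    return A_ub, b_ub, A_eq, b_eq, c, y_upper, e_upper, n_y


def _basic_matrices(instance: Instance):
    """Constraint system of the basic (residue-level) formulation."""
    covered = np.flatnonzero(instance.covered_mask())  # 0-based residues
    pos = {r: i for i, r in enumerate(covered)}
    n_cov = len(covered)
    F = instance.n_fragments
    K = instance.K
    n_x = n_cov * K
    n_e = F * K
    R = sp.lil_matrix((F, n_cov))
    for fi, f in enumerate(instance.fragments):
        for r in range(f.start - 1, f.end):
            R[fi, pos[r]] = 1
    R = R.tocsr()
    blocks_ub = []
    b_ub = []
    for k in range(K):
        Rx = sp.lil_matrix((F, n_x + n_e))
        Rx[:, k * n_cov : (k + 1) * n_cov] = R
        Ie = sp.lil_matrix((F, n_x + n_e))
        Ie[:, n_x + k * F : n_x + (k + 1) * F] = -sp.eye(F)
        blocks_ub.append((Rx + Ie).tocsr())
        b_ub.extend(instance.requirements[:, k])
        blocks_ub.append((-Rx + Ie).tocsr())
        b_ub.extend(-instance.requirements[:, k])
    A_ub = sp.vstack(blocks_ub, format="csr") if blocks_ub else sp.csr_matrix((0, n_x + n_e))
    b_ub = np.array(b_ub, dtype=float)
    A_eq = sp.lil_matrix((n_cov, n_x + n_e))
    for k in range(K):
        A_eq[:, k * n_cov : (k + 1) * n_cov] += sp.eye(n_cov)
    A_eq = A_eq.tocsr()
    b_eq = np.ones(n_cov)
    c = np.concatenate([np.zeros(n_x), np.ones(n_e)])
    x_upper = np.ones(n_x)
    e_upper = np.full(n_e, np.inf)
    return A_ub, b_ub, A_eq, b_eq, c, x_upper, e_upper, n_x, covered


# ---------------------------------------------------------------------------
# single optimum
# ---------------------------------------------------------------------------


def solve_min_error(instance: Instance, formulation: str = "improved"):
    """Minimum total error and one attaining solution.

    Returns ``(optimum, CountSolution)`` for the improved formulation or
    ``(optimum, ResidueAssignment)`` for the basic one.  The optimum is
    the minimum of the summed absolute deviations over all colorings of
    the covered residues.
    """
    if formulation not in ("improved", "basic"):
        raise ValidationError(f"unknown formulation {formulation!r}")
    partition = compute_parts(instance)
    if instance.n_fragments == 0:
        if formulation == "improved":
            return 0, CountSolution(np.zeros((0, instance.K), dtype=np.int64))
        return 0, ResidueAssignment(np.zeros(instance.n, dtype=np.int64))

    if formulation == "improved":
        A_ub, b_ub, A_eq, b_eq, c, v_up, e_up, n_v = _improved_matrices(instance, partition)
    else:
        A_ub, b_ub, A_eq, b_eq, c, v_up, e_up, n_v, covered = _basic_matrices(instance)

    constraints = [
        LinearConstraint(A_ub, -np.inf, b_ub),
        LinearConstraint(A_eq, b_eq, b_eq),
    ]
    integrality = np.concatenate([np.ones(n_v), np.zeros(len(c) - n_v)])
    bounds = Bounds(lb=np.zeros(len(c)), ub=np.concatenate([v_up, e_up]))
    res = milp(c=c, constraints=constraints, integrality=integrality, bounds=bounds)
    if res.status != 0:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"MILP backend failed: {res.message}")
    optimum = int(round(res.fun))
    v = np.rint(res.x[:n_v]).astype(np.int64)
    if formulation == "improved":
        m = partition.n_parts
        y = v.reshape(instance.K, m).T
        solution = CountSolution(y)
        assert error_from_counts(instance, partition, solution).total == optimum
        return optimum, solution
    n_cov = n_v // instance.K
    x = v.reshape(instance.K, n_cov).T
    colors = np.zeros(instance.n, dtype=np.int64)
    for i, r in enumerate(covered):
        colors[r] = int(np.argmax(x[i])) + 1
    return optimum, ResidueAssignment(colors)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _enumerate(instance, partition, bound, formulation):
    """Branch-&-bound enumeration of every solution with error <= bound."""
    if formulation == "improved":
        A_ub, b_ub, A_eq, b_eq, c, v_up, e_up, n_v = _improved_matrices(instance, partition)
        covered = None
    else:
        A_ub, b_ub, A_eq, b_eq, c, v_up, e_up, n_v, covered = _basic_matrices(instance)
    n_all = len(c)

    # cap on total error prunes the relaxation directly
    A_ub = sp.vstack([A_ub, sp.csr_matrix(c)], format="csr")
    b_ub = np.append(b_ub, float(bound))

    # dense helpers for the cheap interval bound evaluated before each LP
    K = instance.K
    if formulation == "improved":
        A_dense = part_matrix(instance, partition)
        sizes = partition.sizes
    else:
        A_dense = np.zeros((instance.n_fragments, n_v // K), dtype=np.int64)
        for fi, f in enumerate(instance.fragments):
            for i, r in enumerate(covered):
                if f.start - 1 <= r <= f.end - 1:
                    A_dense[fi, i] = 1
        sizes = np.ones(n_v // K, dtype=np.int64)
    b_req = instance.requirements.T  # (K, F)

    def interval_bound(lo, up):
        """Lower bound on the error inside a box; inf if linking infeasible.

        Per fragment and color the achievable count range is an interval,
        so ``max(0, b - hi, lo - b)`` summed is a valid relaxation bound.
        """
        Lo = lo.reshape(K, -1)
        Up = up.reshape(K, -1)
        if (Lo.sum(axis=0) > sizes).any() or (Up.sum(axis=0) < sizes).any():
            return np.inf
        S_lo = Lo @ A_dense.T
        S_hi = Up @ A_dense.T
        return int(np.maximum(0, np.maximum(b_req - S_hi, S_lo - b_req)).sum())

    n_units = n_v // K

    def feasible_rows(p: int, lo, up) -> np.ndarray:
        """All (y_p^1..y_p^K) in the box with sum = |p| (compositions)."""
        target = int(sizes[p])
        cols = [int(lo[k * n_units + p]) for k in range(K)]
        colu = [int(up[k * n_units + p]) for k in range(K)]
        rows = [[]]
        for k in range(K):
            nxt = []
            for prefix in rows:
                rem = target - sum(prefix)
                rest_max = sum(colu[k + 1 :])
                rest_min = sum(cols[k + 1 :])
                lo_k = max(cols[k], rem - rest_max)
                hi_k = min(colu[k], rem - rest_min)
                for v in range(lo_k, hi_k + 1):
                    nxt.append(prefix + [v])
            rows = nxt
        return np.array(rows, dtype=np.int64).reshape(len(rows), K)

    def enumerate_box(lo, up, record) -> None:
        """Exact depth-first sweep of a box, one part row at a time.

        Fixing whole parts left to right makes fragment errors exact
        quickly, so the interval bound prunes prefixes sharply; only
        linking-feasible completions within the bound are recorded.
        """
        per_part = [feasible_rows(p, lo, up) for p in range(n_units)]
        if any(len(r) == 0 for r in per_part):
            return
        cur_lo = lo.copy()
        cur_up = up.copy()

        def fix_part(p, row):
            for k in range(K):
                cur_lo[k * n_units + p] = row[k]
                cur_up[k * n_units + p] = row[k]

        def unfix_part(p):
            for k in range(K):
                cur_lo[k * n_units + p] = lo[k * n_units + p]
                cur_up[k * n_units + p] = up[k * n_units + p]

        def rec(p):
            if p == n_units:
                record(cur_lo.copy())
                return
            for row in per_part[p]:
                fix_part(p, row)
                if interval_bound(cur_lo, cur_up) <= bound:
                    rec(p + 1)
            unfix_part(p)

        rec(0)

    _BATCH = 2_000_000

    found: dict[tuple, np.ndarray] = {}

    def record(flat: np.ndarray) -> None:
        found[tuple(map(int, flat))] = np.asarray(flat, dtype=np.int64).copy()

    root = (np.zeros(n_v, dtype=np.int64), v_up.astype(np.int64).copy())
    stack = [root]
    while stack:
        lo, up = stack.pop()
        cheap = interval_bound(lo, up)
        if cheap > bound:
            continue
        free = np.flatnonzero(lo < up)
        if free.size == 0:
            # fully fixed: evaluate exactly, no LP needed (linking was
            # checked inside interval_bound)
            Lo = lo.reshape(K, -1)
            err = int(np.abs(b_req - Lo @ A_dense.T).sum())
            if err <= bound:
                record(lo)
            continue
        n_combos = 1
        for p in range(n_units):
            n_combos *= max(len(feasible_rows(p, lo, up)), 1)
            if n_combos > _BATCH:
                break
        if n_combos <= _BATCH:
            enumerate_box(lo, up, record)
            continue
        bounds = [(float(l), float(u)) for l, u in zip(lo, up)] + [
            (0.0, np.inf)
        ] * (n_all - n_v)
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if res.status == 2:  # infeasible: no solution within bound in this box
            continue
        if res.status != 0:  # pragma: no cover
            raise RuntimeError(f"LP backend failed: {res.message}")
        if math.ceil(res.fun - _EPS) > bound:
            continue
        v = res.x[:n_v]
        frac = v - np.floor(v)
        fractional = free[(frac[free] > _EPS) & (frac[free] < 1 - _EPS)]
        if fractional.size:
            # fractional part closest to 0.5; ties by lowest variable index
            dist = np.abs(frac[fractional] - 0.5)
            j = int(fractional[np.lexsort((fractional, dist))[0]])
            split = int(math.floor(v[j]))
        else:
            # integral relaxation: split the lowest-index free variable at
            # its LP value to guarantee progress
            j = int(free[0])
            split = int(round(v[j]))
            if split >= up[j]:
                split = int(up[j]) - 1
        split = min(max(split, int(lo[j])), int(up[j]) - 1)
        left_lo, left_up = lo.copy(), up.copy()
        left_up[j] = split
        right_lo, right_up = lo.copy(), up.copy()
        right_lo[j] = split + 1
        stack.append((right_lo, right_up))
        stack.append((left_lo, left_up))
    return found


def enumerate_optimal(
    instance: Instance,
    error_bound: int | str = "auto",
    formulation: str = "improved",
) -> SolutionSet:
    """All solutions with total error <= ``error_bound``.

    ``error_bound="auto"`` first computes the optimum and enumerates
    exactly the minimum-error solutions (the canonical solution count).
    A bound below the optimum yields an empty set.  Solutions are returned
    in canonical (row-major lexicographic) order, deduplicated, with
    within-part expansion multiplicities attached at the improved level.
    """
    if formulation not in ("improved", "basic"):
        raise ValidationError(f"unknown formulation {formulation!r}")
    partition = compute_parts(instance)
    if error_bound == "auto":
        error_bound, _ = solve_min_error(instance, formulation="improved")
    error_bound = int(error_bound)
    if error_bound < 0:
        return SolutionSet(optimum=error_bound, formulation=formulation)
    if instance.n_fragments == 0:
        sol = (CountSolution(np.zeros((0, instance.K), dtype=np.int64))
               if formulation == "improved"
               else ResidueAssignment(np.zeros(instance.n, dtype=np.int64)))
        return SolutionSet(optimum=0, formulation=formulation,
                           solutions=[sol], multiplicities=[1])

    found = _enumerate(instance, partition, error_bound, formulation)
    m = partition.n_parts
    solutions = []
    multiplicities = []
    errors = []
    covered = np.flatnonzero(instance.covered_mask())

    def canonical_key(v):
        # row-major y (or colors) order, shared with the Lagrangian enumerator
        if formulation == "improved":
            return tuple(map(int, v.reshape(instance.K, m).T.ravel()))
        return tuple(map(int, v))

    for key in sorted(found, key=lambda kk: canonical_key(found[kk])):
        v = found[key]
        if formulation == "improved":
            y = v.reshape(instance.K, m).T
            sol = CountSolution(y)
            errors.append(error_from_counts(instance, partition, sol).total)
            solutions.append(sol)
            multiplicities.append(count_expansions(partition, sol))
        else:
            x = v.reshape(instance.K, len(covered)).T
            colors = np.zeros(instance.n, dtype=np.int64)
            for i, r in enumerate(covered):
                colors[r] = int(np.argmax(x[i])) + 1
            sol = ResidueAssignment(colors)
            from .model import evaluate_assignment

            errors.append(evaluate_assignment(instance, sol).total)
            solutions.append(sol)
            multiplicities.append(1)
    optimum = min(errors) if errors else error_bound
    return SolutionSet(optimum=int(optimum), formulation=formulation,
                       solutions=solutions, multiplicities=multiplicities)
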