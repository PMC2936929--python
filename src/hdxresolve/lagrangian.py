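"""Lagrangian-relaxation bounds and an ILP-free branch-&-bound enumerator.

Dualizing the linking constraints ``sum_k y_p^k = |p|`` of the part-level
formulation with multipliers ``lambda`` splits the problem into one
independent subproblem per rate class k:

    min  sum_f |a_f . y^k - b_f^k|  +  lambda . y^k,    0 <= y^k <= P,

each an integral minimum-cost flow on the fragment graph (the node
supplies are the differences of consecutive multipliers).  For every
multiplier vector

    z(lambda) = sum_k v_k(lambda) - lambda . P

is a lower bound on the minimum total error.  The dual is maximized by the
Held-Karp subgradient iteration lambda <- lambda + mu (sum_k y^k - P) with
step length mu = theta (UB - z) / ||sum_k y^k - P||^2, theta halved after a
stretch of non-improving iterations.  Because the subproblems are integral
the converged bound matches the LP relaxation of the part-level ILP.

The branch-&-bound enumerator uses these bounds (plus a cheap per-fragment
interval bound) to find *all* solutions within an error bound without any
LP/ILP backend; its solution sets are identical to the ILP enumerator's.

Multipliers are quantized to a dyadic grid (see
:data:`hdxresolve.flow.LAMBDA_SCALE`) so every subproblem is an
integer-cost flow solved exactly and every reported z(lambda) is an exact
dyadic rational -- a certified bound, never a float estimate.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .model import (
    CountSolution,
    Instance,
    ValidationError,
    compute_parts,
    count_expansions,
    error_from_counts,
    fragment_part_spans,
    part_matrix,
)
from .flow import LAMBDA_SCALE, min_cost_interval_flow
from .heuristic import heuristic_solve
from .ilp import SolutionSet

__all__ = [
    "InfeasibleBox",
    "LagrangianState",
    "SubgradientSchedule",
    "lagrangian_subproblem",
    "evaluate_dual",
    "subgradient_optimize",
    "branch_and_bound_enumerate",
    "solve_min_error_bnb",
]


class InfeasibleBox(Exception):
    """Branch bounds admit no solution (lower > upper): prune the node."""


@dataclass
class SubgradientSchedule:
    """Held-Karp step-size schedule parameters.

    theta starts at ``theta0`` and is halved whenever the best Lagrangian
    bound has not improved for ``patience`` consecutive iterations; the
    iteration stops when theta falls below ``theta_min`` or after
    ``max_iterations`` steps.  ``history`` is the window of recent
    subproblem solutions used by the branching rule.
    """

    theta0: float = 2.0
    theta_min: float = 1e-3
    patience: int = 20
    max_iterations: int = 250
    history: int = 10


#: schedule used at branch-&-bound child nodes (warm-started from the parent)
CHILD_SCHEDULE = SubgradientSchedule(patience=5, max_iterations=25)


@dataclass
class LagrangianState:
    """State of one subgradient run."""

    lam: np.ndarray
    theta: float
    UB: float
    best_bound: float = -math.inf
    best_lam: np.ndarray | None = None
    iteration: int = 0
    history: deque = field(default_factory=lambda: deque(maxlen=10))
    feasible_y: np.ndarray | None = None  # set when the subgradient hits 0

    @property
    def lam_bar(self) -> np.ndarray:
        """Node supplies: differences of consecutive multipliers."""
        m = len(self.lam)
        bar = np.zeros(m + 1)
        if m:
            bar[0] = self.lam[0]
            bar[1:m] = self.lam[1:] - self.lam[:-1]
            bar[m] = -self.lam[m - 1]
        return bar


class _Context:
    """Precomputed partition geometry shared by all Lagrangian calls."""

    def __init__(self, instance: Instance):
        self.instance = instance
        self.partition = compute_parts(instance)
        self.caps = self.partition.sizes
        self.spans = (
            fragment_part_spans(instance, self.partition)
            if instance.n_fragments
            else []
        )
        self.A = part_matrix(instance, self.partition)
        self.K = instance.K
        self.m = self.partition.n_parts


def _quantize(lam) -> np.ndarray:
    return np.rint(np.asarray(lam, dtype=float) * LAMBDA_SCALE) / LAMBDA_SCALE


def _subproblem(ctx: _Context, lam, k0: int, lower, upper):
    b = ctx.instance.requirements[:, k0]
    return min_cost_interval_flow(
        ctx.caps, ctx.spans, b, b, lam=lam, lower=lower, upper=upper
    )


def lagrangian_subproblem(instance: Instance, lam, k: int, bounds=None):
    """Optimal ``(y^k, value)`` of the color-k relaxed subproblem.

    ``bounds`` is an optional ``(lower, upper)`` pair of per-part integer
    vectors restricting ``y^k`` (branch-&-bound node bounds); inconsistent
    bounds raise :class:`InfeasibleBox`.  The value is exact for the
    dyadic-quantized multipliers.
    """
    if not (1 <= k <= instance.K):
        raise ValidationError(f"color index {k} out of range 1..{instance.K}")
    ctx = _Context(instance)
    lower, upper = _check_bounds(ctx, bounds)
    value, y = _subproblem(ctx, lam, k - 1, lower, upper)
    return y, value


def _check_bounds(ctx: _Context, bounds):
    if bounds is None:
        return None, None
    lower = np.asarray(bounds[0], dtype=np.int64)
    upper = np.asarray(bounds[1], dtype=np.int64)
    if (lower > upper).any():
        raise InfeasibleBox
    return lower, upper


def evaluate_dual(instance: Instance, lam, bounds=None) -> float:
    """The Lagrangian function z(lambda): a lower bound on the optimum."""
    ctx = _Context(instance)
    z, _ = _evaluate_dual_ctx(ctx, lam, bounds)
    return z


def _evaluate_dual_ctx(ctx: _Context, lam, bounds=None):
    lamq = _quantize(lam)
    total = 0.0
    ys = np.zeros((ctx.m, ctx.K), dtype=np.int64)
    if bounds is None:
        lower = upper = None
    else:
        lower, upper = bounds
    for k0 in range(ctx.K):
        lk = lower[:, k0] if lower is not None else None
        uk = upper[:, k0] if upper is not None else None
        v, y = _subproblem(ctx, lamq, k0, lk, uk)
        total += v
        ys[:, k0] = y
    z = total - float(lamq @ ctx.caps)
    return z, ys


def subgradient_optimize(
    instance: Instance,
    UB: float | None = None,
    schedule: SubgradientSchedule | None = None,
    lam0=None,
    bounds=None,
):
    """Maximize the Lagrangian dual by Held-Karp subgradient steps.

    Returns the final :class:`LagrangianState`; ``state.best_bound`` is the
    sharpest certified lower bound found and ``state.feasible_y`` a
    solution proven optimal when the subgradient vanished (the relaxed
    solution then satisfies the linking constraints and its error equals
    the bound).

    ``UB`` defaults to the best-of-all-orderings heuristic error;
    ``lam0`` defaults to the part-size vector P, which the dual converges
    from quickly.
    """
    ctx = instance if isinstance(instance, _Context) else _Context(instance)
    schedule = schedule or SubgradientSchedule()
    if UB is None:
        _, UB = heuristic_solve(ctx.instance)
    lam = np.asarray(
        lam0 if lam0 is not None else ctx.caps, dtype=float
    ).copy()
    state = LagrangianState(lam=lam, theta=schedule.theta0, UB=float(UB))
    state.history = deque(maxlen=schedule.history)
    if ctx.m == 0:
        state.best_bound = 0.0
        state.best_lam = lam
        state.feasible_y = np.zeros((0, ctx.K), dtype=np.int64)
        return state
    stall = 0
    while state.iteration < schedule.max_iterations and state.theta >= schedule.theta_min:
        try:
            z, ys = _evaluate_dual_ctx(ctx, state.lam, bounds)
        except InfeasibleBox:
            state.best_bound = math.inf
            return state
        state.iteration += 1
        state.history.append(ys)
        if z > state.best_bound:
            state.best_bound = z
            state.best_lam = state.lam.copy()
            stall = 0
        else:
            stall += 1
            if stall >= schedule.patience:
                state.theta /= 2.0
                stall = 0
        g = ys.sum(axis=1) - ctx.caps
        norm2 = float(g @ g)
        if norm2 == 0.0:
            # relaxation optimum satisfies the linking constraints:
            # z equals the true error of ys, so ys is proven optimal
            state.feasible_y = ys
            state.best_bound = max(state.best_bound, z)
            state.best_lam = state.lam.copy()
            return state
        mu = state.theta * max(state.UB - z, 1.0) / norm2
        state.lam = state.lam + mu * g
    return state


# ---------------------------------------------------------------------------
# branch & bound enumeration
# ---------------------------------------------------------------------------


def _interval_bound(ctx: _Context, lower, upper):
    """Cheap per-fragment interval bound; inf when linking is infeasible."""
    if (lower.sum(axis=1) > ctx.caps).any() or (upper.sum(axis=1) < ctx.caps).any():
        return math.inf
    S_lo = ctx.A @ lower  # (F, K)
    S_hi = ctx.A @ upper
    b = ctx.instance.requirements
    return int(np.maximum(0, np.maximum(b - S_hi, S_lo - b)).sum())


def _feasible_rows(ctx: _Context, p: int, lower, upper) -> np.ndarray:
    target = int(ctx.caps[p])
    rows = [[]]
    for k in range(ctx.K):
        nxt = []
        rest_min = int(lower[p, k + 1 :].sum())
        rest_max = int(upper[p, k + 1 :].sum())
        for prefix in rows:
            rem = target - sum(prefix)
            lo_k = max(int(lower[p, k]), rem - rest_max)
            hi_k = min(int(upper[p, k]), rem - rest_min)
            for v in range(lo_k, hi_k + 1):
                nxt.append(prefix + [v])
        rows = nxt
    return np.array(rows, dtype=np.int64).reshape(len(rows), ctx.K)


_BATCH = 2_000_000


def _dfs_enumerate(ctx: _Context, lower, upper, bound: int, record) -> None:
    """Exact depth-first sweep of a box, part by part.

    Each level fixes one part's full count row (a composition of |p|);
    prefixes whose interval bound already exceeds the error bound are
    pruned.  Fragments are intervals, so fixing parts left to right makes
    fragment errors exact quickly and the pruning sharp.
    """
    rows = [_feasible_rows(ctx, p, lower, upper) for p in range(ctx.m)]
    if any(len(r) == 0 for r in rows):
        return
    lo = lower.copy()
    up = upper.copy()

    def rec(p: int) -> None:
        if p == ctx.m:
            record(lo.copy())
            return
        for r in rows[p]:
            lo[p] = r
            up[p] = r
            if _interval_bound(ctx, lo, up) <= bound:
                rec(p + 1)
        lo[p] = lower[p]
        up[p] = upper[p]

    rec(0)


def _sweep_box(ctx: _Context, lower, upper, bound: int, record) -> None:
    _dfs_enumerate(ctx, lower, upper, bound, record)


def _box_size(ctx: _Context, lower, upper) -> int:
    total = 1
    for p in range(ctx.m):
        total *= max(len(_feasible_rows(ctx, p, lower, upper)), 1)
        if total > _BATCH:
            return total
    return total


def _shave_box(ctx: _Context, lower, upper, bound: int):
    """Tighten per-variable bounds by value forcing against the interval bound.

    For each variable, if forcing it to its current lower (upper) value
    already drives the relaxation bound past the error bound, that value
    can hold no solution within the bound and the domain edge moves in.
    Repeats to a fixpoint; returns None when a domain empties.  Sound
    because the interval bound is a valid lower bound on any completion.
    """
    lower = lower.copy()
    upper = upper.copy()
    changed = True
    while changed:
        changed = False
        for p in range(ctx.m):
            for k in range(ctx.K):
                while lower[p, k] < upper[p, k]:
                    save = upper[p, k]
                    upper[p, k] = lower[p, k]
                    bad = _interval_bound(ctx, lower, upper) > bound
                    upper[p, k] = save
                    if not bad:
                        break
                    lower[p, k] += 1
                    changed = True
                while upper[p, k] > lower[p, k]:
                    save = lower[p, k]
                    lower[p, k] = upper[p, k]
                    bad = _interval_bound(ctx, lower, upper) > bound
                    lower[p, k] = save
                    if not bad:
                        break
                    upper[p, k] -= 1
                    changed = True
    if _interval_bound(ctx, lower, upper) > bound:
        return None
    return lower, upper


def _select_branch_variable(ctx: _Context, lower, upper, history):
    """Variable whose windowed average is closest to half-integral."""
    free = (lower < upper)
    if not free.any():
        return None
    if history:
        avg = np.mean([h.astype(float) for h in history], axis=0)
    else:
        avg = (lower + upper) / 2.0
    frac = avg - np.floor(avg)
    score = np.abs(frac - 0.5)
    score[~free] = math.inf
    p, k = np.unravel_index(int(np.argmin(score)), score.shape)
    split = int(math.floor(avg[p, k]))
    split = min(max(split, int(lower[p, k])), int(upper[p, k]) - 1)
    return int(p), int(k), split


def branch_and_bound_enumerate(
    instance: Instance,
    error_bound: int | str = "auto",
    root_schedule: SubgradientSchedule | None = None,
) -> SolutionSet:
    """All solutions within an error bound, by Lagrangian branch-&-bound.

    Produces the same canonicalized :class:`~hdxresolve.ilp.SolutionSet`
    as :func:`hdxresolve.ilp.enumerate_optimal` at the same bound, without
    any LP/ILP backend.  ``"auto"`` first proves the optimum (branch-&-
    bound minimization seeded with the heuristic upper bound), then
    enumerates at that bound.
    """
    ctx = _Context(instance)
    if instance.n_fragments == 0:
        sol = CountSolution(np.zeros((0, instance.K), dtype=np.int64))
        return SolutionSet(optimum=0, formulation="lagrangian",
                           solutions=[sol], multiplicities=[1])
    _, ub_heur = heuristic_solve(instance)
    if error_bound == "auto":
        error_bound = _prove_optimum(ctx, ub_heur, root_schedule)
    error_bound = int(error_bound)
    if error_bound < 0:
        return SolutionSet(optimum=error_bound, formulation="lagrangian")

    found: dict[tuple, np.ndarray] = {}

    def record(y: np.ndarray) -> None:
        found[tuple(map(int, y.ravel()))] = y.copy()

    root_lower = np.zeros((ctx.m, ctx.K), dtype=np.int64)
    root_upper = np.tile(ctx.caps[:, None], (1, ctx.K))
    stack = [(root_lower, root_upper, np.asarray(ctx.caps, dtype=float), 0)]
    while stack:
        lower, upper, lam, depth = stack.pop()
        if _interval_bound(ctx, lower, upper) > error_bound:
            continue
        shaved = _shave_box(ctx, lower, upper, error_bound)
        if shaved is None:
            continue
        lower, upper = shaved
        if _box_size(ctx, lower, upper) <= _BATCH:
            _sweep_box(ctx, lower, upper, error_bound, record)
            continue
        schedule = (root_schedule or SubgradientSchedule()) if depth == 0 else CHILD_SCHEDULE
        state = subgradient_optimize(
            ctx, UB=max(ub_heur, error_bound), schedule=schedule,
            lam0=lam, bounds=(lower, upper),
        )
        if math.ceil(state.best_bound - 1e-9) > error_bound:
            continue
        sel = _select_branch_variable(ctx, lower, upper, state.history)
        if sel is None:  # fully fixed box (should have been swept)
            _sweep_box(ctx, lower, upper, error_bound, record)
            continue
        p, k, split = sel
        left_u = upper.copy(); left_u[p, k] = split
        right_l = lower.copy(); right_l[p, k] = split + 1
        warm = state.best_lam if state.best_lam is not None else state.lam
        stack.append((right_l, upper, warm.copy(), depth + 1))
        stack.append((lower, left_u, warm.copy(), depth + 1))

    solutions = []
    multiplicities = []
    errors = []
    for key in sorted(found):
        sol = CountSolution(found[key])
        errors.append(error_from_counts(instance, ctx.partition, sol).total)
        solutions.append(sol)
        multiplicities.append(count_expansions(ctx.partition, sol))
    optimum = min(errors) if errors else error_bound
    return SolutionSet(optimum=int(optimum), formulation="lagrangian",
                       solutions=solutions, multiplicities=multiplicities)


def solve_min_error_bnb(instance: Instance):
    """Exact ``(optimum, CountSolution)`` by Lagrangian branch-&-bound alone."""
    ctx = _Context(instance)
    if instance.n_fragments == 0:
        return 0, CountSolution(np.zeros((0, instance.K), dtype=np.int64))
    best_sol, ub_heur = heuristic_solve(instance)
    holder = {"y": best_sol.y}
    optimum = _prove_optimum(ctx, ub_heur, None, incumbent_out=holder)
    sol = CountSolution(holder["y"])
    assert error_from_counts(instance, ctx.partition, sol).total == optimum
    return optimum, sol


def _prove_optimum(ctx: _Context, ub_heur: int, root_schedule, incumbent_out=None) -> int:
    """Exact minimum error by Lagrangian branch-&-bound (no enumeration)."""
    incumbent = int(ub_heur)
    root_lower = np.zeros((ctx.m, ctx.K), dtype=np.int64)
    root_upper = np.tile(ctx.caps[:, None], (1, ctx.K))
    stack = [(root_lower, root_upper, np.asarray(ctx.caps, dtype=float), 0)]
    while stack:
        lower, upper, lam, depth = stack.pop()
        cheap = _interval_bound(ctx, lower, upper)
        if cheap >= incumbent or cheap == math.inf:
            continue
        shaved = _shave_box(ctx, lower, upper, incumbent - 1)
        if shaved is None:
            continue
        lower, upper = shaved
        if _box_size(ctx, lower, upper) <= _BATCH:
            best = _box_min(ctx, lower, upper)
            if best is not None and best[0] < incumbent:
                incumbent = best[0]
                if incumbent_out is not None:
                    incumbent_out["y"] = best[1]
            continue
        schedule = (root_schedule or SubgradientSchedule()) if depth == 0 else CHILD_SCHEDULE
        state = subgradient_optimize(
            ctx, UB=incumbent, schedule=schedule, lam0=lam,
            bounds=(lower, upper),
        )
        if state.feasible_y is not None:
            err = int(error_from_counts(
                ctx.instance, ctx.partition, CountSolution(state.feasible_y)).total)
            if err < incumbent:
                incumbent = err
                if incumbent_out is not None:
                    incumbent_out["y"] = state.feasible_y.copy()
        if math.ceil(state.best_bound - 1e-9) >= incumbent:
            continue
        sel = _select_branch_variable(ctx, lower, upper, state.history)
        if sel is None:
            continue
        p, k, split = sel
        left_u = upper.copy(); left_u[p, k] = split
        right_l = lower.copy(); right_l[p, k] = split + 1
        warm = state.best_lam if state.best_lam is not None else state.lam
        stack.append((right_l, upper, warm.copy(), depth + 1))
        stack.append((lower, left_u, warm.copy(), depth + 1))
    return incumbent


def _box_min(ctx: _Context, lower, upper):
    """Exact minimum error over a box by bound-pruned depth-first search."""
    rows = [_feasible_rows(ctx, p, lower, upper) for p in range(ctx.m)]
    if any(len(r) == 0 for r in rows):
        return None
    lo = lower.copy()
    up = upper.copy()
    best: list = [None]

    def rec(p: int) -> None:
        cheap = _interval_bound(ctx, lo, up)
        if best[0] is not None and cheap >= best[0][0]:
            return
        if p == ctx.m:
            err = int(np.abs(ctx.instance.requirements - ctx.A @ lo).sum())
            if best[0] is None or err < best[0][0]:
                best[0] = (err, lo.copy())
            return
        for r in rows[p]:
            lo[p] = r
            up[p] = r
            rec(p + 1)
        lo[p] = lower[p]
        up[p] = upper[p]

    rec(0)
    return best[0]
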