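"""Fast approximate K-color solver by recursive two-color reduction.

One color k is separated from the rest: the instance is collapsed to two
classes with right-hand sides ``(b^k, sum_{k' != k} b^{k'})`` and solved
exactly by the minimum-cost-circulation solver.  Residues given color k in
that optimal two-color solution keep it in the final answer; they are
removed (at part granularity) and the remaining colors are assigned
recursively on the shrunken instance.  Different fixing orders can reach
different total errors, so for small K every permutation is tried and the
best result returned.  There is no approximation guarantee, but a
zero-error instance is always solved to zero: each stage's optimum is then
zero and never misassigns.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .model import (
    CountSolution,
    Instance,
    ValidationError,
    compute_parts,
    error_from_counts,
    fragment_part_spans,
)
from .flow import min_cost_interval_flow, reduce_two_color, _lex_min_optimal

__all__ = ["merge_requirements_for_color", "heuristic_solve", "color_orders"]


def merge_requirements_for_color(instance: Instance, k: int) -> Instance:
    """Two-color instance separating color ``k`` (1-based) from the rest.

    Color 1 of the result is class k, color 2 the merged remaining classes;
    fragments are unchanged.
    """
    if not (1 <= k <= instance.K):
        raise ValidationError(f"color index {k} out of range 1..{instance.K}")
    b_k = instance.requirements[:, k - 1]
    b_rest = instance.requirements.sum(axis=1) - b_k
    rest_name = "+".join(c for i, c in enumerate(instance.color_names) if i != k - 1)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Instance(
            n=instance.n,
            fragments=list(instance.fragments),
            requirements=np.column_stack([b_k, b_rest]),
            color_names=(instance.color_names[k - 1], rest_name),
            residue_labels=instance.residue_labels,
        )


def color_orders(K: int, order: str | tuple | list = "all") -> list[tuple[int, ...]]:
    """Resolve an ordering spec to a list of color permutations (1-based).

    ``"all"`` is exhaustive up to K = 4 (24 orders); beyond that a single
    fixed order is used, descending by total requirement mass downstream.
    """
    if order == "all":
        if K <= 4:
            return sorted(permutations(range(1, K + 1)))
        return []  # caller falls back to a mass-descending single order
    perm = tuple(int(c) for c in order)
    if sorted(perm) != list(range(1, K + 1)):
        raise ValidationError(f"{order!r} is not a permutation of 1..{K}")
    return [perm]


def _solve_one_order(caps, spans, B, order_local):
    """Run the fixing stages for one color order in part-count space.

    ``B`` is the (F, K) requirement matrix; ``order_local`` indexes its
    columns.  Returns the (m, K) count matrix assembled over all stages.
    """
    m = len(caps)
    K = B.shape[1]
    part_left = caps.copy()
    y_out = np.zeros((m, K), dtype=np.int64)
    remaining = list(range(K))
    for k in order_local[:-1]:
        pos = remaining.index(k)
        b_k = B[:, k]
        b_rest = B[:, remaining].sum(axis=1) - b_k
        F_cur = np.array([part_left[lo : hi + 1].sum() for lo, hi in spans])
        red = reduce_two_color(b_k, b_rest, F_cur)
        val, y = min_cost_interval_flow(part_left, spans, red.b_hi, red.b_lo)
        y = _lex_min_optimal(part_left, spans, red.b_hi, red.b_lo, val, y)
        y_out[:, k] = y
        part_left = part_left - y
        remaining.pop(pos)
    y_out[:, remaining[0]] = part_left
    return y_out


def heuristic_solve(instance: Instance, order: str | tuple | list = "all"):
    """Approximate minimum-error solution; returns ``(CountSolution, total)``.

    The reported total is the true error of the assembled solution on the
    original instance (never the sum of stage objectives).  With
    ``order="all"`` every permutation is evaluated and the best (ties: the
    first permutation in lexicographic order) is returned, which makes the
    result deterministic together with the flow solver's lexicographic
    tie-break within each stage.
    """
    partition = compute_parts(instance)
    m = partition.n_parts
    if m == 0:
        return CountSolution(np.zeros((0, instance.K), dtype=np.int64)), 0
    spans = fragment_part_spans(instance, partition)
    caps = partition.sizes
    B = instance.requirements

    orders = color_orders(instance.K, order)
    if not orders:  # K > 4 with "all": fixed mass-descending order
        mass = B.sum(axis=0)
        orders = [tuple(int(i) + 1 for i in np.argsort(-mass, kind="stable"))]

    best = None
    for perm in orders:
        y = _solve_one_order(caps, spans, B, [c - 1 for c in perm])
        sol = CountSolution(y)
        total = error_from_counts(instance, partition, sol).total
        if best is None or total < best[1]:
            best = (sol, total)
    return best
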