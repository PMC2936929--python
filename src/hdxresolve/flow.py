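"""Exact polynomial solver for the two-class case via minimum-cost circulation.

With K = 2 the linking constraint ``y_p^1 + y_p^2 = |p|`` eliminates one
color: write ``y_p`` for the residues of part p given color 1.  Folding the
two requirement vectors into componentwise bounds

    b_hi = max(b^1, F - b^2),    b_lo = min(b^1, F - b^2)

(F the fragment sizes) the total two-color error of any y decomposes as

    sum_f (b_hi_f - b_lo_f)  +  2 * [ sum_f (s_f - b_hi_f)_+ + (b_lo_f - s_f)_+ ]

where ``s_f`` is the number of color-1 residues inside fragment f.  The
bracketed LP has an interval (consecutive-ones) constraint matrix, hence is
totally unimodular: its dual is a minimum-cost circulation on the *fragment
graph* with |P|+1 nodes -- per part a forward/backward arc pair encoding
0 <= y_p <= |p|, per fragment spanning part positions i..j the arcs
(i, j+1) and (j+1, i) carrying unit cost per unit of surplus/shortage.
Optimal y is read off the node potentials of the optimal circulation
(Bellman-Ford on the residual network); ties are broken toward the
lexicographically smallest optimal y.

The same network, with node supplies derived from multiplier differences,
solves the per-color Lagrangian subproblems (see :mod:`hdxresolve.lagrangian`).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import (
    CountSolution,
    Instance,
    Partition,
    ValidationError,
    compute_parts,
    error_from_counts,
    fragment_part_spans,
)

__all__ = [
    "TwoColorReduction",
    "FragmentGraph",
    "reduce_two_color",
    "build_fragment_graph",
    "solve_two_color",
]

#: cost/supply quantization scale for real-valued multipliers (2**16)
LAMBDA_SCALE = 1 << 16


@dataclass
class TwoColorReduction:
    """Componentwise folded requirement bounds for the two-color case."""

    b_hi: np.ndarray
    b_lo: np.ndarray
    F: np.ndarray

    @property
    def constant(self) -> int:
        """The y-independent error floor sum_f (b_hi - b_lo)."""
        return int((self.b_hi - self.b_lo).sum())


def reduce_two_color(b1, b2, F) -> TwoColorReduction:
    """Fold two requirement vectors into the bounds of the one-variable LP."""
    b1 = np.asarray(b1, dtype=np.int64)
    b2 = np.asarray(b2, dtype=np.int64)
    F = np.asarray(F, dtype=np.int64)
    if not (b1.shape == b2.shape == F.shape):
        raise ValidationError("b1, b2 and F must have equal length")
    if (b1 < 0).any() or (b2 < 0).any():
        raise ValidationError("requirements must be nonnegative")
    b_hi = np.maximum(b1, F - b2)
    b_lo = np.minimum(b1, F - b2)
    return TwoColorReduction(b_hi=b_hi, b_lo=b_lo, F=F)


@dataclass
class FragmentGraph:
    """The circulation network of the two-color LP.

    Nodes ``0..m`` are part boundaries (part p lies between nodes p and
    p+1).  Arc keys tag their role: ``("cap+", p)`` / ``("cap-", p)`` encode
    ``0 <= y_p <= |p|``; ``("hi", f)`` / ``("lo", f)`` are the fragment
    surplus/shortage arcs (j+1, i) and (i, j+1).
    """

    graph: nx.MultiDiGraph
    n_parts: int
    n_fragments: int
    scale: int = 1

    @property
    def n_nodes(self) -> int:
        return self.n_parts + 1

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def to_dot(self) -> str:
        """DOT-format dump with capacity/cost annotations (debug aid)."""
        lines = ["digraph fragment_graph {"]
        for u, v, key, data in self.graph.edges(keys=True, data=True):
            cap = data.get("capacity", "inf")
            label = f"{key[0]}{key[1]} c={data['weight']} u={cap}"
            lines.append(f'  {u} -> {v} [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


def build_fragment_graph(
    caps,
    spans: list[tuple[int, int]],
    reduction: TwoColorReduction,
    supplies=None,
    scale: int = 1,
) -> FragmentGraph:
    """Build the circulation (or flow) network for the folded LP.

    Parameters
    ----------
    caps : int array, length m
        Upper bounds on y per part (the part sizes, or a branch box width).
    spans : list of (i, j)
        Per fragment, the inclusive 0-based range of part positions spanned.
    reduction : TwoColorReduction
        Folded bounds b_hi / b_lo (equal vectors in the Lagrangian case).
    supplies : int array of length m+1, optional
        Node supplies (outflow - inflow) in units of ``1/scale`` flow,
        already multiplied by ``scale``; omitted for a pure circulation.
    scale : int
        Flow-volume quantization factor: the dual variables of the fragment
        arcs live in [0, 1], so a real-valued supply vector on the
        ``1/scale`` grid is handled by scaling all flow volumes (supplies
        and fragment-arc capacities) by ``scale`` while costs stay integral.
    """
    caps = np.asarray(caps, dtype=np.int64)
    m = len(caps)
    G = nx.MultiDiGraph()
    for u in range(m + 1):
        demand = 0 if supplies is None else -int(supplies[u])
        G.add_node(u, demand=demand)
    for p in range(m):
        G.add_edge(p, p + 1, key=("cap+", p), weight=0)
        G.add_edge(p + 1, p, key=("cap-", p), weight=int(caps[p]))
    for fi, (lo, hi) in enumerate(spans):
        G.add_edge(hi + 1, lo, key=("hi", fi), weight=int(reduction.b_hi[fi]),
                   capacity=scale)
        G.add_edge(lo, hi + 1, key=("lo", fi), weight=-int(reduction.b_lo[fi]),
                   capacity=scale)
    return FragmentGraph(graph=G, n_parts=m, n_fragments=len(spans), scale=scale)


def _potentials(fg: FragmentGraph, flow: dict) -> np.ndarray:
    """Bellman-Ford node potentials on the residual network of ``flow``.

    Distances from a virtual source with zero-cost arcs to every node; the
    residual network of an optimal flow has no negative cycle, so the
    distances converge and certify optimality.
    """
    m = fg.n_parts
    arcs: list[tuple[int, int, int]] = []
    for u, v, key, data in fg.graph.edges(keys=True, data=True):
        x = flow[u][v][key]
        cap = data.get("capacity")
        if cap is None or x < cap:
            arcs.append((u, v, data["weight"]))
        if x > 0:
            arcs.append((v, u, -data["weight"]))
    dist = np.zeros(m + 1, dtype=np.int64)
    for it in range(m + 1):
        changed = False
        for u, v, w in arcs:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                changed = True
        if not changed:
            break
    else:  # pragma: no cover - would contradict flow optimality
        raise AssertionError("negative cycle in residual network")
    return dist


def min_cost_interval_flow(
    caps,
    spans: list[tuple[int, int]],
    b_hi,
    b_lo,
    lam=None,
    lower=None,
    upper=None,
):
    """Minimize ``sum_f (s_f - b_hi)_+ + (b_lo - s_f)_+ + lam . y`` over a box.

    ``s_f = sum_{p in span f} y_p`` and the box is ``lower <= y <= upper``
    (default ``0 <= y <= caps``).  Solved exactly as a minimum-cost
    flow/circulation on the fragment graph; ``lam`` is quantized to the
    ``1/LAMBDA_SCALE`` grid (the value returned is exact for the quantized
    multipliers, which is all a Lagrangian bound requires).

    Returns ``(value, y)`` with integral ``y`` recovered from node
    potentials.
    """
    caps = np.asarray(caps, dtype=np.int64)
    m = len(caps)
    lower = np.zeros(m, dtype=np.int64) if lower is None else np.asarray(lower, dtype=np.int64)
    upper = caps.copy() if upper is None else np.asarray(upper, dtype=np.int64)
    if (lower > upper).any() or (lower < 0).any() or (upper > caps).any():
        raise ValidationError("inconsistent box bounds")
    b_hi = np.asarray(b_hi, dtype=np.int64)
    b_lo = np.asarray(b_lo, dtype=np.int64)

    # shift the box to [0, upper-lower]
    box = upper - lower
    shift = np.zeros(len(spans), dtype=np.int64)
    for fi, (lo, hi) in enumerate(spans):
        shift[fi] = lower[lo : hi + 1].sum()
    red = TwoColorReduction(b_hi=b_hi - shift, b_lo=b_lo - shift, F=box)

    if lam is None:
        scale = 1
        lam_int = np.zeros(m, dtype=np.int64)
    else:
        scale = LAMBDA_SCALE
        lam_int = np.rint(np.asarray(lam, dtype=float) * scale).astype(np.int64)
    supplies = np.zeros(m + 1, dtype=np.int64)
    if m:
        supplies[0] = lam_int[0]
        supplies[1:m] = lam_int[1:] - lam_int[:-1]
        supplies[m] = -lam_int[m - 1]

    if m == 0:
        return 0.0 if lam is not None else 0, np.zeros(0, dtype=np.int64)

    fg = build_fragment_graph(box, spans, red, supplies=supplies, scale=scale)
    cost, flow = nx.network_simplex(fg.graph)
    dist = _potentials(fg, flow)
    y = lower + (dist[:-1] - dist[1:])

    if lam is None:
        return int(-cost), y
    # mincost is scale * (dual value); add back the box-shift term lam . lower
    return (-cost + int(lam_int @ lower)) / scale, y


def _lex_min_optimal(caps, spans, b_hi, b_lo, optimum, y_start):
    """Lexicographically smallest integral optimum of the folded LP."""
    caps = np.asarray(caps, dtype=np.int64)
    m = len(caps)
    lower = np.zeros(m, dtype=np.int64)
    upper = caps.copy()
    y_cur = np.asarray(y_start, dtype=np.int64).copy()

    def value_with(p: int, v: int):
        lower[p] = upper[p] = v
        val, y = min_cost_interval_flow(caps, spans, b_hi, b_lo, lower=lower, upper=upper)
        return val, y

    for p in range(m):
        # h(v) = optimal value with y_p fixed to v (prefix already fixed) is
        # convex and attains `optimum` at v = y_cur[p]; it is therefore
        # non-increasing on [0, y_cur[p]].  Binary-search the smallest root.
        lo_v, hi_v = 0, int(y_cur[p])
        best_y = y_cur
        while lo_v < hi_v:
            mid = (lo_v + hi_v) // 2
            val, y = value_with(p, mid)
            if val == optimum:
                hi_v = mid
                best_y = y
            else:
                lo_v = mid + 1
        lower[p] = upper[p] = lo_v
        y_cur = best_y if best_y[p] == lo_v else value_with(p, lo_v)[1]
    return y_cur


def solve_two_color(instance: Instance, *, canonical: bool = True):
    """Exact minimum-error solution for a two-class instance.

    Returns ``(optimum, CountSolution)``; the count solution is the
    lexicographically smallest optimal ``y`` (by part position, color 1
    counts) unless ``canonical=False``, which returns the potential-derived
    optimum directly.

    Raises for K != 2 -- use the heuristic or the ILP solver instead.
    """
    if instance.K != 2:
        raise ValidationError(
            f"solve_two_color requires K=2 (got K={instance.K}); "
            "use heuristic_solve or solve_min_error"
        )
    partition = compute_parts(instance)
    if partition.n_parts == 0:
        return 0, CountSolution(np.zeros((0, 2), dtype=np.int64))
    spans = fragment_part_spans(instance, partition)
    caps = partition.sizes
    red = reduce_two_color(
        instance.requirements[:, 0], instance.requirements[:, 1], instance.fragment_sizes
    )
    lp_value, y1 = min_cost_interval_flow(caps, spans, red.b_hi, red.b_lo)
    if canonical:
        y1 = _lex_min_optimal(caps, spans, red.b_hi, red.b_lo, lp_value, y1)
    optimum = red.constant + 2 * int(lp_value)
    solution = CountSolution(np.column_stack([y1, caps - y1]))
    assert error_from_counts(instance, partition, solution).total == optimum
    return optimum, solution
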