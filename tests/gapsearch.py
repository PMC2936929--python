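"""Search for an infinite-integrality-gap witness on the 7-part layout.

The layout is the four-fragment example with parts 1..7 and fragments
(1,3), (2,5), (3,6), (5,7) in part positions.  A witness is a 3-color
right-hand side (and part-size vector) whose LP relaxation has value 0
(i.e. a fractional exact solution exists) while no integral coloring
matches all counts, so the integer optimum is positive.

Two finite stages are searched deterministically:

1. unit part sizes, exhaustively over every right-hand side whose rows sum
   to the fragment lengths (an LP value of 0 forces those sums, because
   summing the per-color count constraints over colors yields the length);
2. part sizes up to 2, over right-hand sides generated from the algebra of
   fractional patterns: modulo 1, the per-part fractional vectors phi_p of
   an exact fractional solution must cancel inside every fragment, which
   on this layout forces phi_6 = phi_2, phi_1 = -(phi_2+phi_3),
   phi_5 = -(phi_2+phi_3+phi_4), phi_7 = -(phi_5+phi_6); all patterns with
   denominators up to 6 are enumerated.

Both stages verify LP feasibility exactly and integral infeasibility by
exhaustive enumeration, so a returned witness is certified.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

SPANS = [(0, 2), (1, 4), (2, 5), (4, 6)]
N_PARTS = 7
K = 3


def _int_rows(s: int) -> np.ndarray:
    return np.array(
        [(a, b, s - a - b) for a in range(s + 1) for b in range(s + 1 - a)]
    ).reshape(-1, 3)


def _colorable_rhs(sizes) -> set[tuple[int, ...]]:
    """All right-hand sides achievable by an integral coloring."""
    rows = [_int_rows(s) for s in sizes]
    shape = [len(r) for r in rows]
    idx = np.indices(shape).reshape(N_PARTS, -1).T
    Y = np.empty((idx.shape[0], N_PARTS, K), dtype=np.int64)
    for p in range(N_PARTS):
        Y[:, p, :] = rows[p][idx[:, p]]
    B = np.stack([Y[:, lo : hi + 1, :].sum(axis=1) for lo, hi in SPANS], axis=1)
    return {tuple(r.tolist()) for r in B.reshape(len(B), -1)}


def _lp_feasible_exact(sizes, b) -> bool:
    """Does a fractional y >= 0 with row sums |p| match all counts exactly?"""
    n_y = N_PARTS * K  # y[p, k] flattened row-major
    A_eq = []
    b_eq = []
    for fi, (lo, hi) in enumerate(SPANS):
        for k in range(K):
            row = np.zeros(n_y)
            for p in range(lo, hi + 1):
                row[p * K + k] = 1
            A_eq.append(row)
            b_eq.append(b[fi][k])
    for p in range(N_PARTS):
        row = np.zeros(n_y)
        row[p * K : (p + 1) * K] = 1
        A_eq.append(row)
        b_eq.append(sizes[p])
    res = linprog(np.zeros(n_y), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    return res.status == 0


def _consistent_rhs(lengths):
    """All rhs matrices with rows summing to the fragment lengths."""
    per_fragment = [
        [(a, b, L - a - b) for a in range(L + 1) for b in range(L + 1 - a)]
        for L in lengths
    ]
    yield from itertools.product(*per_fragment)


def _fractional_pattern_candidates(max_denominator):
    """(sizes, rhs) candidates from the fragment-cancellation algebra."""
    for den in range(2, max_denominator + 1):
        D = [np.array(v) / den
             for v in itertools.product(range(den), repeat=K)
             if sum(v) % den == 0]
        for phi2, phi3, phi4 in itertools.product(D, repeat=3):
            phi5 = (-(phi2 + phi3 + phi4)) % 1
            phis = [(-(phi2 + phi3)) % 1, phi2, phi3, phi4, phi5, phi2,
                    (-(phi5 + phi2)) % 1]
            frac_sums = [int(round(p.sum())) for p in phis]
            sizes = tuple(max(1, f) for f in frac_sums)
            if max(sizes) > 2:
                continue
            g_rows = [_int_rows(sizes[p] - frac_sums[p]) for p in range(N_PARTS)]
            for combo in itertools.product(*g_rows):
                Y = np.array(combo) + np.array(phis)
                bmat = np.stack([Y[lo : hi + 1].sum(axis=0) for lo, hi in SPANS])
                if np.abs(bmat - np.rint(bmat)).max() > 1e-9:
                    continue
                rhs = tuple(tuple(int(round(v)) for v in row) for row in bmat)
                yield sizes, rhs


def figure_layout_gap_search(max_denominator: int = 6):
    """Return ``(sizes, rhs)`` of a witness, or None if the space has none."""
    # stage 1: unit part sizes, exhaustive
    sizes = (1,) * N_PARTS
    lengths = [hi - lo + 1 for lo, hi in SPANS]
    colorable = _colorable_rhs(sizes)
    for rhs in _consistent_rhs(lengths):
        key = tuple(v for row in rhs for v in row)
        if key in colorable:
            continue
        if _lp_feasible_exact(sizes, rhs):
            return sizes, rhs
    # stage 2: sizes up to 2 via fractional-pattern algebra
    cache = {}
    for sizes, rhs in _fractional_pattern_candidates(max_denominator):
        if sizes not in cache:
            cache[sizes] = _colorable_rhs(sizes)
        key = tuple(v for row in rhs for v in row)
        if key in cache[sizes]:
            continue
        if _lp_feasible_exact(sizes, rhs):  # pragma: no cover - not expected
            return sizes, rhs
    return None
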