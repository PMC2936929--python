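"""Independent brute-force oracles used to validate every solver.

These deliberately share no code with the package's solvers: errors are
recomputed from first principles by exhaustive sweeps over all K^n
colorings (vectorized, so n <= 12 stays fast).
"""

from __future__ import annotations

import numpy as np


def all_colorings(n_covered: int, K: int) -> np.ndarray:
    """(K**n, n) array of all colorings with colors 1..K."""
    if n_covered == 0:
        return np.zeros((1, 0), dtype=np.int8)
    grid = np.indices((K,) * n_covered).reshape(n_covered, -1).T
    return (grid + 1).astype(np.int8)


def brute_force_errors(instance) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total error of every coloring of the covered residues.

    Returns ``(errors, colorings, covered_idx)`` where ``colorings`` are
    over the covered residues only (column i = residue covered_idx[i]+1).
    """
    covered = np.flatnonzero(instance.covered_mask())
    combos = all_colorings(len(covered), instance.K)
    errs = np.zeros(len(combos), dtype=np.int64)
    for fi, f in enumerate(instance.fragments):
        cols = [i for i, r in enumerate(covered) if f.start - 1 <= r <= f.end - 1]
        sub = combos[:, cols]
        for k in range(instance.K):
            cnt = (sub == k + 1).sum(axis=1)
            errs += np.abs(int(instance.requirements[fi, k]) - cnt)
    return errs, combos, covered


def brute_force_optimum(instance) -> int:
    errs, _, _ = brute_force_errors(instance)
    return int(errs.min())


def brute_force_optimal_set(instance) -> tuple[int, set[tuple[int, ...]]]:
    """Optimum and the set of all optimal colorings (covered residues)."""
    errs, combos, _ = brute_force_errors(instance)
    best = int(errs.min())
    optimal = {tuple(map(int, row)) for row in combos[errs == best]}
    return best, optimal


def expand_solution_set(instance, solution_set) -> set[tuple[int, ...]]:
    """All residue-level colorings represented by a part-level solution set."""
    from hdxresolve.model import compute_parts, expand_counts

    covered = np.flatnonzero(instance.covered_mask())
    partition = compute_parts(instance)
    out = set()
    for sol in solution_set.solutions:
        for ra in expand_counts(partition, sol, instance.n):
            out.add(tuple(int(c) for c in ra.colors[covered]))
    return out
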