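"""Consensus over enumerated solution sets and agreement with reference rates.

When many equally good solutions exist, averaging over them is usually
closer to an independent reference (e.g. NMR exchange rates) than any
single solution.  Three consensus modes over a part-level solution set:

``single``
    The first solution in canonical order.
``majority``
    Per part, the |p| residue slots are apportioned to colors by largest
    remainder on the (optionally expansion-weighted) summed counts.
``mean``
    Colors are treated as ordinals 1..K; per residue slot the weighted
    mean ordinal is rounded half-to-even back to a color.

Agreement with a reference is scored per part: predicted and reference
color counts are compared as multisets (residues inside one part are
mutually exchangeable, so only counts can be compared), residues without
reference data are excluded, and the score is the matched fraction in
percent.

Raw rates in 1/h are discretized with the conventional thresholds
slow <= 0.1/h and fast >= 8/h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CountSolution, Partition, ValidationError

__all__ = [
    "SLOW_MAX_RATE",
    "FAST_MIN_RATE",
    "ReferenceAssignment",
    "ConsensusResult",
    "discretize_rates",
    "consensus",
    "agreement_score",
]

SLOW_MAX_RATE = 0.1  # 1/h, inclusive
FAST_MIN_RATE = 8.0  # 1/h, inclusive


@dataclass
class ReferenceAssignment:
    """Per-residue reference colors; 0 marks residues without data."""

    colors: np.ndarray
    rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.int64)


@dataclass
class ConsensusResult:
    """Per-part consensus color counts plus provenance tags."""

    counts: np.ndarray
    method: str
    weighting: str

    def as_solution(self) -> CountSolution:
        return CountSolution(self.counts)


def discretize_rates(
    rates: dict[int, float | str] | np.ndarray,
    n: int | None = None,
    color_names=("slow", "medium", "fast"),
) -> ReferenceAssignment:
    """Discretize per-residue rates (1/h) into slow / medium / fast.

    Accepts a mapping residue -> rate or class label (as from
    :func:`hdxresolve.io.load_reference_table`) or a dense array with NaN
    for missing.  Boundary rates go to the extreme classes (slow <= 0.1,
    fast >= 8).
    """
    if isinstance(rates, dict):
        if n is None:
            n = max(rates) if rates else 0
        dense = np.full(n, np.nan)
        labels = np.zeros(n, dtype=np.int64)
        for residue, value in rates.items():
            if not (1 <= residue <= n):
                raise ValidationError(f"residue {residue} outside 1..{n}")
            if isinstance(value, str):
                if value not in color_names:
                    raise ValidationError(f"unknown class label {value!r}")
                labels[residue - 1] = color_names.index(value) + 1
            else:
                dense[residue - 1] = value
    else:
        dense = np.asarray(rates, dtype=float)
        n = len(dense)
        labels = np.zeros(n, dtype=np.int64)
    if np.nanmin(dense, initial=0.0) < 0:
        raise ValidationError("exchange rates must be nonnegative")
    measured = ~np.isnan(dense)
    cls = np.where(dense <= SLOW_MAX_RATE, 1, np.where(dense >= FAST_MIN_RATE, 3, 2))
    labels = np.where(measured, cls, labels)
    return ReferenceAssignment(colors=labels, rates=np.where(measured, dense, np.nan))


def consensus(solution_set, method: str = "mean", weighting: str = "class") -> ConsensusResult:
    """Consensus prediction over a part-level solution set.

    ``weighting="class"`` gives every equivalence class one vote;
    ``"expanded"`` weights each class by the number of residue-level
    colorings it represents.
    """
    if method not in ("single", "majority", "mean"):
        raise ValidationError(f"unknown consensus method {method!r}")
    if weighting not in ("class", "expanded"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    sols = solution_set.solutions
    if not sols:
        raise ValidationError("cannot build a consensus of an empty solution set")
    if not isinstance(sols[0], CountSolution):
        raise ValidationError("consensus requires part-level count solutions")
    Y = np.stack([s.y for s in sols])  # (S, m, K)
    w = (
        np.asarray(solution_set.multiplicities, dtype=float)
        if weighting == "expanded"
        else np.ones(len(sols))
    )
    m, K = Y.shape[1], Y.shape[2]
    sizes = Y[0].sum(axis=1)

    if method == "single":
        counts = Y[0].copy()
    elif method == "majority":
        counts = np.zeros((m, K), dtype=np.int64)
        summed = np.tensordot(w, Y, axes=(0, 0))  # (m, K)
        for p in range(m):
            counts[p] = _largest_remainder(summed[p], int(sizes[p]))
    else:  # mean
        counts = np.zeros((m, K), dtype=np.int64)
        for p in range(m):
            size = int(sizes[p])
            # expand each solution's counts into its sorted per-slot ordinals
            slots = np.zeros((len(sols), size))
            for s in range(len(sols)):
                ordinals = np.repeat(np.arange(1, K + 1), Y[s, p])
                slots[s] = ordinals
            mean_ord = (w @ slots) / w.sum()
            rounded = np.clip(_round_half_even(mean_ord), 1, K).astype(np.int64)
            for k in range(K):
                counts[p, k] = int((rounded == k + 1).sum())
    return ConsensusResult(counts=counts, method=method, weighting=weighting)


def _largest_remainder(weights: np.ndarray, seats: int) -> np.ndarray:
    total = weights.sum()
    if total == 0:
        quotas = np.full(len(weights), seats / len(weights))
    else:
        quotas = weights / total * seats
    base = np.floor(quotas).astype(np.int64)
    remainder = quotas - base
    short = seats - int(base.sum())
    # distribute leftovers by largest remainder; ties to the lower color index
    order = np.lexsort((np.arange(len(weights)), -remainder))
    for i in range(short):
        base[order[i]] += 1
    return base


def _round_half_even(values: np.ndarray) -> np.ndarray:
    return np.rint(values)  # numpy rounds half to even


def agreement_score(
    prediction: ConsensusResult | CountSolution,
    reference: ReferenceAssignment,
    partition: Partition,
) -> tuple[float, list[dict]]:
    """Percent agreement between predicted and reference colors, per part.

    Within a part only color multisets are comparable; each part
    contributes the size of the multiset intersection between the
    predicted counts and the reference counts over its residues with
    reference data.  Returns ``(score, per_part_rows)``; the score is NaN
    when no residue is comparable.
    """
    counts = prediction.counts if isinstance(prediction, ConsensusResult) else prediction.y
    K = counts.shape[1]
    matched_total = 0
    compared_total = 0
    rows = []
    for pi, part in enumerate(partition.parts):
        ref = reference.colors[part.start - 1 : part.end]
        present = ref > 0
        ref_counts = np.array([(ref == k + 1).sum() for k in range(K)])
        matched = int(np.minimum(counts[pi], ref_counts).sum())
        compared = int(present.sum())
        matched = min(matched, compared)
        matched_total += matched
        compared_total += compared
        rows.append(
            {
                "part": pi,
                "start": part.start,
                "end": part.end,
                "matched": matched,
                "compared": compared,
                "predicted": counts[pi].tolist(),
                "reference": ref_counts.tolist(),
            }
        )
    score = 100.0 * matched_total / compared_total if compared_total else float("nan")
    return score, rows
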