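"""Core domain model for residue-level exchange-rate assignment.

A solution-phase HDX-MS experiment on a digested protein yields, for each
peptic fragment (a contiguous residue interval), the number of backbone
amide hydrogens falling into each of K discretized exchange-rate classes
(canonically slow / medium / fast).  The task is to assign one class
("color") to every residue so that, within every fragment, the per-class
residue counts match the measured class counts as closely as possible.

The central objects are:

* :class:`Instance` -- protein length, fragment intervals and the per
  fragment x class "requirement" counts ``b``.
* :class:`Partition` -- the decomposition of the covered residues into
  *parts*: maximal runs of residues contained in exactly the same set of
  fragments.  No fragment starts or ends inside a part, so permuting
  colors among the residues of one part never changes any fragment's
  error.  A part-level count matrix ``y`` therefore represents a whole
  equivalence class of residue-level assignments.
* :class:`CountSolution` -- the ``|P| x K`` matrix ``y`` of per-part
  per-color residue counts.
* :class:`ErrorReport` -- per fragment and class, the absolute deviation
  ``|b_f^k - #{residues in f with color k}|`` and its total, the objective
  every solver in this package minimizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Interval",
    "Instance",
    "Partition",
    "ResidueAssignment",
    "CountSolution",
    "ErrorReport",
    "SubproblemDecomposition",
    "ValidationError",
    "compute_parts",
    "part_matrix",
    "fragment_part_spans",
    "decompose_subproblems",
    "evaluate_assignment",
    "error_from_counts",
    "counts_from_assignment",
    "count_expansions",
    "DEFAULT_COLOR_NAMES",
]

DEFAULT_COLOR_NAMES = ("slow", "medium", "fast")


class ValidationError(ValueError):
    """Raised when an instance or table violates a structural precondition."""


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive residue interval ``{start, ..., end}``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid interval ({self.start}, {self.end}): need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class Instance:
    """A fragment-count instance.

    Parameters
    ----------
    n : int
        Number of residues, numbered 1..n from the N- to the C-terminus.
    fragments : sequence of Interval
        Peptic fragments as residue intervals; overlaps are the point.
    requirements : (|F|, K) int array
        ``requirements[f, k]`` is the measured number of residues of
        fragment ``f`` in rate class ``k`` (the right-hand side b_f^k).
    color_names : sequence of str
        Length-K class labels, default ``("slow", "medium", "fast")``.
    residue_labels : str or None
        Optional one-letter residue codes of length n.
    """

    n: int
    fragments: list[Interval]
    requirements: np.ndarray
    color_names: tuple[str, ...] = DEFAULT_COLOR_NAMES
    residue_labels: str | None = None

    def __post_init__(self) -> None:
        self.fragments = [
            f if isinstance(f, Interval) else Interval(*f) for f in self.fragments
        ]
        self.requirements = np.asarray(self.requirements, dtype=np.int64)
        if self.requirements.size == 0:
            self.requirements = np.zeros(
                (len(self.fragments), len(self.color_names)), dtype=np.int64
            )
        self.color_names = tuple(self.color_names)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def K(self) -> int:
        return len(self.color_names)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def fragment_sizes(self) -> np.ndarray:
        """The fragment-size vector F."""
        return np.array([len(f) for f in self.fragments], dtype=np.int64)

    def covered_mask(self) -> np.ndarray:
        """Boolean mask of length n: residue i (1-based) covered by >=1 fragment."""
        mask = np.zeros(self.n, dtype=bool)
        for f in self.fragments:
            mask[f.start - 1 : f.end] = True
        return mask

    def validate(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be nonnegative")
        if self.K < 2:
            raise ValidationError("need at least two rate classes (K >= 2)")
        if self.requirements.shape != (len(self.fragments), self.K):
            raise ValidationError(
                f"requirements shape {self.requirements.shape} does not match "
                f"({len(self.fragments)}, {self.K})"
            )
        if (self.requirements < 0).any():
            raise ValidationError("requirement counts must be nonnegative")
        if self.residue_labels is not None and len(self.residue_labels) != self.n:
            raise ValidationError("residue_labels length must equal n")
        for i, f in enumerate(self.fragments):
            if f.end > self.n:
                raise ValidationError(
                    f"fragment {i + 1} ({f.start}, {f.end}) extends past n={self.n}"
                )
        # Inconsistent counts are tolerated: the error terms absorb them.
        sizes = self.fragment_sizes
        if len(self.fragments):
            bad_sum = np.flatnonzero(self.requirements.sum(axis=1) != sizes)
            for i in bad_sum:
                warnings.warn(
                    f"fragment {i + 1}: class counts sum to "
                    f"{int(self.requirements[i].sum())} but the fragment has "
                    f"{int(sizes[i])} residues",
                    stacklevel=2,
                )
            bad_entry = np.flatnonzero((self.requirements > sizes[:, None]).any(axis=1))
            for i in bad_entry:
                warnings.warn(
                    f"fragment {i + 1}: a class count exceeds the fragment length",
                    stacklevel=2,
                )


@dataclass
class Partition:
    """Decomposition of the covered residues into parts.

    Parts are maximal contiguous runs of residues whose sets of containing
    fragments are identical; residues covered by no fragment belong to no
    part (no prediction is made for them).
    """

    parts: list[Interval]
    fragment_sets: list[frozenset[int]] = field(default_factory=list)

    @property
    def sizes(self) -> np.ndarray:
        """The part-size vector P."""
        return np.array([len(p) for p in self.parts], dtype=np.int64)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def covered(self) -> set[int]:
        return {r for p in self.parts for r in range(p.start, p.end + 1)}

    def part_of(self, residue: int) -> int | None:
        for i, p in enumerate(self.parts):
            if residue in p:
                return i
        return None


@dataclass
class ResidueAssignment:
    """A residue-level coloring pi: covered residue -> color 1..K.

    ``colors`` is a length-n vector; entry 0 marks residues with no
    prediction (uncovered or deliberately unassigned).
    """

    colors: np.ndarray

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.int64)

    @classmethod
    def from_mapping(cls, n: int, mapping: dict[int, int]) -> "ResidueAssignment":
        colors = np.zeros(n, dtype=np.int64)
        for residue, color in mapping.items():
            colors[residue - 1] = color
        return cls(colors)

    def indicator(self, K: int) -> np.ndarray:
        """Binary view x with x[i, k-1] = 1 iff pi(i+1) = k."""
        x = np.zeros((len(self.colors), K), dtype=np.int64)
        assigned = self.colors > 0
        x[np.flatnonzero(assigned), self.colors[assigned] - 1] = 1
        return x


@dataclass
class CountSolution:
    """Per-part per-color residue counts y (one equivalence class of colorings)."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)

    def key(self) -> tuple:
        """Canonical hashable serialization (row-major)."""
        return tuple(map(int, self.y.ravel()))

    def validate(self, partition: Partition) -> None:
        sizes = partition.sizes
        if self.y.shape[0] != len(sizes):
            raise ValidationError("y has wrong number of parts")
        if (self.y < 0).any() or (self.y > sizes[:, None]).any():
            raise ValidationError("y entries must lie in [0, |p|]")
        if not np.array_equal(self.y.sum(axis=1), sizes):
            raise ValidationError("row sums of y must equal the part sizes")


@dataclass
class ErrorReport:
    """Per fragment x class deviations e and their total (the objective)."""

    e: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.e.sum())


@dataclass
class SubproblemDecomposition:
    """Connected components of the fragment overlap graph.

    ``components`` is a list of ``(fragment_indices, residue_range)`` pairs;
    fragments in different components share no residue, so the instance can
    be solved component by component and the errors added.
    """

    components: list[tuple[list[int], Interval]]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_parts(instance: Instance) -> Partition:
    """Partition the covered residues into parts.

    A part is a maximal contiguous run of residues contained in exactly the
    same set of fragments, so for every fragment f and part p either
    ``p <= f`` or ``p & f = {}`` and no fragment boundary falls inside a part.
    """
    if not instance.fragments:
        return Partition(parts=[], fragment_sets=[])
    membership: list[frozenset[int] | None] = []
    sets_per_residue = [set() for _ in range(instance.n)]
    for fi, f in enumerate(instance.fragments):
        for r in range(f.start - 1, f.end):
            sets_per_residue[r].add(fi)
    membership = [frozenset(s) if s else None for s in sets_per_residue]

    parts: list[Interval] = []
    fragment_sets: list[frozenset[int]] = []
    start = None
    current: frozenset[int] | None = None
    for idx in range(instance.n + 1):
        fs = membership[idx] if idx < instance.n else None
        if fs != current:
            if current is not None:
                parts.append(Interval(start + 1, idx))
                fragment_sets.append(current)
            start = idx
            current = fs
    return Partition(parts=parts, fragment_sets=fragment_sets)


def part_matrix(instance: Instance, partition: Partition) -> np.ndarray:
    """The |F| x |P| 0/1 inclusion matrix A with a[f, p] = 1 iff p is inside f."""
    A = np.zeros((instance.n_fragments, partition.n_parts), dtype=np.int64)
    for pi, p in enumerate(partition.parts):
        for fi in partition.fragment_sets[pi]:
            A[fi, pi] = 1
    return A


def fragment_part_spans(instance: Instance, partition: Partition) -> list[tuple[int, int]]:
    """Per fragment, the inclusive range (i, j) of part positions it spans.

    Parts are ordered left to right, so the parts inside a fragment are
    consecutive (the consecutive-ones property of the inclusion matrix).
    """
    spans: list[tuple[int, int]] = []
    for fi in range(instance.n_fragments):
        positions = [
            pi for pi, fs in enumerate(partition.fragment_sets) if fi in fs
        ]
        if not positions:
            raise ValidationError(f"fragment {fi + 1} covers no part")
        lo, hi = min(positions), max(positions)
        if positions != list(range(lo, hi + 1)):  # pragma: no cover - structural
            raise AssertionError("inclusion matrix row is not consecutive")
        spans.append((lo, hi))
    return spans


def decompose_subproblems(instance: Instance) -> SubproblemDecomposition:
    """Split the fragment set into independent subproblems.

    Two fragments overlap if they share a residue; connected components of
    the overlap graph can be solved independently and their minimum errors
    added.  Computed by a sweep over fragments sorted by start.
    """
    order = sorted(range(instance.n_fragments), key=lambda i: (
        instance.fragments[i].start, instance.fragments[i].end))
    components: list[tuple[list[int], Interval]] = []
    current: list[int] = []
    lo = hi = None
    for fi in order:
        f = instance.fragments[fi]
        if current and f.start <= hi:
            current.append(fi)
            hi = max(hi, f.end)
        else:
            if current:
                components.append((sorted(current), Interval(lo, hi)))
            current = [fi]
            lo, hi = f.start, f.end
    if current:
        components.append((sorted(current), Interval(lo, hi)))
    return SubproblemDecomposition(components=components)


def evaluate_assignment(instance: Instance, assignment: ResidueAssignment) -> ErrorReport:
    """Per-fragment, per-class absolute deviation of a residue coloring.

    ``e[f, k] = |b[f, k] - #{residues in f with color k + 1}|``; the report's
    ``total`` is the minimized objective.
    """
    colors = assignment.colors
    if len(colors) != instance.n:
        raise ValidationError("assignment length must equal n")
    covered = instance.covered_mask()
    if (colors[covered] == 0).any():
        missing = int(np.flatnonzero(covered & (colors == 0))[0]) + 1
        raise ValidationError(f"assignment missing covered residue {missing}")
    if (colors > instance.K).any() or (colors < 0).any():
        raise ValidationError("assignment uses an invalid color index")
    e = np.zeros((instance.n_fragments, instance.K), dtype=np.int64)
    for fi, f in enumerate(instance.fragments):
        inside = colors[f.start - 1 : f.end]
        for k in range(instance.K):
            e[fi, k] = abs(int(instance.requirements[fi, k]) - int((inside == k + 1).sum()))
    return ErrorReport(e=e)


def error_from_counts(
    instance: Instance, partition: Partition, solution: CountSolution
) -> ErrorReport:
    """Error of a part-level count solution (error depends on pi only through y)."""
    solution.validate(partition)
    A = part_matrix(instance, partition)
    e = np.abs(instance.requirements - A @ solution.y)
    return ErrorReport(e=e)


def counts_from_assignment(
    partition: Partition, assignment: ResidueAssignment, K: int
) -> CountSolution:
    """Aggregate a residue coloring into per-part color counts y."""
    y = np.zeros((partition.n_parts, K), dtype=np.int64)
    for pi, p in enumerate(partition.parts):
        inside = assignment.colors[p.start - 1 : p.end]
        if (inside == 0).any():
            raise ValidationError(f"assignment missing a residue of part {pi}")
        for k in range(K):
            y[pi, k] = int((inside == k + 1).sum())
    return CountSolution(y=y)


def expand_counts(
    partition: Partition, solution: CountSolution, n: int
) -> Iterable[ResidueAssignment]:
    """Yield every residue-level coloring in the equivalence class of y."""
    from itertools import permutations

    solution.validate(partition)

    def part_colorings(p: Interval, row: np.ndarray) -> list[tuple[int, ...]]:
        base: list[int] = []
        for k, cnt in enumerate(row):
            base.extend([k + 1] * int(cnt))
        return sorted(set(permutations(base)))

    per_part = [
        part_colorings(p, solution.y[pi]) for pi, p in enumerate(partition.parts)
    ]

    def rec(pi: int, colors: np.ndarray):
        if pi == len(partition.parts):
            yield ResidueAssignment(colors.copy())
            return
        p = partition.parts[pi]
        for combo in per_part[pi]:
            colors[p.start - 1 : p.end] = combo
            yield from rec(pi + 1, colors)
            colors[p.start - 1 : p.end] = 0

    yield from rec(0, np.zeros(n, dtype=np.int64))


def count_expansions(partition: Partition, solution: CountSolution) -> int:
    """Number of residue-level colorings in the equivalence class of y.

    Within a part of size ``|p|`` holding counts ``y_p`` there are
    ``|p|! / prod_k y_p^k!`` distinct orderings; parts are independent, so
    the class size is the product of these multinomials.
    """
    solution.validate(partition)
    total = 1
    for pi, p in enumerate(partition.parts):
        size = len(p)
        ways = math.factorial(size)
        for cnt in solution.y[pi]:
            ways //= math.factorial(int(cnt))
        total *= ways
    return total


def restrict_instance(instance: Instance, fragment_indices: Sequence[int]) -> Instance:
    """Sub-instance holding only the given fragments (same n and colors)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Instance(
            n=instance.n,
            fragments=[instance.fragments[i] for i in fragment_indices],
            requirements=instance.requirements[list(fragment_indices)],
            color_names=instance.color_names,
            residue_labels=instance.residue_labels,
        )
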