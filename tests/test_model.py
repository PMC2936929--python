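"""Core model: partitions, decomposition, error evaluation, expansions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdxresolve.model import (
    Instance,
    Interval,
    ResidueAssignment,
    ValidationError,
    compute_parts,
    count_expansions,
    counts_from_assignment,
    decompose_subproblems,
    error_from_counts,
    evaluate_assignment,
    expand_counts,
    part_matrix,
)

from .conftest import random_instance


class TestInterval:
    def test_length_and_containment(self):
        iv = Interval(12, 19)
        assert len(iv) == 8
        assert 12 in iv and 19 in iv and 20 not in iv

    def test_reversed_endpoints_rejected(self):
        with pytest.raises(ValidationError):
            Interval(19, 12)

    def test_zero_start_rejected(self):
        with pytest.raises(ValidationError):
            Interval(0, 4)


class TestInstanceValidation:
    def test_empty_fragment_list_is_valid(self):
        inst = Instance(n=5, fragments=[], requirements=np.zeros((0, 3)))
        assert inst.n_fragments == 0

    def test_fragment_past_end_rejected(self):
        with pytest.raises(ValidationError):
            Instance(n=5, fragments=[Interval(3, 7)], requirements=[[1, 1, 2]])

    def test_negative_requirement_rejected(self):
        with pytest.raises(ValidationError):
            Instance(n=5, fragments=[Interval(1, 3)], requirements=[[1, -1, 3]])

    def test_sum_mismatch_warns_but_accepts(self, recwarn):
        import warnings

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            Instance(n=5, fragments=[Interval(1, 3)], requirements=[[4, 1, 1]])
        assert any("sum" in str(w.message) for w in caught)


class TestComputeParts:
    def test_two_overlapping_fragments(self):
        inst = Instance(n=5, fragments=[Interval(1, 3), Interval(2, 5)],
                        requirements=np.ones((2, 3)))
        parts = compute_parts(inst).parts
        assert parts == [Interval(1, 1), Interval(2, 3), Interval(4, 5)]

    def test_single_full_fragment(self):
        inst = Instance(n=9, fragments=[Interval(1, 9)], requirements=[[3, 3, 3]])
        partition = compute_parts(inst)
        assert partition.parts == [Interval(1, 9)]
        assert partition.sizes.tolist() == [9]

    def test_part_from_specific_fragment_set(self):
        # residues 7..9 lie in exactly fragments 1, 2, 6, 8 (1-based)
        frs = [Interval(2, 9), Interval(7, 14), Interval(1, 3), Interval(12, 20),
               Interval(15, 22), Interval(5, 11), Interval(21, 28), Interval(7, 9),
               Interval(10, 13)]
        inst = Instance(n=28, fragments=frs,
                        requirements=np.array([[len(f), 0, 0] for f in frs]))
        partition = compute_parts(inst)
        idx = partition.parts.index(Interval(7, 9))
        assert partition.fragment_sets[idx] == frozenset({0, 1, 5, 7})

    def test_no_fragments_empty_partition(self):
        inst = Instance(n=4, fragments=[], requirements=np.zeros((0, 3)))
        assert compute_parts(inst).parts == []

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_partition_invariants_random(self, seed):
        """Every part is inside or disjoint from every fragment, parts tile
        the covered residues, and part-matrix rows have consecutive ones."""
        rng = np.random.default_rng(seed)
        inst = random_instance(rng)
        partition = compute_parts(inst)
        covered = set(np.flatnonzero(inst.covered_mask()) + 1)
        assert partition.covered() == covered
        seen = set()
        for pi, p in enumerate(partition.parts):
            res = set(range(p.start, p.end + 1))
            assert not (res & seen)
            seen |= res
            for fi, f in enumerate(inst.fragments):
                fres = set(range(f.start, f.end + 1))
                assert res <= fres or not (res & fres)
                assert (fi in partition.fragment_sets[pi]) == (res <= fres)
        A = part_matrix(inst, partition)
        for row in A:
            ones = np.flatnonzero(row)
            assert np.array_equal(ones, np.arange(ones.min(), ones.max() + 1))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_parts_match_per_residue_oracle(self, seed):
        """Parts are maximal runs of equal per-residue fragment sets."""
        rng = np.random.default_rng(seed)
        inst = random_instance(rng)
        per_res = {}
        for r in range(1, inst.n + 1):
            fs = frozenset(i for i, f in enumerate(inst.fragments) if r in f)
            if fs:
                per_res[r] = fs
        partition = compute_parts(inst)
        for pi, p in enumerate(partition.parts):
            for r in range(p.start, p.end + 1):
                assert per_res[r] == partition.fragment_sets[pi]
            # maximality: neighbors differ
            assert per_res.get(p.start - 1) != partition.fragment_sets[pi]
            assert per_res.get(p.end + 1) != partition.fragment_sets[pi]


class TestDecomposeSubproblems:
    @pytest.mark.parametrize(
        "fragments,expected",
        [
            ([(1, 3), (5, 7)], [[0], [1]]),
            ([(1, 4), (4, 6), (8, 9)], [[0, 1], [2]]),
            ([(1, 3), (2, 5), (4, 8)], [[0, 1, 2]]),
        ],
    )
    def test_component_structure(self, fragments, expected):
        frs = [Interval(*f) for f in fragments]
        inst = Instance(n=9, fragments=frs,
                        requirements=np.array([[len(f), 0, 0] for f in frs]))
        comps = decompose_subproblems(inst).components
        assert [c[0] for c in comps] == expected

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_components_match_pairwise_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instance(rng)
        # union-find over explicit pairwise overlap checks
        parent = list(range(inst.n_fragments))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(inst.n_fragments):
            for j in range(i + 1, inst.n_fragments):
                if inst.fragments[i].overlaps(inst.fragments[j]):
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(inst.n_fragments):
            oracle.setdefault(find(i), set()).add(i)
        comps = decompose_subproblems(inst).components
        assert {frozenset(c[0]) for c in comps} == {
            frozenset(v) for v in oracle.values()
        }


class TestEvaluateAssignment:
    def test_exact_requirement_gives_zero_row(self, fig1_fragment):
        colors = np.zeros(28, dtype=int)
        colors[11:19] = [1, 1, 1, 1, 1, 2, 2, 3]  # counts (5, 2, 1)
        report = evaluate_assignment(fig1_fragment, ResidueAssignment(colors))
        assert report.e[0].tolist() == [0, 0, 0]
        assert report.total == 0

    def test_one_unit_swap_costs_two(self, fig1_fragment):
        colors = np.zeros(28, dtype=int)
        colors[11:19] = [1, 1, 1, 1, 1, 2, 2, 2]  # counts (5, 3, 0)
        report = evaluate_assignment(fig1_fragment, ResidueAssignment(colors))
        assert report.e[0].tolist() == [0, 1, 1]

    def test_degenerate_coloring(self):
        inst = Instance(n=3, fragments=[Interval(1, 3)], requirements=[[1, 1, 1]])
        report = evaluate_assignment(
            inst, ResidueAssignment(np.array([1, 1, 1])))
        assert report.e[0].tolist() == [2, 1, 1]
        assert report.total == 4

    def test_missing_covered_residue_rejected(self, fig1_fragment):
        with pytest.raises(ValidationError):
            evaluate_assignment(fig1_fragment,
                                ResidueAssignment(np.zeros(28, dtype=int)))


class TestCounts:
    def test_direct_count(self):
        inst = Instance(n=3, fragments=[Interval(2, 3)], requirements=[[1, 1]],
                        color_names=("a", "b"))
        partition = compute_parts(inst)
        ra = ResidueAssignment.from_mapping(3, {2: 1, 3: 2})
        y = counts_from_assignment(partition, ra, 2)
        assert y.y.tolist() == [[1, 1]]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_error_depends_on_assignment_only_through_counts(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instance(rng)
        partition = compute_parts(inst)
        covered = np.flatnonzero(inst.covered_mask())
        colors = np.zeros(inst.n, dtype=np.int64)
        colors[covered] = rng.integers(1, inst.K + 1, len(covered))
        ra = ResidueAssignment(colors)
        y = counts_from_assignment(partition, ra, inst.K)
        assert evaluate_assignment(inst, ra).total == \
            error_from_counts(inst, partition, y).total

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_within_part_permutation_preserves_error(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instance(rng)
        partition = compute_parts(inst)
        covered = np.flatnonzero(inst.covered_mask())
        if not len(covered):
            return
        colors = np.zeros(inst.n, dtype=np.int64)
        colors[covered] = rng.integers(1, inst.K + 1, len(covered))
        before = evaluate_assignment(inst, ResidueAssignment(colors)).e
        part = partition.parts[int(rng.integers(len(partition.parts)))]
        seg = slice(part.start - 1, part.end)
        colors[seg] = rng.permutation(colors[seg])
        after = evaluate_assignment(inst, ResidueAssignment(colors)).e
        assert np.array_equal(before, after)


class TestCountExpansions:
    def test_examples(self):
        from hdxresolve.model import CountSolution, Partition

        p1 = Partition(parts=[Interval(1, 1), Interval(2, 2)], fragment_sets=[])
        assert count_expansions(p1, CountSolution([[1, 0], [0, 1]])) == 1
        p2 = Partition(parts=[Interval(1, 3)], fragment_sets=[])
        assert count_expansions(p2, CountSolution([[1, 1, 1]])) == 6
        p3 = Partition(parts=[Interval(1, 2), Interval(3, 5)], fragment_sets=[])
        assert count_expansions(
            p3, CountSolution([[1, 1, 0], [2, 0, 1]])) == 2 * 3

    def test_row_sum_violation_rejected(self):
        from hdxresolve.model import CountSolution, Partition

        p = Partition(parts=[Interval(1, 2)], fragment_sets=[])
        with pytest.raises(ValidationError):
            count_expansions(p, CountSolution([[1, 0, 0]]))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_explicit_enumeration(self, seed):
        """The multinomial product equals the number of distinct colorings
        produced by explicitly permuting colors within parts."""
        rng = np.random.default_rng(seed)
        inst = random_instance(rng, n_max=8, f_max=3)
        partition = compute_parts(inst)
        covered = np.flatnonzero(inst.covered_mask())
        colors = np.zeros(inst.n, dtype=np.int64)
        colors[covered] = rng.integers(1, inst.K + 1, len(covered))
        y = counts_from_assignment(partition, ResidueAssignment(colors), inst.K)
        explicit = {tuple(ra.colors) for ra in expand_counts(partition, y, inst.n)}
        assert len(explicit) == count_expansions(partition, y)
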