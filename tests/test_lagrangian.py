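"""Lagrangian subproblems, dual bounds, subgradient and branch-&-bound."""

import itertools
import math

import numpy as np
import pytest

from hdxresolve.flow import LAMBDA_SCALE
from hdxresolve.ilp import enumerate_optimal, solve_min_error
from hdxresolve.lagrangian import (
    InfeasibleBox,
    SubgradientSchedule,
    branch_and_bound_enumerate,
    evaluate_dual,
    lagrangian_subproblem,
    solve_min_error_bnb,
    subgradient_optimize,
)
from hdxresolve.model import Instance, Interval, compute_parts
from hdxresolve.simulate import SyntheticSpec, generate_instance

from .conftest import random_instance
from .oracles import brute_force_optimal_set


def _quantized(lam):
    return np.rint(np.asarray(lam, dtype=float) * LAMBDA_SCALE) / LAMBDA_SCALE


class TestSubproblem:
    def test_zero_multipliers_consistent_data(self):
        inst, _ = generate_instance(SyntheticSpec(n=20, seed=9))
        partition = compute_parts(inst)
        for k in (1, 2, 3):
            y, value = lagrangian_subproblem(inst, np.zeros(partition.n_parts), k)
            assert value == 0

    def test_huge_positive_multipliers_drive_y_to_zero(self, fig1_fragment):
        partition = compute_parts(fig1_fragment)
        lam = np.full(partition.n_parts, 1000.0)
        y, value = lagrangian_subproblem(fig1_fragment, lam, 1)
        assert (y == 0).all()
        assert value == fig1_fragment.requirements[:, 0].sum()

    def test_infeasible_bounds_signal_prune(self, fig1_fragment):
        partition = compute_parts(fig1_fragment)
        m = partition.n_parts
        with pytest.raises(InfeasibleBox):
            lagrangian_subproblem(fig1_fragment, np.zeros(m), 1,
                                  bounds=(np.ones(m, dtype=int),
                                          np.zeros(m, dtype=int)))

    def test_matches_box_brute_force(self, rng):
        """Subproblem value equals the exhaustive minimum over all integral
        y in the box, for the quantized multipliers."""
        from hdxresolve.model import fragment_part_spans, part_matrix

        for _ in range(30):
            inst = random_instance(rng, n_max=8, f_max=4)
            partition = compute_parts(inst)
            m = partition.n_parts
            A = part_matrix(inst, partition)
            lam = rng.normal(0, 1.5, m)
            lamq = _quantized(lam)
            k = int(rng.integers(1, inst.K + 1))
            y, value = lagrangian_subproblem(inst, lam, k)
            b = inst.requirements[:, k - 1]
            best = min(
                np.abs(A @ np.array(combo) - b).sum() + lamq @ np.array(combo)
                for combo in itertools.product(
                    *[range(s + 1) for s in partition.sizes])
            )
            assert value == pytest.approx(best, abs=1e-9)
            assert np.abs(A @ y - b).sum() + lamq @ y == pytest.approx(best, abs=1e-9)


class TestDual:
    def test_zero_lambda_on_noise_free_instance(self):
        inst, _ = generate_instance(SyntheticSpec(n=24, seed=4))
        partition = compute_parts(inst)
        assert evaluate_dual(inst, np.zeros(partition.n_parts)) == 0

    def test_lower_bounds_the_optimum_for_any_lambda(self, rng):
        for _ in range(20):
            inst = random_instance(rng)
            optimum, _ = solve_min_error(inst)
            m = compute_parts(inst).n_parts
            for lam in (rng.normal(0, 2, m), rng.uniform(-3, 3, m), np.zeros(m)):
                assert evaluate_dual(inst, lam) <= optimum + 1e-9

    def test_converged_bound_reaches_lp_relaxation(self, rng):
        """Integral subproblems mean the dual optimum equals the LP
        relaxation of the part-level ILP; the subgradient gets close."""
        from scipy.optimize import linprog
        from hdxresolve.ilp import _improved_matrices

        for _ in range(8):
            inst = random_instance(rng, n_max=10, f_max=5)
            optimum, _ = solve_min_error(inst)
            partition = compute_parts(inst)
            if partition.n_parts == 0:
                continue
            A_ub, b_ub, A_eq, b_eq, c, v_up, e_up, n_v = _improved_matrices(
                inst, partition)
            bounds = [(0, u) for u in v_up] + [(0, None)] * (len(c) - n_v)
            lp = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                         bounds=bounds, method="highs")
            state = subgradient_optimize(inst)
            assert state.best_bound <= optimum + 1e-9
            assert state.best_bound >= lp.fun - 0.5

    def test_noise_free_terminates_with_feasible_zero(self):
        inst, _ = generate_instance(SyntheticSpec(n=30, seed=8))
        state = subgradient_optimize(inst)
        assert state.best_bound == 0
        assert state.feasible_y is not None

    def test_theta_schedule_monotone_in_range(self, rng):
        inst = random_instance(rng)
        sched = SubgradientSchedule(max_iterations=80, patience=3)
        state = subgradient_optimize(inst, schedule=sched)
        assert 0 < state.theta <= 2.0

    def test_lam_bar_supplies_sum_to_zero(self, rng):
        inst = random_instance(rng)
        state = subgradient_optimize(
            inst, schedule=SubgradientSchedule(max_iterations=10))
        assert state.lam_bar.sum() == pytest.approx(0, abs=1e-9)
        assert len(state.lam_bar) == compute_parts(inst).n_parts + 1


class TestBranchAndBound:
    def test_unique_solution_instance(self):
        inst = Instance(n=2, fragments=[Interval(1, 1), Interval(2, 2)],
                        requirements=[[1, 0, 0], [0, 1, 0]])
        ss = branch_and_bound_enumerate(inst)
        assert ss.optimum == 0 and ss.n_solutions == 1

    def test_identical_solution_sets_with_ilp(self, rng):
        for _ in range(25):
            inst = random_instance(rng)
            ss_l = branch_and_bound_enumerate(inst)
            ss_i = enumerate_optimal(inst)
            assert ss_l.optimum == ss_i.optimum
            assert [s.key() for s in ss_l.solutions] == \
                [s.key() for s in ss_i.solutions]
            assert ss_l.multiplicities == ss_i.multiplicities

    def test_enumeration_matches_brute_force(self, rng):
        from .oracles import expand_solution_set

        for _ in range(10):
            inst = random_instance(rng, n_max=9, f_max=4)
            ss = branch_and_bound_enumerate(inst)
            bf_opt, bf_set = brute_force_optimal_set(inst)
            assert ss.optimum == bf_opt
            assert expand_solution_set(inst, ss) == bf_set

    def test_solve_min_error_bnb_matches_milp(self, rng):
        for _ in range(15):
            inst = random_instance(rng)
            opt_l, sol = solve_min_error_bnb(inst)
            opt_i, _ = solve_min_error(inst)
            assert opt_l == opt_i

    def test_deterministic_across_runs(self, rng):
        inst = random_instance(rng)
        s1 = branch_and_bound_enumerate(inst)
        s2 = branch_and_bound_enumerate(inst)
        assert [a.key() for a in s1.solutions] == [a.key() for a in s2.solutions]
        st1 = subgradient_optimize(inst)
        st2 = subgradient_optimize(inst)
        assert np.array_equal(st1.lam, st2.lam)
        assert st1.best_bound == st2.best_bound
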