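"""iMAT MILP construction, optimality, sensitivity and consensus."""

import numpy as np
import pytest

from imatpipe.gem_core import stoichiometric_matrix
from imatpipe.imat import (ActivityCallSet, build_imat, robustness_consensus,
                           sensitivity_calls, solve_imat)
from imatpipe.omics_integration import ReactionExpressionState

from conftest import build_model
from oracles import ImatEnumerationOracle


def state(r_high=(), r_low=()):
    return ReactionExpressionState(values={}, r_high=set(r_high),
                                   r_low=set(r_low))


@pytest.fixture()
def branched_model():
    """EX_A => A, R1: A->B (R_H), R2: B->C (R_H), R3: B->D (R_L), EX_C, EX_D."""
    return build_model(
        {
            "EX_A": {"A": -1},
            "R1": {"A": -1, "B": 1},
            "R2": {"B": -1, "C": 1},
            "R3": {"B": -1, "D": 1},
            "EX_C": {"C": -1},
            "EX_D": {"D": -1},
        },
        {"EX_A": (-10, 0), "R1": (0, 10), "R2": (0, 10), "R3": (0, 10),
         "EX_C": (0, 10), "EX_D": (0, 10)},
    )


def oracle_for(model, problem):
    return ImatEnumerationOracle(
        stoichiometric_matrix(model), problem.lb, problem.ub,
        problem.rh, problem.rl, problem.epsilon)


class TestBuildImat:
    def test_binary_variable_count(self, branched_model):
        problem = build_imat(branched_model,
                             state(r_high=("R1", "R2"), r_low=("R3",)))
        assert problem.n_binaries == 2 * 2 + 1

    def test_empty_sets_pure_feasibility(self, branched_model):
        sol = solve_imat(build_imat(branched_model, state()))
        assert sol.status == "optimal" and sol.objective == 0

    def test_unknown_reaction_rejected(self, branched_model):
        with pytest.raises(KeyError):
            build_imat(branched_model, state(r_high=("nope",)))

    def test_forward_indicator_forces_epsilon(self, branched_model):
        """With y+ = 1, Eq (4) collapses to v >= eps (symbolic check)."""
        problem = build_imat(branched_model, state(r_high=("R1",)),
                             epsilon=1.0)
        i = problem.index_of("R1")
        # v_i + y+ (lb_i - eps) >= lb_i with lb_i = 0, y+ = 1  ->  v_i >= eps
        assert problem.lb[i] == 0.0
        assert problem.lb[i] - (problem.lb[i] - problem.epsilon) == 1.0


class TestSolveImat:
    def test_branched_chain_objective(self, branched_model):
        st_ = state(r_high=("R1", "R2"), r_low=("R3",))
        problem = build_imat(branched_model, st_, epsilon=1.0)
        sol = solve_imat(problem)
        assert sol.status == "optimal"
        assert sol.objective == 3  # R1, R2 active, R3 silent
        assert oracle_for(branched_model, problem).objective() == 3
        assert sol.x["R3"] == 1
        assert abs(sol.fluxes["R3"]) < 1e-9

    def test_all_bounds_zero_only_inactivity_satisfiable(self, branched_model):
        for rxn in branched_model.reactions:
            rxn.bounds = (0.0, 0.0)
        st_ = state(r_high=("R1", "R2"), r_low=("R3",))
        sol = solve_imat(build_imat(branched_model, st_))
        assert sol.objective == 1  # |R_L| only

    def test_solution_invariants(self, branched_model):
        st_ = state(r_high=("R1", "R2", "EX_C"), r_low=("R3", "EX_D"))
        sol = solve_imat(build_imat(branched_model, st_))
        total = (sum(sol.y_plus.values()) + sum(sol.y_minus.values())
                 + sum(sol.x.values()))
        assert sol.objective == total
        assert 0 <= sol.objective <= 5
        for rid in sol.y_plus:
            assert sol.y_plus[rid] + sol.y_minus[rid] <= 1

    def test_deterministic_for_fixed_seed(self, branched_model):
        st_ = state(r_high=("R1", "R2"), r_low=("R3",))
        a = solve_imat(build_imat(branched_model, st_), seed=3)
        b = solve_imat(build_imat(branched_model, st_), seed=3)
        assert a.objective == b.objective
        assert a.y_plus == b.y_plus and a.x == b.x

    def test_reverse_activity_needs_corrected_constraint(self):
        """An R_H reaction restricted to reverse flux is credited by the
        corrected reverse-activity constraint; the as-printed variant
        (y- feasible only while v >= -eps) cannot express it."""
        model = build_model(
            # R written A -> B but bounded to run only in reverse (B -> A);
            # B is taken up, A is secreted, so the pathway demands v_R <= 0
            {"EX_A": {"A": -1}, "R": {"A": -1, "B": 1}, "EX_B": {"B": -1}},
            {"EX_A": (2, 10), "R": (-10, 0), "EX_B": (-10, 0)},
        )
        st_ = state(r_high=("R",))
        corrected = solve_imat(build_imat(model, st_))
        assert corrected.objective == 1
        assert corrected.fluxes["R"] <= -1.0
        # as printed, y- = 0 forces v >= v_max and y- = 1 forces v >= -eps,
        # so the demanded reverse flux of -2 is unreachable altogether
        printed = solve_imat(build_imat(model, st_, printed_eq5=True))
        assert printed.status == "infeasible"


class TestSensitivity:
    def test_branched_chain_calls(self, branched_model):
        st_ = state(r_high=("R1", "R2"), r_low=("R3",))
        calls = sensitivity_calls(branched_model, st_)
        assert calls.base_objective == 3
        fa, fi = calls.forced_objectives["R3"]
        assert fa == 2 and fi == 3  # forcing R3 active costs one unit
        assert calls.calls["R3"] == "inactive"
        assert calls.calls["R1"] == "active"
        fa1, fi1 = calls.forced_objectives["R1"]
        assert fa1 == 3 and fi1 < 3

    def test_parallel_redundant_reactions_undetermined(self):
        model = build_model(
            {"EX_A": {"A": -1}, "Ra": {"A": -1, "C": 1},
             "Rb": {"A": -1, "C": 1}, "EX_C": {"C": -1}},
            {"EX_A": (-10, 0), "Ra": (0, 10), "Rb": (0, 10),
             "EX_C": (1.0, 10)},  # demand forces some route
        )
        calls = sensitivity_calls(model, state(r_high=("EX_C",)))
        assert calls.calls["Ra"] == "undetermined"
        assert calls.calls["Rb"] == "undetermined"
        assert calls.calls["EX_C"] == "active"

    def test_forced_objectives_never_exceed_optimum(self, branched_model):
        st_ = state(r_high=("R1", "EX_C"), r_low=("R3",))
        calls = sensitivity_calls(branched_model, st_)
        for fa, fi in calls.forced_objectives.values():
            assert fa <= calls.base_objective + 1e-6
            assert fi <= calls.base_objective + 1e-6

    def test_matches_enumeration_oracle_on_random_instance(self):
        from imatpipe.synthetic_data import generate_toy_gem

        model, _ = generate_toy_gem(n_pathways=2, reactions_per_pathway=3,
                                    n_blocked=0, seed=21)
        rng = np.random.default_rng(22)
        rids = [r.id for r in model.reactions]
        chosen = list(rng.choice(rids, size=4, replace=False))
        st_ = state(r_high=chosen[:2], r_low=chosen[2:])
        problem = build_imat(model, st_)
        oracle = oracle_for(model, problem)
        assert solve_imat(problem).objective == oracle.objective()
        calls = sensitivity_calls(model, st_)
        for j, rid in enumerate(problem.reaction_ids):
            assert calls.calls[rid] == oracle.call(j), rid


class TestRobustnessConsensus:
    def _cs(self, call, pair):
        return ActivityCallSet(calls={"R": call}, threshold_pair=pair)

    @pytest.mark.parametrize(
        "votes, expected",
        [
            (("active", "active", "active"), "active"),
            (("inactive",) * 3, "inactive"),
            (("active", "inactive", "active"), "undetermined"),
            (("active", "undetermined", "active"), "undetermined"),
            (("undetermined",) * 3, "undetermined"),
        ],
    )
    def test_unanimity_rule(self, votes, expected):
        sets = [self._cs(v, p) for v, p in zip(votes, "abc")]
        assert robustness_consensus(sets).calls["R"] == expected

    def test_provenance_keeps_per_pair_calls(self):
        sets = [self._cs("active", "30_70"), self._cs("inactive", "33_66")]
        cons = robustness_consensus(sets)
        assert cons.provenance["R"] == {"30_70": "active",
                                        "33_66": "inactive"}

    def test_mismatched_reaction_sets_rejected(self):
        a = ActivityCallSet(calls={"R": "active"}, threshold_pair="a")
        b = ActivityCallSet(calls={"Q": "active"}, threshold_pair="b")
        with pytest.raises(ValueError):
            robustness_consensus([a, b])

    def test_needs_at_least_two(self):
        with pytest.raises(ValueError):
            robustness_consensus([self._cs("active", "a")])
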