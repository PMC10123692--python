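"""Lipid boundary expansion, FVA, blocked-reaction and dead-end removal."""

import numpy as np
import pytest

from imatpipe.gem_core import PROVENANCE_KEY, stoichiometric_matrix
from imatpipe.model_prep import (InfeasibleModelError, LipidLookupError,
                                 expand_lipid_boundary, flux_variability,
                                 reduce_model, remove_blocked,
                                 remove_dead_end_metabolites)
from imatpipe.synthetic_data import generate_toy_gem

from conftest import build_model
from oracles import lp_range


class TestExpandLipidBoundary:
    @pytest.fixture()
    def lipid_model(self):
        return build_model(
            {
                "EX_A": {"A_c": -1},
                "T1": {"A_c": -1, "pail_c": 1},
                "T2": {"A_c": -1, "pail_m": 1},
                "T3": {"A_c": -1, "chsterol_c": 1},
            },
            {"EX_A": (-10, 10)},
        )

    def test_multi_compartment_lipid(self, lipid_model):
        out = expand_lipid_boundary(lipid_model, [("pail", ["c", "m"])])
        assert "pail_bd" in out.metabolites
        added = [r for r in out.reactions
                 if r.annotation.get(PROVENANCE_KEY)]
        transports = [r for r in added
                      if r.annotation[PROVENANCE_KEY] == "transport-to-boundary"]
        sinks = [r for r in added if r.annotation[PROVENANCE_KEY] == "sink"]
        assert len(transports) == 2 and len(sinks) == 1
        assert sinks[0].id == "SK_pail_bd"
        assert all(r.bounds == (-1000.0, 1000.0) for r in added)

    def test_single_compartment_lipid_gets_sink(self, lipid_model):
        out = expand_lipid_boundary(lipid_model, [("chsterol", ["c"])])
        assert "chsterol_bd" not in out.metabolites
        assert "SK_chsterol_c" in out.reactions
        added = [r for r in out.reactions if r.annotation.get(PROVENANCE_KEY)]
        assert len(added) == 1

    def test_empty_list_is_noop(self, lipid_model):
        out = expand_lipid_boundary(lipid_model, [])
        assert len(out.reactions) == len(lipid_model.reactions)
        assert len(out.metabolites) == len(lipid_model.metabolites)

    def test_unknown_lipid_raises(self, lipid_model):
        with pytest.raises(LipidLookupError, match="tag"):
            expand_lipid_boundary(lipid_model, [("tag", ["c", "m"])])

    def test_added_entity_counts(self, lipid_model):
        lipids = [("pail", ["c", "m"]), ("chsterol", ["c"])]
        out = expand_lipid_boundary(lipid_model, lipids)
        # one boundary metabolite per multi-compartment lipid, one transport
        # per instance, one sink per measured lipid
        assert len(out.metabolites) - len(lipid_model.metabolites) == 1
        assert len(out.reactions) - len(lipid_model.reactions) == 2 + 2


class TestFluxVariability:
    def test_linear_chain_interior_range(self, chain_model):
        fva = flux_variability(chain_model)
        # vertex enumeration on the 1-dof polytope: flux in [0, 10]
        assert fva.at["AB", "minimum"] == pytest.approx(0.0, abs=1e-9)
        assert fva.at["AB", "maximum"] == pytest.approx(10.0, abs=1e-6)

    def test_no_producer_forces_zero(self):
        model = build_model(
            {"EX_A": {"A": -1}, "R": {"B": -1, "C": 1}, "EX_C": {"C": -1}},
            {"EX_A": (-10, 0), "R": (0, 10), "EX_C": (0, 10)},
        )
        fva = flux_variability(model)
        assert fva.loc["R"].abs().max() < 1e-9

    def test_closed_system_all_zero(self, chain_model):
        chain_model.reactions.EX_A.bounds = (0, 0)
        chain_model.reactions.EX_B.bounds = (0, 0)
        fva = flux_variability(chain_model)
        assert fva.abs().to_numpy().max() < 1e-9

    def test_infeasible_model_raises_before_solves(self, chain_model):
        chain_model.reactions.EX_B.bounds = (5.0, 10.0)
        chain_model.reactions.EX_A.bounds = (0.0, 0.0)
        with pytest.raises(InfeasibleModelError):
            flux_variability(chain_model)


class TestRemoveBlocked:
    def test_dangling_side_branch_removed(self):
        model = build_model(
            {
                "EX_A": {"A": -1},
                "AB": {"A": -1, "B": 1},
                "EX_B": {"B": -1},
                "BX": {"B": -1, "X": 1},  # X has no consumer or exchange
            },
            {"EX_A": (-10, 0), "AB": (0, 10), "EX_B": (0, 10), "BX": (0, 10)},
        )
        out, report = remove_blocked(model)
        assert report.removed_blocked == ["BX"]
        assert "AB" in out.reactions

    def test_open_network_untouched(self, chain_model):
        out, report = remove_blocked(chain_model)
        assert report.removed_blocked == []
        assert len(out.reactions) == 3

    def test_planted_blocked_found_exactly(self):
        model, truth = generate_toy_gem(n_pathways=3, reactions_per_pathway=3,
                                        n_blocked=3, seed=5)
        out, report = remove_blocked(model)
        assert sorted(report.removed_blocked) == sorted(truth.blocked_reactions)
        # oracle: per-reaction LP range at tolerance 1e-9
        S = stoichiometric_matrix(model)
        lb = [r.lower_bound for r in model.reactions]
        ub = [r.upper_bound for r in model.reactions]
        for j, rxn in enumerate(model.reactions):
            lo, hi = lp_range(S, lb, ub, j)
            assert (abs(lo) < 1e-9 and abs(hi) < 1e-9) == \
                (rxn.id in report.removed_blocked)

    def test_idempotent(self):
        model, _ = generate_toy_gem(n_pathways=3, reactions_per_pathway=3,
                                    n_blocked=2, seed=6)
        once, rep1 = remove_blocked(model)
        twice, rep2 = remove_blocked(once)
        assert rep2.removed_blocked == []
        assert sorted(r.id for r in twice.reactions) == \
            sorted(r.id for r in once.reactions)

    def test_surviving_bounds_unchanged(self):
        model, _ = generate_toy_gem(seed=7)
        out, _ = remove_blocked(model)
        for rxn in out.reactions:
            assert rxn.bounds == model.reactions.get_by_id(rxn.id).bounds


class TestDeadEndRemoval:
    def test_orphans_removed_to_fixed_point(self):
        model, truth = generate_toy_gem(n_pathways=2, reactions_per_pathway=3,
                                        n_blocked=2, seed=8)
        blocked_free, _ = remove_blocked(model)
        out, report = remove_dead_end_metabolites(blocked_free)
        assert report.iterations <= 3
        assert all(len(m.reactions) > 0 for m in out.metabolites)
        # the dangling products of the planted blocked reactions are gone
        for b in range(2):
            assert f"dead_{b + 1}_c" in report.removed_dead_end

    def test_clean_model_unchanged(self, chain_model):
        out, report = remove_dead_end_metabolites(chain_model)
        assert report.removed_dead_end == []
        assert len(out.metabolites) == len(chain_model.metabolites)


class TestReductionSoundness:
    def test_feasible_space_preserved(self):
        """Random feasible vertices survive reduction in both directions."""
        from scipy.optimize import linprog

        model, _ = generate_toy_gem(n_pathways=3, reactions_per_pathway=5,
                                    n_blocked=2, seed=9)
        reduced, report = reduce_model(model)
        keep = [r.id for r in reduced.reactions]
        S_full = stoichiometric_matrix(model)
        S_red = stoichiometric_matrix(reduced)
        rng = np.random.default_rng(10)

        def vertices(model_, S, n):
            lb = [r.lower_bound for r in model_.reactions]
            ub = [r.upper_bound for r in model_.reactions]
            out = []
            for _ in range(n):
                c = rng.normal(size=S.shape[1])
                res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                              bounds=list(zip(lb, ub)), method="highs")
                assert res.status == 0
                out.append(res.x)
            return out

        full_ids = [r.id for r in model.reactions]
        red_index = {rid: i for i, rid in enumerate(keep)}
        for v in vertices(model, S_full, 25):
            proj = np.zeros(len(keep))
            for rid, val in zip(full_ids, v):
                if rid in red_index:
                    proj[red_index[rid]] = val
            assert np.abs(S_red @ proj).max() < 1e-6
        for v in vertices(reduced, S_red, 25):
            lifted = np.zeros(len(full_ids))
            for rid, val in zip(keep, v):
                lifted[full_ids.index(rid)] = val
            assert np.abs(S_full @ lifted).max() < 1e-6
            for val, rxn in zip(lifted, model.reactions):
                assert rxn.lower_bound - 1e-6 <= val <= rxn.upper_bound + 1e-6
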