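"""Model refinement: lipid boundary expansion and reduction by FVA.

Whole-cell lipid measurements cannot be attributed to a single intracellular
compartment, so the model is expanded with a *boundary* compartment: each
measured lipid present in several compartments gets one boundary metabolite,
transport reactions from every intracellular instance into it, and a sink on
the boundary pool; lipids restricted to a single compartment get a sink
directly on the intracellular instance.  Lipidomic rate bounds are later
imposed on those sinks.

Reduction removes *blocked* reactions (flux variability range [0, 0] over the
whole feasible space) and then iteratively strips dead-end metabolites (left
participating in no reaction) together with reactions whose stoichiometry has
become empty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import cobra
import pandas as pd
from cobra import Metabolite, Reaction
from cobra.flux_analysis import flux_variability_analysis

from .gem_core import PROVENANCE_KEY

__all__ = [
    "BOUNDARY_COMPARTMENT",
    "ReductionReport",
    "expand_lipid_boundary",
    "flux_variability",
    "remove_blocked",
    "remove_dead_end_metabolites",
    "reduce_model",
]

BOUNDARY_COMPARTMENT = "bd"

#: blocked-reaction tolerance — solver-noise floor
BLOCKED_TOL = 1e-9

#: default span of added sink / boundary-transport reactions; reversible so
#: that measured rate bounds of either sign can be imposed later
SINK_BOUNDS = (-1000.0, 1000.0)


@dataclass
class ReductionReport:
    removed_blocked: list = field(default_factory=list)
    removed_dead_end: list = field(default_factory=list)
    iterations: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [(rid, "blocked") for rid in self.removed_blocked]
        rows += [(mid, "dead_end") for mid in self.removed_dead_end]
        return pd.DataFrame(rows, columns=["id", "reason"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class LipidLookupError(KeyError):
    """A measured lipid was not found in any of its stated compartments."""


def expand_lipid_boundary(
    model: cobra.Model,
    measured_lipids: Sequence[Tuple[str, Sequence[str]]],
    boundary_compartment: str = BOUNDARY_COMPARTMENT,
) -> cobra.Model:
    """Return a copy of ``model`` expanded with a boundary lipid compartment.

    ``measured_lipids`` lists ``(lipid_base_id, compartments)`` pairs; the
    metabolite for base ``L`` in compartment ``c`` is looked up as ``L_c``.
    Multi-compartment lipids get one boundary metabolite ``L_bd``, one
    transport reaction per intracellular instance and one sink on the
    boundary pool; single-compartment lipids get a sink on the intracellular
    instance.  Added reactions carry a provenance annotation.
    """
    out = model.copy()
    for base, comps in measured_lipids:
        instances = []
        for comp in comps:
            mid = f"{base}_{comp}"
            if mid in out.metabolites:
                instances.append(out.metabolites.get_by_id(mid))
        if not instances:
            raise LipidLookupError(
                f"lipid {base!r} not found in any of compartments {list(comps)}"
            )
        if len(instances) > 1:
            bmet = Metabolite(
                f"{base}_{boundary_compartment}",
                name=f"{base} (boundary pool)",
                compartment=boundary_compartment,
            )
            out.add_metabolites([bmet])
            new_rxns = []
            for met in instances:
                t = Reaction(
                    f"T_{base}_{met.compartment}_{boundary_compartment}",
                    lower_bound=SINK_BOUNDS[0],
                    upper_bound=SINK_BOUNDS[1],
                )
                t.add_metabolites({met: -1.0, bmet: 1.0})
                t.annotation[PROVENANCE_KEY] = "transport-to-boundary"
                new_rxns.append(t)
            sk = Reaction(
                f"SK_{base}_{boundary_compartment}",
                lower_bound=SINK_BOUNDS[0],
                upper_bound=SINK_BOUNDS[1],
            )
            sk.add_metabolites({bmet: -1.0})
            sk.annotation[PROVENANCE_KEY] = "sink"
            new_rxns.append(sk)
            out.add_reactions(new_rxns)
        else:
            met = instances[0]
            sk = Reaction(
                f"SK_{base}_{met.compartment}",
                lower_bound=SINK_BOUNDS[0],
                upper_bound=SINK_BOUNDS[1],
            )
            sk.add_metabolites({met: -1.0})
            sk.annotation[PROVENANCE_KEY] = "sink"
            out.add_reactions([sk])
    return out


class InfeasibleModelError(RuntimeError):
    pass


def _assert_feasible(model: cobra.Model) -> None:
    with model as m:
        m.objective = m.problem.Objective(0)
        m.slim_optimize()
        status = m.solver.status
    if status != "optimal":
        raise InfeasibleModelError(
            f"base model {model.id!r} is infeasible (solver status {status})"
        )


def flux_variability(
    model: cobra.Model,
    reactions: Optional[Iterable] = None,
    fraction_of_optimum: float = 0.0,
) -> pd.DataFrame:
    """Per-reaction [min, max] flux over {v : S v = 0, lb <= v <= ub}.

    Runs with no objective-optimality constraint by default
    (``fraction_of_optimum=0``): blocked-status detection needs the full
    feasible space, not the optimal-face slice.  Raises
    :class:`InfeasibleModelError` before any per-reaction solve if the base
    model is infeasible.  Returns a DataFrame with columns ``minimum`` and
    ``maximum`` indexed by reaction id.
    """
    _assert_feasible(model)
    return flux_variability_analysis(
        model,
        reaction_list=reactions,
        fraction_of_optimum=fraction_of_optimum,
        processes=1,
    )


def remove_blocked(
    model: cobra.Model, tol: float = BLOCKED_TOL
) -> Tuple[cobra.Model, ReductionReport]:
    """Remove reactions whose flux variability range is [0, 0] within ``tol``."""
    fva = flux_variability(model)
    blocked = [
        rid
        for rid in fva.index
        if abs(fva.at[rid, "minimum"]) < tol and abs(fva.at[rid, "maximum"]) < tol
    ]
    out = model.copy()
    with warnings.catch_warnings():
        # cobra's Model.remove_reactions passes single members to
        # Group.remove_members, tripping its own list-argument warning
        warnings.simplefilter("ignore", UserWarning)
        out.remove_reactions([out.reactions.get_by_id(r) for r in blocked],
                             remove_orphans=False)
    return out, ReductionReport(removed_blocked=sorted(blocked))


def remove_dead_end_metabolites(
    model: cobra.Model,
) -> Tuple[cobra.Model, ReductionReport]:
    """Strip metabolites in no reaction, iterated to a fixed point.

    A removal round also drops reactions whose stoichiometry has become
    empty, which can orphan further metabolites; rounds repeat until nothing
    changes.
    """
    out = model.copy()
    report = ReductionReport()
    while True:
        orphans = [m for m in out.metabolites if len(m.reactions) == 0]
        empty_rxns = [r for r in out.reactions if len(r.metabolites) == 0]
        if not orphans and not empty_rxns:
            break
        report.iterations += 1
        report.removed_dead_end.extend(sorted(m.id for m in orphans))
        out.remove_metabolites(orphans)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out.remove_reactions(empty_rxns)
    return out, report


def reduce_model(
    model: cobra.Model, tol: float = BLOCKED_TOL
) -> Tuple[cobra.Model, ReductionReport]:
    """Blocked-reaction removal followed by dead-end metabolite stripping."""
    out, rep1 = remove_blocked(model, tol=tol)
    out, rep2 = remove_dead_end_metabolites(out)
    return out, ReductionReport(
        removed_blocked=rep1.removed_blocked,
        removed_dead_end=rep2.removed_dead_end,
        iterations=rep2.iterations,
    )
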