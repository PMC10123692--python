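"""iMAT: transcriptome-consistent flux activity by mixed-integer programming.

Given reaction sets R_H (highly expressed) and R_L (lowly expressed), the
MILP seeks a steady-state flux vector maximizing the number of reactions
whose activity agrees with expression:

    max  sum_{i in R_H} (y+_i + y-_i)  +  sum_{i in R_L} x_i
    s.t. S v = 0
         v_min <= v <= v_max
         v_i + y+_i (v_min,i - eps) >= v_min,i      (i in R_H)
         v_i + y-_i (v_max,i + eps) <= v_max,i      (i in R_H)
         (1 - x_i) v_min,i <= v_i <= (1 - x_i) v_max,i   (i in R_L)

y+_i = 1 forces forward activity (v_i >= eps), y-_i = 1 reverse activity
(v_i <= -eps); x_i = 1 forces inactivity (v_i = 0).  eps > 0 is the minimum
flux magnitude that counts as "active".

Because the optimum is typically degenerate, per-reaction activity is called
by *sensitivity analysis*: two additional MILPs per reaction, one forcing
|v_i| >= eps and one forcing v_i = 0.  A reaction is called active when
forcing it inactive degrades the optimum while forcing it active does not
(and symmetrically for inactive); when both forced problems attain the
unconstrained optimum the reaction stays undetermined.  A *robustness
consensus* across several percentile threshold pairs keeps only reactions
with a unanimous, determined call.

Solved with HiGHS via scipy.optimize.milp at zero MIP gap; the solve is
deterministic for a fixed problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import cobra
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .gem_core import stoichiometric_matrix
from .omics_integration import ReactionExpressionState

__all__ = [
    "DEFAULT_EPSILON",
    "ImatProblem",
    "ImatSolution",
    "ActivityCallSet",
    "build_imat",
    "solve_imat",
    "sensitivity_calls",
    "robustness_consensus",
]

DEFAULT_EPSILON = 1.0

#: box applied to reactions with infinite declared bounds (standard iMAT scaling)
DEFAULT_BOX = 1000.0

#: absolute tolerance when comparing (integer-valued) MILP objectives
OBJ_TOL = 1e-6


@dataclass(frozen=True)
class ImatProblem:
    """An assembled iMAT instance; immutable, `with_forced` derives variants."""

    reaction_ids: Tuple[str, ...]
    S: sparse.csr_matrix  # metabolites x reactions
    lb: np.ndarray
    ub: np.ndarray
    rh: Tuple[int, ...]  # indices into reaction_ids
    rl: Tuple[int, ...]
    epsilon: float = DEFAULT_EPSILON
    forced: Optional[Tuple[int, str]] = None  # (reaction index, mode)
    printed_eq5: bool = False  # vacuous ">=" variant of the reverse constraint

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if set(self.rh) & set(self.rl):
            raise ValueError("R_H and R_L overlap")

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_binaries(self) -> int:
        return 2 * len(self.rh) + len(self.rl)

    def index_of(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)

    def with_forced(self, reaction_id: str, mode: str) -> "ImatProblem":
        """Derive a problem forcing one reaction active-either or inactive."""
        if mode not in {"active-forward", "active-reverse", "active-either",
                        "inactive"}:
            raise ValueError(f"unknown forced mode {mode!r}")
        return replace(self, forced=(self.index_of(reaction_id), mode))


def build_imat(
    model: cobra.Model,
    state: ReactionExpressionState,
    epsilon: float = DEFAULT_EPSILON,
    printed_eq5: bool = False,
) -> ImatProblem:
    """Assemble the iMAT MILP from a bounded model and reaction states."""
    reaction_ids = tuple(r.id for r in model.reactions)
    known = set(reaction_ids)
    for rid in state.r_high | state.r_low:
        if rid not in known:
            raise KeyError(f"reaction {rid!r} in R_H/R_L but not in the model")
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    lb = np.clip(lb, -DEFAULT_BOX, DEFAULT_BOX)
    ub = np.clip(ub, -DEFAULT_BOX, DEFAULT_BOX)
    S = sparse.csr_matrix(stoichiometric_matrix(model))
    idx = {rid: i for i, rid in enumerate(reaction_ids)}
    rh = tuple(sorted(idx[r] for r in state.r_high))
    rl = tuple(sorted(idx[r] for r in state.r_low))
    return ImatProblem(
        reaction_ids=reaction_ids,
        S=S,
        lb=lb,
        ub=ub,
        rh=rh,
        rl=rl,
        epsilon=epsilon,
        printed_eq5=printed_eq5,
    )


@dataclass
class ImatSolution:
    status: str  # "optimal" | "infeasible"
    objective: float  # Eq (1) count at the optimum; -inf when infeasible
    fluxes: Optional[pd.Series] = None
    y_plus: Dict[str, int] = field(default_factory=dict)
    y_minus: Dict[str, int] = field(default_factory=dict)
    x: Dict[str, int] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_imat(problem: ImatProblem, seed: int = 0) -> ImatSolution:
    """Solve to proven optimality (zero MIP gap).

    ``seed`` is accepted for interface uniformity; HiGHS is deterministic for
    a fixed problem, so the seed does not influence the result.
    """
    del seed
    n = problem.n_reactions
    h, l = len(problem.rh), len(problem.rl)
    has_forced_either = (
        problem.forced is not None and problem.forced[1] == "active-either"
    )
    nv = n + 2 * h + l + (1 if has_forced_either else 0)
    off_yp, off_ym, off_x = n, n + h, n + 2 * h
    d_idx = n + 2 * h + l  # auxiliary direction binary of forced-active

    lo = np.concatenate([problem.lb, np.zeros(nv - n)])
    hi = np.concatenate([problem.ub, np.ones(nv - n)])
    integrality = np.concatenate([np.zeros(n), np.ones(nv - n)])
    eps = problem.epsilon

    rows: List[Tuple[dict, float, float]] = []  # (coeffs, lower, upper)

    # mass balance S v = 0
    Sc = problem.S.tocoo()
    bal: Dict[int, dict] = {}
    for i, j, val in zip(Sc.row, Sc.col, Sc.data):
        bal.setdefault(i, {})[j] = val
    for coeffs in bal.values():
        rows.append((coeffs, 0.0, 0.0))

    for k, i in enumerate(problem.rh):
        # forward activity: v_i + y+ (lb_i - eps) >= lb_i
        rows.append(({i: 1.0, off_yp + k: problem.lb[i] - eps},
                     problem.lb[i], np.inf))
        if problem.printed_eq5:
            # as-printed variant (cannot express reverse activity)
            rows.append(({i: 1.0, off_ym + k: problem.ub[i] + eps},
                         problem.ub[i], np.inf))
        else:
            # reverse activity: v_i + y- (ub_i + eps) <= ub_i
            rows.append(({i: 1.0, off_ym + k: problem.ub[i] + eps},
                         -np.inf, problem.ub[i]))
        rows.append(({off_yp + k: 1.0, off_ym + k: 1.0}, -np.inf, 1.0))

    for k, i in enumerate(problem.rl):
        # (1 - x) lb <= v <= (1 - x) ub
        rows.append(({i: 1.0, off_x + k: problem.lb[i]}, problem.lb[i], np.inf))
        rows.append(({i: 1.0, off_x + k: problem.ub[i]}, -np.inf, problem.ub[i]))

    if problem.forced is not None:
        j, mode = problem.forced
        if mode == "inactive":
            lo[j] = 0.0
            hi[j] = 0.0
            if problem.lb[j] > 0 or problem.ub[j] < 0:
                return ImatSolution(status="infeasible", objective=-np.inf)
        elif mode == "active-forward":
            lo[j] = max(lo[j], eps)
        elif mode == "active-reverse":
            hi[j] = min(hi[j], -eps)
        else:  # active-either, via direction binary d
            # d=1 -> v_j >= eps ; d=0 -> v_j <= -eps
            rows.append(({j: 1.0, d_idx: -(eps - problem.lb[j])},
                         problem.lb[j], np.inf))
            rows.append(({j: 1.0, d_idx: -(problem.ub[j] + eps)},
                         -np.inf, -eps))
        if lo[j] > hi[j]:
            return ImatSolution(status="infeasible", objective=-np.inf)

    A = sparse.lil_matrix((len(rows), nv))
    cl = np.empty(len(rows))
    cu = np.empty(len(rows))
    for r, (coeffs, lo_r, up_r) in enumerate(rows):
        for j, val in coeffs.items():
            A[r, j] = val
        cl[r], cu[r] = lo_r, up_r

    c = np.zeros(nv)
    c[off_yp: off_x + l] = -1.0  # maximize sum of indicators
    if has_forced_either:
        c[d_idx] = 0.0

    res = milp(
        c=c,
        constraints=[LinearConstraint(A.tocsr(), cl, cu)] if rows else [],
        bounds=Bounds(lo, hi),
        integrality=integrality,
        options={"mip_rel_gap": 0.0, "presolve": True},
    )
    if res.status != 0 or res.x is None:
        return ImatSolution(status="infeasible", objective=-np.inf)

    xvec = res.x
    ind = np.rint(xvec[n: n + 2 * h + l]).astype(int)
    y_plus = {problem.reaction_ids[i]: int(ind[k])
              for k, i in enumerate(problem.rh)}
    y_minus = {problem.reaction_ids[i]: int(ind[h + k])
               for k, i in enumerate(problem.rh)}
    xind = {problem.reaction_ids[i]: int(ind[2 * h + k])
            for k, i in enumerate(problem.rl)}
    objective = float(sum(y_plus.values()) + sum(y_minus.values())
                      + sum(xind.values()))
    fluxes = pd.Series(xvec[:n], index=list(problem.reaction_ids))
    return ImatSolution(
        status="optimal",
        objective=objective,
        fluxes=fluxes,
        y_plus=y_plus,
        y_minus=y_minus,
        x=xind,
    )


@dataclass
class ActivityCallSet:
    """Per-reaction activity calls from sensitivity analysis.

    ``forced_objectives`` maps reaction id -> (forced-active objective,
    forced-inactive objective); infeasible forced problems carry -inf.
    ``provenance`` holds per-threshold-pair calls for consensus sets.
    """

    calls: Dict[str, str]  # reaction id -> active | inactive | undetermined
    threshold_pair: str = ""
    base_objective: float = np.nan
    forced_objectives: Dict[str, Tuple[float, float]] = field(
        default_factory=dict
    )
    provenance: Dict[str, Dict[str, str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"call": pd.Series(self.calls)}
        ).rename_axis("reaction_id")


def _classify(opt: float, fa: float, fi: float, tol: float) -> str:
    active_attains = fa >= opt - tol
    inactive_attains = fi >= opt - tol
    if active_attains and not inactive_attains:
        return "active"
    if inactive_attains and not active_attains:
        return "inactive"
    return "undetermined"


def sensitivity_calls(
    model: cobra.Model,
    state: ReactionExpressionState,
    epsilon: float = DEFAULT_EPSILON,
    reactions: Optional[Iterable[str]] = None,
    tol: float = OBJ_TOL,
    seed: int = 0,
) -> ActivityCallSet:
    """Call every reaction active / inactive / undetermined.

    For each reaction two MILPs are solved: one forcing |v_i| >= eps
    (direction-agnostic, via one auxiliary binary) and one forcing v_i = 0.
    A reaction is active when only the forced-active problem attains the
    unconstrained optimum, inactive when only the forced-inactive one does,
    undetermined otherwise.
    """
    problem = build_imat(model, state, epsilon=epsilon)
    base = solve_imat(problem, seed=seed)
    if not base.optimal:
        raise RuntimeError("unconstrained iMAT problem is infeasible")
    opt = base.objective
    rids = list(reactions) if reactions is not None else [
        r.id for r in model.reactions
    ]
    calls: Dict[str, str] = {}
    objectives: Dict[str, Tuple[float, float]] = {}
    for rid in rids:
        fa = solve_imat(problem.with_forced(rid, "active-either"), seed=seed)
        fi = solve_imat(problem.with_forced(rid, "inactive"), seed=seed)
        if fa.objective > opt + tol or fi.objective > opt + tol:
            raise AssertionError(
                f"forced objective exceeds unconstrained optimum for {rid}"
            )
        objectives[rid] = (fa.objective, fi.objective)
        calls[rid] = _classify(opt, fa.objective, fi.objective, tol)
    return ActivityCallSet(
        calls=calls,
        threshold_pair=state.threshold_pair,
        base_objective=opt,
        forced_objectives=objectives,
    )


def robustness_consensus(call_sets: Sequence[ActivityCallSet]) -> ActivityCallSet:
    """Unanimity consensus across threshold pairs.

    A reaction keeps its call only when every pair gives the same determined
    call; any conflict or any undetermined vote yields undetermined.
    """
    if len(call_sets) < 2:
        raise ValueError("consensus needs at least two call sets")
    keys = set(call_sets[0].calls)
    for cs in call_sets[1:]:
        if set(cs.calls) != keys:
            raise ValueError("call sets cover different reaction sets")
    calls: Dict[str, str] = {}
    provenance: Dict[str, Dict[str, str]] = {}
    for rid in keys:
        votes = {cs.threshold_pair or str(i): cs.calls[rid]
                 for i, cs in enumerate(call_sets)}
        provenance[rid] = votes
        vals = set(votes.values())
        if len(vals) == 1 and vals != {"undetermined"}:
            calls[rid] = vals.pop()
        else:
            calls[rid] = "undetermined"
    return ActivityCallSet(
        calls=calls, threshold_pair="consensus", provenance=provenance
    )
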