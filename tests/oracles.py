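"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's MILP path: iMAT objectives and
sensitivity calls are recomputed by exhaustive enumeration of indicator
assignments, each checked by plain LP feasibility (scipy.optimize.linprog),
and Fisher p-values by direct hypergeometric summation with exact integer
binomials.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

NEG_INF = float("-inf")


def lp_feasible(S, lb, ub) -> bool:
    res = linprog(
        c=np.zeros(S.shape[1]),
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.status == 0


def lp_range(S, lb, ub, j) -> Optional[Tuple[float, float]]:
    """[min, max] of v_j over {S v = 0, lb <= v <= ub}; None if infeasible."""
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(S.shape[1])
        c[j] = sign
        res = linprog(c=c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        if res.status != 0:
            return None
        out.append(sign * res.fun)
    return out[0], out[1]  # (min, max)


class ImatEnumerationOracle:
    """Exhaustive enumeration over iMAT indicator assignments.

    Every R_H reaction takes one of {forward-active, reverse-active,
    unsatisfied} and every R_L reaction one of {inactive, unsatisfied};
    an assignment's score is the number of satisfied reactions and its
    feasibility is one LP.  The optimum, the forced-active and the
    forced-inactive objectives are maxima over feasible assignments
    (with the per-reaction side condition checked on the assignment's
    flux polytope).
    """

    def __init__(self, S, lb, ub, rh, rl, epsilon):
        self.S = np.asarray(S, dtype=float)
        self.lb = np.asarray(lb, dtype=float)
        self.ub = np.asarray(ub, dtype=float)
        self.rh = list(rh)
        self.rl = list(rl)
        self.eps = float(epsilon)
        combos = []
        for rh_assign in itertools.product((0, 1, 2), repeat=len(self.rh)):
            for rl_assign in itertools.product((0, 1), repeat=len(self.rl)):
                count = sum(1 for a in rh_assign if a != 0) + sum(rl_assign)
                combos.append((count, rh_assign, rl_assign))
        combos.sort(key=lambda t: -t[0])
        self.combos = combos
        self._feas: Dict[int, bool] = {}
        self._ranges: Dict[Tuple[int, int], Optional[Tuple[float, float]]] = {}

    def _bounds_for(self, ci):
        _, rh_assign, rl_assign = self.combos[ci]
        lb, ub = self.lb.copy(), self.ub.copy()
        for a, j in zip(rh_assign, self.rh):
            if a == 1:  # forward active
                lb[j] = max(lb[j], self.eps)
            elif a == 2:  # reverse active
                ub[j] = min(ub[j], -self.eps)
        for a, j in zip(rl_assign, self.rl):
            if a:
                lb[j], ub[j] = 0.0, 0.0
        return lb, ub

    def feasible(self, ci) -> bool:
        if ci not in self._feas:
            lb, ub = self._bounds_for(ci)
            self._feas[ci] = bool(np.all(lb <= ub)) and lp_feasible(
                self.S, lb, ub)
        return self._feas[ci]

    def vrange(self, ci, j):
        key = (ci, j)
        if key not in self._ranges:
            lb, ub = self._bounds_for(ci)
            self._ranges[key] = lp_range(self.S, lb, ub, j)
        return self._ranges[key]

    def objective(self) -> float:
        for ci, (count, _, _) in enumerate(self.combos):
            if self.feasible(ci):
                return float(count)
        return NEG_INF

    def _base_range(self, j):
        return lp_range(self.S, self.lb, self.ub, j)

    def forced_active_objective(self, j) -> float:
        base = self._base_range(j)
        if base is None or (base[1] < self.eps and base[0] > -self.eps):
            return NEG_INF
        for ci, (count, _, _) in enumerate(self.combos):
            if not self.feasible(ci):
                continue
            rng = self.vrange(ci, j)
            if rng and (rng[1] >= self.eps - 1e-9 or rng[0] <= -self.eps + 1e-9):
                return float(count)
        return NEG_INF

    def forced_inactive_objective(self, j) -> float:
        base = self._base_range(j)
        if base is None or base[0] > 1e-9 or base[1] < -1e-9:
            return NEG_INF
        for ci, (count, _, _) in enumerate(self.combos):
            if not self.feasible(ci):
                continue
            rng = self.vrange(ci, j)
            if rng and rng[0] <= 1e-9 and rng[1] >= -1e-9:
                return float(count)
        return NEG_INF

    def call(self, j, tol=1e-6) -> str:
        opt = self.objective()
        fa = self.forced_active_objective(j)
        fi = self.forced_inactive_objective(j)
        active_attains = fa >= opt - tol
        inactive_attains = fi >= opt - tol
        if active_attains and not inactive_attains:
            return "active"
        if inactive_attains and not active_attains:
            return "inactive"
        return "undetermined"


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by direct hypergeometric summation."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c

    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    p_obs = prob(a)
    return float(sum(p for x in range(lo, hi + 1)
                     if (p := prob(x)) <= p_obs * (1 + 1e-9)))


def gpr_eval_recursive(tree, gene_values):
    """Recursive trinary GPR oracle over a nested tuple tree.

    Trees are ("and", children...) / ("or", children...) / gene id strings.
    """
    if isinstance(tree, str):
        return gene_values[tree]
    op, *children = tree
    vals = [gpr_eval_recursive(c, gene_values) for c in children]
    return min(vals) if op == "and" else max(vals)
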