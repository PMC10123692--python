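"""Omics integration: expression -> reaction states, metabolomics -> flux bounds.

Two data streams constrain the network.  Transcriptomics: per-gene replicate
means are classified into lowly (-1) / moderately (0) / highly (+1) expressed
by percentile thresholds of the metabolic-gene distribution, propagated
through GPRs (AND = min, OR = max) to give each reaction an expression state;
the highly and lowly expressed reaction sets R_H and R_L feed the iMAT MILP.

Metabolomics/lipidomics: triplicate concentration measurements at 0 h and
5 h give an uncertainty-widened net-change window per species,

    ub = (c5 + Sd5) - (c0 - Sd0)
    lb = (c5 - Sd5) - (c0 + Sd0)

imposed on the matching exchange (medium measurements) or sink (whole-cell
measurements) reaction.  By default the window is divided by the sampling
interval so that bounds are rates, matching exchange-flux units; set
``as_rate=False`` for the raw concentration differences.  The sign convention
is positive = secretion/accumulation, negative = uptake/consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import cobra
import numpy as np
import pandas as pd

from .gem_core import evaluate_gpr, is_boundary

__all__ = [
    "ExpressionProfile",
    "GeneClassMap",
    "ReactionExpressionState",
    "MetaboliteTimeSeries",
    "ExchangeBounds",
    "classify_genes",
    "reaction_states",
    "metabolite_bounds",
    "apply_exchange_bounds",
    "read_expression_tsv",
    "read_metabolomics_tsv",
    "InfeasibleBoundsError",
]


@dataclass
class ExpressionProfile:
    """Normalized expression values, genes x replicates, for one condition."""

    condition: str
    data: pd.DataFrame  # index: gene ids; columns: replicates

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression profile")
        if self.data.shape[1] < 1:
            raise ValueError("expression profile needs at least one replicate")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def gene_means(self) -> pd.Series:
        """Arithmetic mean over replicates, the per-gene summary statistic."""
        return self.data.mean(axis=1)

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str, condition: str) -> ExpressionProfile:
    data = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionProfile(condition=condition, data=data)


@dataclass
class GeneClassMap:
    classes: pd.Series  # gene id -> {-1, 0, +1}
    lower_pct: float
    upper_pct: float
    lower_value: float
    upper_value: float

    @property
    def threshold_pair(self) -> str:
        return f"{self.lower_pct:g}_{self.upper_pct:g}"


def classify_genes(
    profile: ExpressionProfile,
    lower_pct: float = 33.0,
    upper_pct: float = 66.0,
    restrict_to: Optional[Iterable[str]] = None,
) -> GeneClassMap:
    """Trinary gene classification by percentile thresholds of replicate means.

    Thresholds are the ``lower_pct`` and ``upper_pct`` percentiles (linear
    interpolation between order statistics) of the per-gene replicate means.
    Classes use strict comparison, so a gene exactly at a threshold is
    moderate.  When ``restrict_to`` is given (typically the model's metabolic
    genes) the threshold distribution uses only those genes, but every gene
    in the profile is classified.
    """
    if not (0 < lower_pct < upper_pct < 100):
        raise ValueError("need 0 < lower_pct < upper_pct < 100")
    means = profile.gene_means()
    if means.empty:
        raise ValueError("empty expression profile")
    ref = means
    if restrict_to is not None:
        keep = means.index.intersection(pd.Index(list(restrict_to)))
        if len(keep) > 0:
            ref = means.loc[keep]
    lo = float(np.percentile(ref.to_numpy(), lower_pct))
    hi = float(np.percentile(ref.to_numpy(), upper_pct))
    classes = pd.Series(0, index=means.index, dtype=int)
    classes[means > hi] = 1
    classes[means < lo] = -1
    return GeneClassMap(
        classes=classes,
        lower_pct=lower_pct,
        upper_pct=upper_pct,
        lower_value=lo,
        upper_value=hi,
    )


@dataclass
class ReactionExpressionState:
    values: dict  # reaction id -> {-1, 0, +1}
    r_high: set = field(default_factory=set)
    r_low: set = field(default_factory=set)
    threshold_pair: str = ""

    def __post_init__(self) -> None:
        assert not (self.r_high & self.r_low)


def reaction_states(
    model: cobra.Model, classes: GeneClassMap
) -> ReactionExpressionState:
    """Propagate gene classes through GPRs to per-reaction expression states.

    Reactions with an empty GPR get value 0 and never enter R_H or R_L;
    genes absent from the classification are treated as moderate.
    """
    gene_values = classes.classes.to_dict()
    values: dict = {}
    r_high, r_low = set(), set()
    for rxn in model.reactions:
        if not rxn.gene_reaction_rule.strip():
            values[rxn.id] = 0
            continue
        val = evaluate_gpr(rxn.gpr, gene_values, missing=0)
        values[rxn.id] = val
        if val == 1:
            r_high.add(rxn.id)
        elif val == -1:
            r_low.add(rxn.id)
    return ReactionExpressionState(
        values=values,
        r_high=r_high,
        r_low=r_low,
        threshold_pair=classes.threshold_pair,
    )


@dataclass
class MetaboliteTimeSeries:
    """Mean +/- SD concentrations of one species at 0 h and 5 h."""

    metabolite_id: str
    c0: float
    sd0: float
    c5: float
    sd5: float
    compartment: str = "medium"  # "medium" -> exchange, "cell" -> sink

    def __post_init__(self) -> None:
        if self.sd0 < 0 or self.sd5 < 0:
            raise ValueError(
                f"negative standard deviation for {self.metabolite_id}"
            )


@dataclass
class ExchangeBounds:
    reaction_id: str
    lb: float
    ub: float

    def __post_init__(self) -> None:
        assert self.lb <= self.ub + 1e-12


def metabolite_bounds(
    ts: MetaboliteTimeSeries,
    reaction_id: Optional[str] = None,
    duration: float = 5.0,
    as_rate: bool = True,
) -> ExchangeBounds:
    """Uncertainty-widened net-change bounds for one measured species.

    ub = (c5 + Sd5) - (c0 - Sd0); lb = (c5 - Sd5) - (c0 + Sd0); divided by
    ``duration`` when ``as_rate`` (the default) so bounds are fluxes.  The
    width is always 2 (Sd0 + Sd5) (/ duration), hence lb <= ub.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    ub = (ts.c5 + ts.sd5) - (ts.c0 - ts.sd0)
    lb = (ts.c5 - ts.sd5) - (ts.c0 + ts.sd0)
    if as_rate:
        ub /= duration
        lb /= duration
    return ExchangeBounds(
        reaction_id=reaction_id or ts.metabolite_id, lb=lb, ub=ub
    )


def read_metabolomics_tsv(path: str) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        MetaboliteTimeSeries(
            metabolite_id=row["metabolite_id"],
            compartment=row.get("compartment", "medium"),
            c0=row["c0"],
            sd0=row["Sd0"],
            c5=row["c5"],
            sd5=row["Sd5"],
        )
        for _, row in df.iterrows()
    ]


class InfeasibleBoundsError(RuntimeError):
    """Measured bounds made the model infeasible; carries the applied bounds."""

    def __init__(self, bounds: Sequence[ExchangeBounds]):
        self.bounds = list(bounds)
        lines = ", ".join(f"{b.reaction_id}[{b.lb:g},{b.ub:g}]" for b in bounds)
        super().__init__(
            f"model infeasible after applying measured bounds: {lines}"
        )


def apply_exchange_bounds(
    model: cobra.Model,
    bounds: Sequence[ExchangeBounds],
    check_feasible: bool = True,
) -> cobra.Model:
    """Return a copy of the model with measured bounds on exchange/sink reactions.

    Every targeted reaction must exist and be a boundary pseudo-reaction.  A
    follow-up feasibility LP detects conflicting constraints and raises
    :class:`InfeasibleBoundsError` listing the applied bounds.
    """
    out = model.copy()
    for b in bounds:
        if b.reaction_id not in out.reactions:
            raise KeyError(f"unknown exchange reaction {b.reaction_id!r}")
        rxn = out.reactions.get_by_id(b.reaction_id)
        if not is_boundary(rxn):
            raise ValueError(
                f"reaction {b.reaction_id!r} is not an exchange or sink"
            )
        rxn.bounds = (b.lb, b.ub)
    if check_feasible and bounds:
        with out as m:
            m.objective = m.problem.Objective(0)
            m.slim_optimize()
            if m.solver.status != "optimal":
                raise InfeasibleBoundsError(bounds)
    return out


def relax_infeasible_bounds(
    model: cobra.Model, bounds: Sequence[ExchangeBounds]
) -> tuple:
    """Widen sign-forcing measured intervals to include zero until feasible.

    Measurement noise can produce an interval that forces net production or
    consumption of a species the network cannot balance; such a constraint
    is physically impossible and is relaxed rather than fatal.  Intervals
    whose nearest endpoint to zero is smallest are widened first (least
    information lost).  Returns (bounded model, effective bounds, relaxed
    reaction ids); re-raises :class:`InfeasibleBoundsError` when no
    sign-forcing interval is left to relax.
    """
    current = list(bounds)
    relaxed: list = []
    while True:
        try:
            return apply_exchange_bounds(model, current), current, relaxed
        except InfeasibleBoundsError:
            candidates = [
                b for b in current
                if (b.lb > 0 or b.ub < 0) and b.reaction_id not in relaxed
            ]
            if not candidates:
                raise
            pick = min(candidates,
                       key=lambda b: (min(abs(b.lb), abs(b.ub)), b.reaction_id))
            idx = current.index(pick)
            current[idx] = ExchangeBounds(
                pick.reaction_id, min(pick.lb, 0.0), max(pick.ub, 0.0)
            )
            relaxed.append(pick.reaction_id)
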