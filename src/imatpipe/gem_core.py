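"""Genome-scale metabolic model container, SBML/JSON ingestion and GPR evaluation.

The in-memory model is a :class:`cobra.Model`; this module adds the pieces the
activity-inference pipeline needs on top of cobrapy: strict ingestion with
invariant checks, subsystem-preserving SBML output (via the SBML groups
package), and trinary gene-protein-reaction (GPR) rule evaluation.

GPR rules are Boolean expressions over gene identifiers.  For transcriptome
integration each gene carries a class in {-1, 0, +1} (lowly / moderately /
highly expressed) and the rule is folded with AND = min and OR = max, the
convention of the original iMAT formulation: an enzyme complex (AND) is only
as available as its scarcest subunit, while isozymes (OR) are as available as
the most abundant one.
"""

from __future__ import annotations

import ast
import contextlib
import logging
from typing import Mapping, Union

import cobra
import numpy as np
from cobra.core import Group
from cobra.core.gene import GPR
from cobra.util.array import create_stoichiometric_matrix

__all__ = [
    "ModelFormatError",
    "read_sbml",
    "write_sbml",
    "read_json",
    "write_json",
    "validate_model",
    "stoichiometric_matrix",
    "parse_gpr",
    "evaluate_gpr",
    "reaction_kind",
    "PROVENANCE_KEY",
]

#: annotation key used to tag reactions added by this pipeline (provenance)
PROVENANCE_KEY = "imatpipe_provenance"


class ModelFormatError(ValueError):
    """Raised when an SBML/JSON document violates model invariants."""


@contextlib.contextmanager
def _quiet_sbml_log():
    # cobra logs an error for models without an objective; toy fixtures and
    # feasibility-only models legitimately have none
    logger = logging.getLogger("cobra.io.sbml")
    level = logger.level
    logger.setLevel(logging.CRITICAL)
    try:
        yield
    finally:
        logger.setLevel(level)


def validate_model(model: cobra.Model) -> None:
    """Check structural invariants; raise :class:`ModelFormatError` on failure.

    Checks: unique reaction and metabolite identifiers, every metabolite
    referenced by a reaction present in the model, every GPR gene present in
    the gene list, metabolite compartments registered, and lb <= ub.
    """
    rids = [r.id for r in model.reactions]
    if len(rids) != len(set(rids)):
        raise ModelFormatError("duplicate reaction identifiers")
    mids = [m.id for m in model.metabolites]
    if len(mids) != len(set(mids)):
        raise ModelFormatError("duplicate metabolite identifiers")
    met_set = set(mids)
    gene_set = {g.id for g in model.genes}
    compartments = set(model.compartments)
    for rxn in model.reactions:
        for met in rxn.metabolites:
            if met.id not in met_set:
                raise ModelFormatError(
                    f"reaction {rxn.id} references unknown metabolite {met.id}"
                )
        for gene in rxn.genes:
            if gene.id not in gene_set:
                raise ModelFormatError(
                    f"reaction {rxn.id} references unknown gene {gene.id}"
                )
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelFormatError(
                f"reaction {rxn.id} has lower_bound > upper_bound"
            )
    for met in model.metabolites:
        if met.compartment and met.compartment not in compartments:
            raise ModelFormatError(
                f"metabolite {met.id} in unregistered compartment {met.compartment}"
            )


def read_sbml(path: str) -> cobra.Model:
    """Read an SBML file (L2 or L3, FBC bounds when present) into a model.

    FBC flux bounds win over kinetic-law fallbacks (cobrapy semantics).
    Subsystem labels are restored from SBML groups.  Raises
    :class:`ModelFormatError` on unparseable files or invalid GPR strings,
    naming the offending element.
    """
    try:
        with _quiet_sbml_log():
            model = cobra.io.read_sbml_model(path)
    except Exception as exc:  # libsbml raises a zoo of exception types
        raise ModelFormatError(f"cannot parse SBML file {path!r}: {exc}") from exc
    # force GPR parse so a malformed rule fails here, naming the reaction
    for rxn in model.reactions:
        try:
            _ = rxn.gpr
        except Exception as exc:
            raise ModelFormatError(
                f"invalid GPR on reaction {rxn.id}: {exc}"
            ) from exc
    validate_model(model)
    return model


def _sync_subsystem_groups(model: cobra.Model) -> None:
    """Mirror per-reaction ``subsystem`` labels into SBML groups before writing."""
    existing = {g.id for g in model.groups}
    by_subsystem: dict[str, list] = {}
    for rxn in model.reactions:
        if rxn.subsystem:
            by_subsystem.setdefault(rxn.subsystem, []).append(rxn)
    for name, members in by_subsystem.items():
        gid = name.replace(" ", "_")
        if gid in existing:
            continue
        grp = Group(gid, name=name)
        grp.kind = "partonomy"
        grp.add_members(list(members))
        model.add_groups([grp])


def write_sbml(model: cobra.Model, path: str) -> None:
    """Write the model as SBML L3 + FBC, preserving subsystems via groups."""
    _sync_subsystem_groups(model)
    with _quiet_sbml_log():
        cobra.io.write_sbml_model(model, path)


def read_json(path: str) -> cobra.Model:
    """Read a model from cobrapy's JSON schema (used for text fixtures)."""
    model = cobra.io.load_json_model(path)
    validate_model(model)
    return model


def write_json(model: cobra.Model, path: str) -> None:
    cobra.io.save_json_model(model, path)


def stoichiometric_matrix(model: cobra.Model) -> np.ndarray:
    """Dense S matrix: metabolites in rows, reactions in columns.

    Entry (i, j) is the stoichiometric coefficient of metabolite i in
    reaction j (negative for substrates, positive for products).
    """
    if len(model.reactions) == 0 or len(model.metabolites) == 0:
        return np.zeros((len(model.metabolites), len(model.reactions)))
    return create_stoichiometric_matrix(model, array_type="dense")


def parse_gpr(rule: str) -> GPR:
    """Parse a GPR string such as ``"(g1 and g2) or g3"`` into an expression tree."""
    return GPR.from_string(rule)


def _eval_node(node: ast.AST, gene_values: Mapping[str, int], missing: int) -> int:
    if isinstance(node, ast.Name):
        return int(gene_values.get(node.id, missing))
    if isinstance(node, ast.BoolOp):
        children = [_eval_node(v, gene_values, missing) for v in node.values]
        if isinstance(node.op, ast.And):
            return min(children)
        if isinstance(node.op, ast.Or):
            return max(children)
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, gene_values, missing)
    raise ValueError(f"unsupported GPR node: {ast.dump(node)}")


def evaluate_gpr(
    gpr: Union[GPR, str, None],
    gene_values: Mapping[str, int],
    missing: int = 0,
) -> int:
    """Fold a GPR over trinary gene classes with AND = min, OR = max.

    Parameters
    ----------
    gpr
        Parsed GPR tree, a rule string, or None/empty (returns 0).
    gene_values
        Gene id -> class in {-1, 0, +1}.
    missing
        Class assumed for genes absent from ``gene_values`` (default 0,
        i.e. moderately expressed — keeps the reaction out of both the
        highly- and lowly-expressed sets unless other genes decide it).
    """
    if gpr is None:
        return 0
    if isinstance(gpr, str):
        if not gpr.strip():
            return 0
        gpr = parse_gpr(gpr)
    if gpr.body is None:
        return 0
    return _eval_node(gpr.body, gene_values, missing)


def reaction_kind(rxn: cobra.Reaction) -> str:
    """Classify a reaction: internal, exchange, sink or transport-to-boundary.

    Boundary pseudo-reactions touch exactly one metabolite; exchanges carry
    the conventional ``EX_`` prefix (or an extracellular metabolite), sinks
    the ``SK_``/``sink_`` prefix.  Reactions added by the lipid-boundary
    expansion carry an explicit provenance annotation that wins.
    """
    tagged = rxn.annotation.get(PROVENANCE_KEY) if rxn.annotation else None
    if tagged in {"sink", "transport-to-boundary"}:
        return tagged
    if len(rxn.metabolites) == 1:
        if rxn.id.startswith("EX_"):
            return "exchange"
        if rxn.id.startswith(("SK_", "sink_", "DM_")):
            return "sink"
        met = next(iter(rxn.metabolites))
        if met.compartment in {"e", "e0", "extracellular"}:
            return "exchange"
        return "sink"
    return "internal"


def is_boundary(rxn: cobra.Reaction) -> bool:
    return reaction_kind(rxn) in {"exchange", "sink"}
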