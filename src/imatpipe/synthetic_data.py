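"""Synthetic toy models and omics data with known ground truth.

Every pipeline stage is exercisable offline on small generated inputs: a toy
genome-scale model with subsystem labels and GPRs, two-condition expression
replicates whose percentile classes are consistent with planted reaction
activity, triplicate concentration time courses generated from planted
exchange fluxes, and gene-set collections with a planted enrichment.

Toy network topology: a common uptake hub feeds one linear chain per
pathway, each chain ending in its own secretion exchange.  Pathway roles
define the two study conditions ("exposed" vs "control"):

* one *differential* pathway carries flux only in the exposed condition and
  its genes are highly expressed there and lowly expressed in the control;
* *inactive* pathways carry no flux in either condition (lowly expressed);
* *active* pathways carry flux in both (highly expressed);
* *moderate* pathways carry flux in both but their genes sit in the middle
  of the expression distribution, keeping the three percentile strata
  populated so that strict percentile classification recovers the planted
  high/low classes.

Expression strata are well separated (means 4 / 8 / 12, within-stratum SD
0.3) with multiplicative replicate noise at 5% CV; a configurable fraction
of genes is mislabeled ("flipped") to emulate noise.  Metabolomic
concentrations follow c5 = c0 + rate x duration with multiplicative
log-normal replicate noise.  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import cobra
import numpy as np
import pandas as pd
from cobra import Metabolite, Reaction

from .omics_integration import ExpressionProfile, MetaboliteTimeSeries

__all__ = [
    "CONDITIONS",
    "GroundTruth",
    "generate_toy_gem",
    "generate_expression",
    "generate_metabolomics",
    "generate_gene_sets",
    "generate_expression_panel",
    "generate_panel_gene_sets",
]

CONDITIONS = ("exposed", "control")

#: expression stratum means for low / moderate / high genes
STRATUM_MEANS = {-1: 4.0, 0: 8.0, 1: 12.0}
STRATUM_SD = 0.3

#: planted chain fluxes exceed the default iMAT activity threshold (eps = 1)
FLUX_RANGE = (1.5, 3.0)

#: baseline concentration of measured species; sized so that rate x duration
#: dominates replicate noise (cv x baseline) while a spurious 3-replicate
#: interval around a true-zero rate stays below the activity threshold
BASELINE_CONC = 10.0


@dataclass
class GroundTruth:
    conditions: Tuple[str, str] = CONDITIONS
    #: condition -> reaction id -> carries flux in the planted state
    reaction_activity: Dict[str, Dict[str, bool]] = field(default_factory=dict)
    #: condition -> gene id -> planted expression class {-1, 0, +1}
    expression_class: Dict[str, Dict[str, int]] = field(default_factory=dict)
    #: condition -> exchange reaction id -> planted rate (+ secretion)
    exchange_fluxes: Dict[str, Dict[str, float]] = field(default_factory=dict)
    differential_subsystems: List[str] = field(default_factory=list)
    pathway_roles: Dict[str, str] = field(default_factory=dict)
    blocked_reactions: List[str] = field(default_factory=list)
    enriched_gene_sets: Dict[str, List[str]] = field(default_factory=dict)
    discriminative_genes: List[str] = field(default_factory=list)


def _pathway_roles(n_pathways: int) -> List[str]:
    cycle = ["inactive", "moderate", "moderate", "active"]
    return ["differential"] + [cycle[i % 4] for i in range(n_pathways - 1)]


def _gpr_for(rng: np.random.Generator, decisive: str,
             companions: List[str]) -> str:
    if not companions:
        return decisive
    if len(companions) == 1:
        op = rng.choice(["and", "or"])
        return f"{decisive} {op} {companions[0]}"
    return f"({decisive} and {companions[0]}) or {companions[1]}"


def generate_toy_gem(
    n_pathways: int = 4,
    reactions_per_pathway: int = 6,
    n_blocked: int = 2,
    seed: int = 0,
) -> Tuple[cobra.Model, GroundTruth]:
    """Toy stoichiometric network with planted activity states.

    Returns a feasibility-verified cobra model plus the ground truth.  Each
    pathway is a linear chain off a shared uptake hub with its own secretion
    exchange; ``n_blocked`` dangling reactions (product without any
    consumer or exchange) are planted.  GPRs mix 1-3 genes with AND/OR.
    """
    if n_pathways < 2 or reactions_per_pathway < 3:
        raise ValueError("need n_pathways >= 2 and reactions_per_pathway >= 3")
    last_err: Optional[Exception] = None
    for attempt in range(10):
        rng = np.random.default_rng(seed + 1_000_003 * attempt)
        try:
            return _build_toy_gem(rng, n_pathways, reactions_per_pathway,
                                  n_blocked)
        except RuntimeError as err:  # infeasible construction; retry
            last_err = err
    raise RuntimeError(f"could not build a feasible toy model: {last_err}")


def _build_toy_gem(
    rng: np.random.Generator,
    n_pathways: int,
    reactions_per_pathway: int,
    n_blocked: int,
) -> Tuple[cobra.Model, GroundTruth]:
    model = cobra.Model("toy_gem")
    hub = Metabolite("hub_c", name="uptake hub", compartment="c")
    model.add_metabolites([hub])
    ex_hub = Reaction("EX_hub", lower_bound=-1000.0, upper_bound=0.0)
    ex_hub.add_metabolites({hub: -1.0})
    model.add_reactions([ex_hub])

    truth = GroundTruth()
    roles = _pathway_roles(n_pathways)
    fluxes = rng.uniform(*FLUX_RANGE, size=n_pathways)
    for cond in CONDITIONS:
        truth.reaction_activity[cond] = {}
        truth.expression_class[cond] = {}
        truth.exchange_fluxes[cond] = {}

    chain_rids: List[List[str]] = []
    for p in range(n_pathways):
        sub = f"pathway_{p + 1}"
        role = roles[p]
        truth.pathway_roles[sub] = role
        prev = hub
        rids = []
        new_rxns = []
        for j in range(reactions_per_pathway):
            met = Metabolite(f"m_{p + 1}_{j + 1}_c", compartment="c")
            model.add_metabolites([met])
            rid = f"R_{p + 1}_{j + 1}"
            rxn = Reaction(rid, lower_bound=0.0, upper_bound=1000.0)
            rxn.add_metabolites({prev: -1.0, met: 1.0})
            rxn.subsystem = sub
            n_comp = int(rng.integers(0, 3))
            decisive = f"g_{rid}"
            companions = [f"g_{rid}_c{t + 1}" for t in range(n_comp)]
            rxn.gene_reaction_rule = _gpr_for(rng, decisive, companions)
            new_rxns.append(rxn)
            rids.append(rid)
            prev = met
            # planted classes: all genes of a reaction share its stratum
            for cond in CONDITIONS:
                cls = _planted_class(role, cond)
                for g in [decisive, *companions]:
                    truth.expression_class[cond][g] = cls
        ex = Reaction(f"EX_p{p + 1}", lower_bound=0.0, upper_bound=1000.0)
        ex.add_metabolites({prev: -1.0})
        ex.subsystem = sub
        new_rxns.append(ex)
        model.add_reactions(new_rxns)
        chain_rids.append(rids)

        for cond in CONDITIONS:
            active = _planted_active(role, cond)
            rate = float(fluxes[p]) if active else 0.0
            truth.exchange_fluxes[cond][ex.id] = rate
            for rid in rids:
                truth.reaction_activity[cond][rid] = active
            truth.reaction_activity[cond][ex.id] = active

        if role == "differential":
            truth.differential_subsystems.append(sub)
            genes = sorted(
                g for g in truth.expression_class["exposed"]
                if g.startswith(f"g_R_{p + 1}_")
            )
            truth.discriminative_genes = genes
            truth.enriched_gene_sets = {"PLANTED_UP_EXPOSED": genes}

    # planted blocked reactions: dangling products with no consumer
    blocked_rxns = []
    for b in range(n_blocked):
        p = int(rng.integers(0, n_pathways))
        j = int(rng.integers(0, reactions_per_pathway - 1))
        dead = Metabolite(f"dead_{b + 1}_c", compartment="c")
        model.add_metabolites([dead])
        src = model.metabolites.get_by_id(f"m_{p + 1}_{j + 1}_c")
        rid = f"R_blocked_{b + 1}"
        rxn = Reaction(rid, lower_bound=0.0, upper_bound=1000.0)
        rxn.add_metabolites({src: -1.0, dead: 1.0})
        rxn.subsystem = f"pathway_{p + 1}"
        rxn.gene_reaction_rule = f"g_{rid}"
        blocked_rxns.append(rxn)
        truth.blocked_reactions.append(rid)
        for cond in CONDITIONS:
            truth.reaction_activity[cond][rid] = False
            truth.expression_class[cond][f"g_{rid}"] = -1
    model.add_reactions(blocked_rxns)

    for cond in CONDITIONS:
        truth.exchange_fluxes[cond]["EX_hub"] = -float(
            sum(truth.exchange_fluxes[cond][f"EX_p{p + 1}"]
                for p in range(n_pathways))
        )
        truth.reaction_activity[cond]["EX_hub"] = any(
            truth.reaction_activity[cond][r]
            for rids in chain_rids for r in rids
        )
        _verify_steady_state(model, truth, cond)
    return model, truth


def _planted_active(role: str, condition: str) -> bool:
    if role == "differential":
        return condition == "exposed"
    return role in {"active", "moderate"}


def _planted_class(role: str, condition: str) -> int:
    if role == "differential":
        return 1 if condition == "exposed" else -1
    return {"active": 1, "inactive": -1, "moderate": 0}[role]


def _verify_steady_state(model: cobra.Model, truth: GroundTruth,
                         condition: str) -> None:
    """Check the planted state admits a feasible steady-state flux vector."""
    v = {}
    for rxn in model.reactions:
        if rxn.id.startswith("EX_"):
            v[rxn.id] = truth.exchange_fluxes[condition].get(rxn.id, 0.0)
        elif truth.reaction_activity[condition].get(rxn.id, False):
            p = int(rxn.id.split("_")[1])
            v[rxn.id] = truth.exchange_fluxes[condition][f"EX_p{p}"]
        else:
            v[rxn.id] = 0.0
    for met in model.metabolites:
        net = sum(rxn.metabolites[met] * v[rxn.id] for rxn in met.reactions)
        if abs(net) > 1e-9:
            raise RuntimeError(
                f"planted state violates mass balance at {met.id} ({condition})"
            )
    for rxn in model.reactions:
        if not (rxn.lower_bound - 1e-9 <= v[rxn.id] <= rxn.upper_bound + 1e-9):
            raise RuntimeError(
                f"planted flux of {rxn.id} outside bounds ({condition})"
            )


def generate_expression(
    model: cobra.Model,
    truth: GroundTruth,
    flip_fraction: float = 0.1,
    n_replicates: int = 4,
    cv: float = 0.05,
    seed: int = 0,
) -> Dict[str, ExpressionProfile]:
    """Two-condition expression replicates consistent with the planted classes.

    Genes of planted-high reactions draw from the high stratum, planted-low
    from the low stratum, moderate in between; a ``flip_fraction`` of genes
    is reassigned to a wrong stratum (independently per condition) and
    replicates carry multiplicative Gaussian noise at ``cv``.
    """
    if not (0 <= flip_fraction < 0.5):
        raise ValueError("flip_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.expression_class[CONDITIONS[0]])
    profiles = {}
    for cond in CONDITIONS:
        classes = dict(truth.expression_class[cond])
        n_flip = int(round(flip_fraction * len(genes)))
        for g in rng.choice(genes, size=n_flip, replace=False):
            wrong = [s for s in (-1, 0, 1) if s != classes[g]]
            classes[g] = int(rng.choice(wrong))
        base = np.array([
            rng.normal(STRATUM_MEANS[classes[g]], STRATUM_SD) for g in genes
        ])
        reps = base[:, None] * (
            1.0 + rng.normal(0.0, cv, size=(len(genes), n_replicates))
        )


        data = pd.DataFrame(
            reps, index=pd.Index(genes, name="gene_id"),
            columns=[f"{cond}_rep{i + 1}" for i in range(n_replicates)],
        )
        profiles[cond] = ExpressionProfile(condition=cond, data=data)
    return profiles


def generate_metabolomics(
    truth: GroundTruth,
    condition: str,
    duration: float = 5.0,
    cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> List[MetaboliteTimeSeries]:
    """Triplicate concentration time courses from planted exchange fluxes.

    c5 = c0 + rate x duration with multiplicative log-normal noise per
    replicate; means and SDs are computed from the replicates, so cv = 0
    inverts exactly to the planted rate.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for rid in sorted(truth.exchange_fluxes[condition]):
        rate = truth.exchange_fluxes[condition][rid]
        c0 = BASELINE_CONC + (abs(rate) * duration if rate < 0 else 0.0)
        c5 = c0 + rate * duration
        reps0 = c0 * np.exp(rng.normal(0.0, cv, size=n_replicates))
        reps5 = c5 * np.exp(rng.normal(0.0, cv, size=n_replicates))
        out.append(
            MetaboliteTimeSeries(
                metabolite_id=rid,
                c0=float(reps0.mean()),
                sd0=float(reps0.std(ddof=1)) if n_replicates > 1 else 0.0,
                c5=float(reps5.mean()),
                sd5=float(reps5.std(ddof=1)) if n_replicates > 1 else 0.0,
                compartment="medium",
            )
        )
    return out


def generate_gene_sets(
    model: cobra.Model,
    truth: GroundTruth,
    n_null_sets: int = 10,
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Planted-enrichment gene set plus size-matched random null sets."""
    rng = np.random.default_rng(seed)
    universe = sorted(g.id for g in model.genes)
    sets = dict(truth.enriched_gene_sets)
    size = max(len(v) for v in sets.values()) if sets else 5
    for i in range(n_null_sets):
        sets[f"NULL_{i + 1}"] = sorted(
            rng.choice(universe, size=min(size, len(universe)),
                       replace=False).tolist()
        )
    return sets


def generate_expression_panel(
    n_genes: int = 200,
    n_signal: int = 20,
    n_samples: int = 4,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> Tuple[ExpressionProfile, ExpressionProfile, List[str]]:
    """Two-condition expression panel with a planted up-shifted gene block.

    Background genes draw iid N(8, 1) per sample; ``n_signal`` genes gain
    ``effect`` in the exposed condition.  Used to exercise GSEA and PLS-DA
    at transcriptome-like scale without a metabolic model.
    """


    rng = np.random.default_rng(seed)
    genes = [f"pg{i + 1:04d}" for i in range(n_genes)]
    signal = sorted(rng.choice(genes, size=n_signal, replace=False).tolist())
    base = rng.normal(8.0, 1.0, size=n_genes)
    profiles = {}
    for cond in CONDITIONS:
        vals = base[:, None] + rng.normal(0.0, noise_sd,
                                          size=(n_genes, n_samples))
        if cond == "exposed":
            vals[np.isin(genes, signal)] += effect
        data = pd.DataFrame(
            vals, index=pd.Index(genes, name="gene_id"),
            columns=[f"{cond}_rep{i + 1}" for i in range(n_samples)],
        )
        profiles[cond] = ExpressionProfile(condition=cond, data=data)
    return profiles["exposed"], profiles["control"], signal


def generate_panel_gene_sets(
    signal_genes: Sequence[str],
    universe: Sequence[str],
    n_null_sets: int = 20,
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Panel gene sets: the planted signal set plus random null sets."""
    rng = np.random.default_rng(seed)
    sets = {"PLANTED_SIGNAL": sorted(signal_genes)}
    size = len(signal_genes)
    for i in range(n_null_sets):
        sets[f"NULL_{i + 1}"] = sorted(
            rng.choice(list(universe), size=size, replace=False).tolist()
        )
    return sets


def materialize_workspace(
    out_dir: str,
    seed: int = 0,
    n_pathways: int = 4,
    reactions_per_pathway: int = 6,
    n_blocked: int = 2,
    flip_fraction: float = 0.1,
    cv: float = 0.1,
    n_perm: int = 200,
) -> str:
    """Write a complete example workspace (SBML, TSVs, GMT, config, truth).

    Returns the path of the generated config file; ``run_pipeline`` on that
    config exercises every stage.  Ground truth is stored alongside as JSON
    for recovery checks.
    """
    import json
    import os

    import yaml

    from .enrichment import write_gmt
    from .gem_core import write_sbml

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    model, truth = generate_toy_gem(
        n_pathways=n_pathways,
        reactions_per_pathway=reactions_per_pathway,
        n_blocked=n_blocked,
        seed=seed,
    )
    write_sbml(model, os.path.join(out_dir, "model.xml"))
    profiles = generate_expression(
        model, truth, flip_fraction=flip_fraction,
        seed=int(rng.integers(2**31)),
    )
    expression_paths = {}
    metabolomics_paths = {}
    for cond in CONDITIONS:
        ep = os.path.join(out_dir, f"expression_{cond}.tsv")
        profiles[cond].to_tsv(ep)
        expression_paths[cond] = ep
        series = generate_metabolomics(
            truth, cond, cv=cv, seed=int(rng.integers(2**31)))
        mp = os.path.join(out_dir, f"metabolomics_{cond}.tsv")
        pd.DataFrame(
            [(ts.metabolite_id, ts.compartment, ts.c0, ts.sd0, ts.c5, ts.sd5)
             for ts in series],
            columns=["metabolite_id", "compartment", "c0", "Sd0", "c5", "Sd5"],
        ).to_csv(mp, sep="\t", index=False)
        metabolomics_paths[cond] = mp
    gene_sets = generate_gene_sets(model, truth,
                                   seed=int(rng.integers(2**31)))
    gmt_path = os.path.join(out_dir, "gene_sets.gmt")
    write_gmt(gene_sets, gmt_path)

    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(
            {
                "reaction_activity": truth.reaction_activity,
                "exchange_fluxes": truth.exchange_fluxes,
                "differential_subsystems": truth.differential_subsystems,
                "pathway_roles": truth.pathway_roles,
                "blocked_reactions": truth.blocked_reactions,
                "discriminative_genes": truth.discriminative_genes,
                "enriched_gene_sets": truth.enriched_gene_sets,
            },
            fh, indent=2,
        )
    config = {
        "model_path": os.path.join(out_dir, "model.xml"),
        "expression_paths": expression_paths,
        "metabolomics_paths": metabolomics_paths,
        "gene_sets_path": gmt_path,
        "output_dir": os.path.join(out_dir, "results"),
        "n_perm": n_perm,
        "seed": seed,
    }
    config_path = os.path.join(out_dir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh)
    return config_path
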