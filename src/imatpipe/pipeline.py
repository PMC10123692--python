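"""End-to-end orchestration of the activity-inference pipeline.

Stages: model preparation (optional lipid-boundary expansion, then reduction)
-> omics integration (percentile gene classes per threshold pair, measured
exchange bounds with a held-out fraction) -> iMAT sensitivity calls per
condition x threshold pair and their robustness consensus -> pathway-level
differential activity -> differential reactions -> GSEA -> PLS-DA/VIP
signature -> hold-out consumption/secretion validation.  ``run_pipeline``
writes every stage output as TSV/JSON plus a manifest with configuration,
package versions, the solver used, and a SHA-256 hash of every input and
output file.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import gsea, plsda_vip, read_gmt, select_signature
from .gem_core import read_json, read_sbml
from .imat import (ActivityCallSet, build_imat, robustness_consensus,
                   sensitivity_calls, solve_imat)
from .model_prep import expand_lipid_boundary, reduce_model
from .omics_integration import (classify_genes, metabolite_bounds,
                                reaction_states, read_expression_tsv,
                                read_metabolomics_tsv,
                                relax_infeasible_bounds)
from .pathways import (activity_long_table, differential_pathways,
                       differential_reactions)
from .validation import predict_exchange_signs, sign_agreement_test

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

DEFAULT_THRESHOLD_PAIRS = ((30.0, 70.0), (33.0, 66.0), (40.0, 60.0))


@dataclass
class RunConfig:
    model_path: str
    expression_paths: Dict[str, str]  # condition -> TSV
    metabolomics_paths: Dict[str, str]  # condition -> TSV
    gene_sets_path: Optional[str] = None
    output_dir: str = "imatpipe_run"
    threshold_pairs: Sequence[Tuple[float, float]] = DEFAULT_THRESHOLD_PAIRS
    epsilon: float = 1.0
    duration: float = 5.0
    rate_bounds: bool = True  # divide concentration windows by duration
    diff_threshold: float = 0.10
    alpha: float = 0.05
    vip_threshold: float = 1.5
    n_perm: int = 1000
    seed: int = 0
    holdout_fraction: float = 0.2
    expand_lipids: Optional[List] = None  # [(base id, [compartments]), ...]
    expand_before_reduce: bool = True
    percentiles_on_model_genes: bool = True
    validation_mode: str = "flux"  # or "fva"

    def __post_init__(self) -> None:
        for lo, hi in self.threshold_pairs:
            if not lo < hi:
                raise ValueError(f"bad threshold pair ({lo}, {hi})")
        if not (0 <= self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["threshold_pairs"] = [list(p) for p in self.threshold_pairs]
        return d


@dataclass
class PipelineResult:
    calls: Dict[str, List[ActivityCallSet]]
    consensus: Dict[str, ActivityCallSet]
    pathway_table: pd.DataFrame
    differential: pd.DataFrame
    differential_rxns: pd.DataFrame
    enrichment: Optional[pd.DataFrame]
    vip: Optional[pd.Series]
    signature: Optional[List[str]]
    validation: Optional[dict]
    manifest: dict


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_model(path: str):
    if path.endswith((".json",)):
        return read_json(path)
    return read_sbml(path)


def _observed_sign(rate: float, floor: float) -> str:
    if rate >= floor:
        return "secreted"
    if rate <= -floor:
        return "consumed"
    return "none"


def run_pipeline(config: RunConfig) -> PipelineResult:
    os.makedirs(config.output_dir, exist_ok=True)
    out = config.output_dir
    conditions = sorted(config.expression_paths)
    if set(conditions) != set(config.metabolomics_paths):
        raise RuntimeError(
            "stage omics_integration: expression and metabolomics conditions differ"
        )

    # ---- model_prep -------------------------------------------------------
    model = _read_model(config.model_path)
    if config.expand_lipids and config.expand_before_reduce:
        model = expand_lipid_boundary(model, config.expand_lipids)
    model, report = reduce_model(model)
    if config.expand_lipids and not config.expand_before_reduce:
        model = expand_lipid_boundary(model, config.expand_lipids)
    report.to_tsv(os.path.join(out, "reduction_report.tsv"))
    model_genes = {g.id for g in model.genes}

    # ---- omics_integration ------------------------------------------------
    expression = {}
    for cond in conditions:
        path = config.expression_paths[cond]
        if not os.path.exists(path):
            raise RuntimeError(
                f"stage omics_integration: missing expression file {path!r}"
            )
        expression[cond] = read_expression_tsv(path, condition=cond)
    metabolomics = {}
    for cond in conditions:
        path = config.metabolomics_paths[cond]
        if not os.path.exists(path):
            raise RuntimeError(
                f"stage omics_integration: missing metabolomics file {path!r}"
            )
        metabolomics[cond] = read_metabolomics_tsv(path)

    # hold out a fraction of measured species for validation (same species in
    # every condition, drawn once from the shared measured panel)
    rng = np.random.default_rng(config.seed)
    measured_ids = sorted({ts.metabolite_id for cond in conditions
                           for ts in metabolomics[cond]})
    n_hold = int(round(config.holdout_fraction * len(measured_ids)))
    holdout = set(rng.choice(measured_ids, size=n_hold, replace=False)) \
        if n_hold else set()

    bounded = {}
    bounds_rows = []
    for cond in conditions:
        bounds = [
            metabolite_bounds(ts, duration=config.duration,
                              as_rate=config.rate_bounds)
            for ts in metabolomics[cond]
            if ts.metabolite_id not in holdout
        ]
        bounds = [b for b in bounds if b.reaction_id in
                  {r.id for r in model.reactions}]
        bounded[cond], effective, relaxed = relax_infeasible_bounds(model,
                                                                    bounds)
        bounds_rows += [
            (cond, b.reaction_id, b.lb, b.ub, b.reaction_id in relaxed)
            for b in effective
        ]
    pd.DataFrame(
        bounds_rows,
        columns=["condition", "reaction_id", "lb", "ub", "relaxed"],
    ).to_csv(os.path.join(out, "exchange_bounds.tsv"), sep="\t", index=False)

    # ---- imat_solver ------------------------------------------------------
    calls: Dict[str, List[ActivityCallSet]] = {}
    mid_pair = config.threshold_pairs[len(config.threshold_pairs) // 2]
    solutions = {}
    for cond in conditions:
        calls[cond] = []
        for lo, hi in config.threshold_pairs:
            classes = classify_genes(
                expression[cond], lower_pct=lo, upper_pct=hi,
                restrict_to=model_genes if config.percentiles_on_model_genes
                else None,
            )
            state = reaction_states(bounded[cond], classes)
            cs = sensitivity_calls(
                bounded[cond], state, epsilon=config.epsilon,
                seed=config.seed,
            )
            calls[cond].append(cs)
            if (lo, hi) == tuple(mid_pair):
                problem = build_imat(bounded[cond], state,
                                     epsilon=config.epsilon)
                solutions[cond] = solve_imat(problem, seed=config.seed)
    consensus = {c: robustness_consensus(calls[c]) for c in conditions}

    call_table = pd.DataFrame({
        f"{cond}_{cs.threshold_pair}": pd.Series(cs.calls)
        for cond in conditions for cs in calls[cond]
    })
    for cond in conditions:
        call_table[f"{cond}_consensus"] = pd.Series(consensus[cond].calls)
    call_table.rename_axis("reaction_id").to_csv(
        os.path.join(out, "activity_calls.tsv"), sep="\t")

    # ---- pathway_analysis -------------------------------------------------
    cond_a, cond_b = conditions[0], conditions[-1] if len(conditions) > 1 \
        else conditions[0]
    if "exposed" in conditions and "control" in conditions:
        cond_a, cond_b = "exposed", "control"
    pathway_table = activity_long_table(calls, model)
    pathway_table.to_csv(os.path.join(out, "pathway_activity.tsv"),
                         sep="\t", index=False)
    differential = differential_pathways(
        calls[cond_a], calls[cond_b], model,
        diff_threshold=config.diff_threshold, alpha=config.alpha,
    )
    differential.to_csv(os.path.join(out, "differential_pathways.tsv"),
                        sep="\t")
    diff_rxns = differential_reactions(consensus[cond_a], consensus[cond_b])
    diff_rxns.to_csv(os.path.join(out, "differential_reactions.tsv"),
                     sep="\t", index=False)

    # ---- enrichment -------------------------------------------------------
    enrichment_df = None
    vip_series = None
    signature = None
    if config.gene_sets_path:
        gene_sets = read_gmt(config.gene_sets_path)
        enrichment_df = gsea(
            expression[cond_a], expression[cond_b], gene_sets,
            n_perm=config.n_perm, seed=config.seed,
        )
        enrichment_df.to_csv(os.path.join(out, "gsea_results.tsv"), sep="\t")
    try:
        vip_scores = plsda_vip(expression[cond_a], expression[cond_b])
        vip_series = vip_scores.vip
        signature = select_signature(vip_scores, config.vip_threshold)
        vip_series.rename_axis("gene_id").to_csv(
            os.path.join(out, "vip_scores.tsv"), sep="\t")
        with open(os.path.join(out, "signature.gmt"), "w") as fh:
            fh.write("\t".join(["VIP_SIGNATURE", "imatpipe", *signature]) + "\n")
    except ValueError:
        pass  # too few samples for PLS-DA; stage skipped

    # ---- validation -------------------------------------------------------
    validation = None
    if holdout:
        floor = config.epsilon / 100.0
        frames = []
        per_condition = {}
        for cond in conditions:
            ts_by_id = {ts.metabolite_id: ts for ts in metabolomics[cond]}
            mapping = {m: m for m in holdout if m in ts_by_id
                       and m in {r.id for r in model.reactions}}
            observed = {
                m: _observed_sign(
                    (ts_by_id[m].c5 - ts_by_id[m].c0) / config.duration, floor)
                for m in mapping
            }
            if config.validation_mode == "fva":
                # sign-determinate flux-variability intervals: predict only
                # when mass balance pins the held-out exchange away from zero
                from .model_prep import flux_variability

                fva = flux_variability(bounded[cond],
                                       reactions=sorted(mapping.values()))
                predicted = {}
                for m, rid in mapping.items():
                    lo, hi = fva.at[rid, "minimum"], fva.at[rid, "maximum"]
                    if lo >= floor:
                        predicted[m] = "secreted"
                    elif hi <= -floor:
                        predicted[m] = "consumed"
                    else:
                        predicted[m] = "none"
            else:
                predicted = predict_exchange_signs(
                    solutions[cond], consensus[cond], mapping,
                    epsilon=config.epsilon)
            try:
                rep = sign_agreement_test(predicted, observed)
            except ValueError:  # every held-out species abstained
                per_condition[cond] = {"n": 0}
                continue
            per_condition[cond] = rep.summary()
            df = rep.table.copy()
            df["condition"] = cond
            frames.append(df)
        pooled = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame(columns=["metabolite", "predicted",
                                             "observed", "agree"]))
        validation = {
            "per_condition": per_condition,
            "pooled_fraction_correct": (
                float(pooled["agree"].mean()) if len(pooled) else float("nan")
            ),
            "pooled_n": len(pooled),
            "held_out_species": sorted(holdout),
        }
        pooled.to_csv(os.path.join(out, "validation_table.tsv"), sep="\t",
                      index=False)
        with open(os.path.join(out, "validation_summary.json"), "w") as fh:
            json.dump(validation, fh, indent=2)

    # ---- manifest ---------------------------------------------------------
    inputs = [config.model_path, *config.expression_paths.values(),
              *config.metabolomics_paths.values()]
    if config.gene_sets_path:
        inputs.append(config.gene_sets_path)
    outputs = sorted(
        f for f in os.listdir(out)
        if f.endswith((".tsv", ".json", ".gmt")) and f != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "imatpipe_version": __version__,
        "solver": "scipy.optimize.milp (HiGHS), mip_rel_gap=0",
        "seed": config.seed,
        "inputs": {p: _sha256(p) for p in inputs},
        "outputs": {f: _sha256(os.path.join(out, f)) for f in outputs},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        calls=calls,
        consensus=consensus,
        pathway_table=pathway_table,
        differential=differential,
        differential_rxns=diff_rxns,
        enrichment=enrichment_df,
        vip=vip_series,
        signature=signature,
        validation=validation,
        manifest=manifest,
    )
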