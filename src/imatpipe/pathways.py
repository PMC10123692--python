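"""Pathway-level activity states and differential-activity statistics.

A pathway (GEM subsystem) activity state is the number of reactions called
active divided by the pathway's reaction count.  Two conditions are compared
per percentile-threshold pair with Fisher's exact test on the active /
not-active counts, Bonferroni-corrected by the number of pathways tested; a
pathway is differentially activated when the mean activity-ratio difference
across threshold pairs exceeds 10 percentage points and the maximum
corrected p-value across pairs is below 0.05.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import cobra
import numpy as np
import pandas as pd
from scipy import stats

from .imat import ActivityCallSet

__all__ = [
    "UNASSIGNED",
    "pathway_activity",
    "fisher_exact_2x2",
    "differential_pathways",
    "differential_reactions",
]

UNASSIGNED = "unassigned"

#: minimum |mean activity-ratio difference| for a differential call
DIFF_THRESHOLD = 0.10

#: corrected p-value cutoff
ALPHA = 0.05


def _subsystem_map(model: cobra.Model) -> dict:
    return {
        r.id: (r.subsystem if r.subsystem else UNASSIGNED)
        for r in model.reactions
    }


def _is_transport(subsystem: str) -> bool:
    return "transport" in subsystem.lower()


def pathway_activity(
    calls: ActivityCallSet, model: cobra.Model
) -> pd.DataFrame:
    """Per-subsystem active-reaction counts and activity ratios.

    Undetermined calls count as not active.  Reactions without a subsystem
    label are grouped under "unassigned".  Returns a DataFrame indexed by
    subsystem with columns n_active, n_total, ratio, threshold_pair,
    is_transport.
    """
    submap = _subsystem_map(model)
    rows: dict = {}
    for rid, sub in submap.items():
        n_active, n_total = rows.get(sub, (0, 0))
        rows[sub] = (
            n_active + (1 if calls.calls.get(rid) == "active" else 0),
            n_total + 1,
        )
    df = pd.DataFrame(
        [
            (sub, a, t, a / t, calls.threshold_pair, _is_transport(sub))
            for sub, (a, t) in sorted(rows.items())
        ],
        columns=["subsystem", "n_active", "n_total", "ratio",
                 "threshold_pair", "is_transport"],
    ).set_index("subsystem")
    return df


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    All-zero margins return 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


def differential_pathways(
    calls_a: Sequence[ActivityCallSet],
    calls_b: Sequence[ActivityCallSet],
    model: cobra.Model,
    diff_threshold: float = DIFF_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Differentially activated pathways between two conditions.

    ``calls_a`` and ``calls_b`` hold one call set per percentile threshold
    pair, matched between conditions.  Per subsystem and pair, Fisher's exact
    test compares active vs not-active counts (undetermined pooled with
    inactive); Bonferroni correction uses the number of subsystems tested,
    and the maximum corrected p over pairs is retained.  ``threshold_consistent``
    flags pathways whose per-pair tests never disagree with each other at
    ``alpha`` (i.e. no pair-vs-pair instability); the differential call uses
    the mean-ratio difference and max corrected p.
    """
    pairs_a = [cs.threshold_pair for cs in calls_a]
    pairs_b = [cs.threshold_pair for cs in calls_b]
    if pairs_a != pairs_b:
        raise ValueError(
            f"threshold pairs differ between conditions: {pairs_a} vs {pairs_b}"
        )
    act_a = [pathway_activity(cs, model) for cs in calls_a]
    act_b = [pathway_activity(cs, model) for cs in calls_b]
    subsystems = act_a[0].index
    n_tested = int((act_a[0]["n_total"] >= 1).sum())
    records = []
    for sub in subsystems:
        ratios_a = [df.at[sub, "ratio"] for df in act_a]
        ratios_b = [df.at[sub, "ratio"] for df in act_b]
        n_total = int(act_a[0].at[sub, "n_total"])
        corrected = []
        for df_a, df_b in zip(act_a, act_b):
            na, nb = int(df_a.at[sub, "n_active"]), int(df_b.at[sub, "n_active"])
            p = fisher_exact_2x2(na, n_total - na, nb, n_total - nb)
            corrected.append(min(1.0, p * n_tested))
        mean_a, mean_b = float(np.mean(ratios_a)), float(np.mean(ratios_b))
        diff = mean_a - mean_b
        max_p = float(max(corrected))
        records.append(
            dict(
                subsystem=sub,
                n_total=n_total,
                mean_ratio_A=mean_a,
                mean_ratio_B=mean_b,
                diff=diff,
                max_bonferroni_p=max_p,
                differential=bool(abs(diff) > diff_threshold and max_p < alpha),
                is_transport=_is_transport(sub),
            )
        )
    return pd.DataFrame(records).set_index("subsystem")


def activity_long_table(
    calls_by_condition: dict, model: cobra.Model
) -> pd.DataFrame:
    """Plot-ready long format: subsystem, condition, threshold_pair, ratio."""
    frames = []
    for condition, call_sets in calls_by_condition.items():
        for cs in call_sets:
            df = pathway_activity(cs, model).reset_index()
            df["condition"] = condition
            frames.append(df[["subsystem", "condition", "threshold_pair",
                              "ratio"]])
    return pd.concat(frames, ignore_index=True)


def differential_reactions(
    consensus_a: ActivityCallSet, consensus_b: ActivityCallSet
) -> pd.DataFrame:
    """Reactions with a consensus call of active in exactly one condition.

    A reaction is reported only when its consensus is active in one
    condition and inactive in the other; an undetermined consensus in either
    condition excludes it.
    """
    if set(consensus_a.calls) != set(consensus_b.calls):
        raise ValueError("consensus call sets cover different reactions")
    rows = []
    for rid in sorted(consensus_a.calls):
        ca, cb = consensus_a.calls[rid], consensus_b.calls[rid]
        if ca == "active" and cb == "inactive":
            rows.append((rid, "A"))
        elif ca == "inactive" and cb == "active":
            rows.append((rid, "B"))
    return pd.DataFrame(rows, columns=["reaction_id", "active_in"])
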