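"""Hold-out validation: predicted vs measured consumption/secretion signs.

Metabolites whose measured rates were *not* imposed as constraints provide an
independent check of the inferred flux state: the sign of each held-out
exchange flux in the optimal iMAT solution (positive = secreted, negative =
consumed) is compared with the sign of its measured rate, and the agreement
is tested with Fisher's exact test on the predicted-sign x observed-sign
contingency table (a binomial test against a 50% null is available as an
alternative).  Reactions with an undetermined consensus, or flux magnitude
below eps/100, abstain from prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import pandas as pd
from scipy import stats

from .imat import ActivityCallSet, ImatSolution
from .pathways import fisher_exact_2x2

__all__ = [
    "SignAgreementReport",
    "predict_exchange_signs",
    "sign_agreement_test",
]


def predict_exchange_signs(
    solution: ImatSolution,
    calls: Optional[ActivityCallSet],
    metabolite_to_exchange: Mapping[str, str],
    epsilon: float = 1.0,
) -> Dict[str, str]:
    """Predicted sign per metabolite: consumed / secreted / none.

    ``metabolite_to_exchange`` maps each held-out metabolite to its exchange
    (or sink) reaction.  Predictions abstain ("none") when the consensus
    call is undetermined or |flux| < eps/100.
    """
    if solution.fluxes is None:
        raise ValueError("solution carries no flux vector")
    missing = [m for m, r in metabolite_to_exchange.items()
               if r not in solution.fluxes.index]
    if missing:
        raise KeyError(
            f"no exchange reaction in the solution for metabolites: {missing}"
        )
    out: Dict[str, str] = {}
    floor = epsilon / 100.0
    for met, rid in metabolite_to_exchange.items():
        if calls is not None and calls.calls.get(rid) == "undetermined":
            out[met] = "none"
            continue
        v = float(solution.fluxes[rid])
        if v >= floor:
            out[met] = "secreted"
        elif v <= -floor:
            out[met] = "consumed"
        else:
            out[met] = "none"
    return out


@dataclass
class SignAgreementReport:
    table: pd.DataFrame  # metabolite, predicted, observed, agree
    n_compared: int
    fraction_correct: float
    p_value: float
    abstained: List[str] = field(default_factory=list)
    method: str = "fisher"

    def summary(self) -> dict:
        return {
            "n": self.n_compared,
            "fraction_correct": self.fraction_correct,
            "p_value": self.p_value,
            "n_abstained": len(self.abstained),
            "method": self.method,
        }


def sign_agreement_test(
    predicted: Mapping[str, str],
    observed: Mapping[str, str],
    method: str = "fisher",
) -> SignAgreementReport:
    """Agreement between predicted and observed consumption/secretion signs.

    Abstentions ("none" on either side) are excluded and reported.  With
    ``method="fisher"`` the 2x2 predicted-sign x observed-sign table is
    tested; ``method="binomial"`` tests #agreements against a fair-coin null
    (one-sided, greater).  A degenerate table (a single comparable
    metabolite, or an empty margin) yields p = 1.
    """
    rows = []
    abstained = []
    for met in sorted(predicted):
        pred = predicted[met]
        obs = observed.get(met, "none")
        if pred == "none" or obs == "none":
            abstained.append(met)
            continue
        rows.append((met, pred, obs, pred == obs))
    if not rows:
        raise ValueError("no metabolite with both a prediction and an observation")
    table = pd.DataFrame(rows, columns=["metabolite", "predicted", "observed",
                                        "agree"])
    n = len(table)
    frac = float(table["agree"].mean())
    if method == "fisher":
        a = int(((table.predicted == "consumed") & (table.observed == "consumed")).sum())
        b = int(((table.predicted == "consumed") & (table.observed == "secreted")).sum())
        c = int(((table.predicted == "secreted") & (table.observed == "consumed")).sum())
        d = int(((table.predicted == "secreted") & (table.observed == "secreted")).sum())
        p = fisher_exact_2x2(a, b, c, d)
    elif method == "binomial":
        p = float(stats.binomtest(int(table["agree"].sum()), n, 0.5,
                                  alternative="greater").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SignAgreementReport(
        table=table,
        n_compared=n,
        fraction_correct=frac,
        p_value=p,
        abstained=abstained,
        method=method,
    )
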