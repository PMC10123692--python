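import sys
from pathlib import Path

import cobra
import pytest
from cobra import Metabolite, Reaction

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from imatpipe.synthetic_data import generate_toy_gem


def build_model(reactions, bounds, mets_compartment="c"):
    """Small helper: build a cobra model from {rid: {met: coeff}} + bounds."""
    model = cobra.Model("fixture")
    mets = {}
    for stoich in reactions.values():
        for mid in stoich:
            if mid not in mets:
                tail = mid.rsplit("_", 1)[-1]
                comp = tail if len(tail) == 1 else mets_compartment
                mets[mid] = Metabolite(mid, compartment=comp)
    model.add_metabolites(list(mets.values()))
    rxns = []
    for rid, stoich in reactions.items():
        lo, hi = bounds.get(rid, (0.0, 1000.0))
        r = Reaction(rid, lower_bound=lo, upper_bound=hi)
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        rxns.append(r)
    model.add_reactions(rxns)
    return model


@pytest.fixture(scope="session")
def toy_bundle():
    """Default toy model + ground truth, shared read-only across tests."""
    return generate_toy_gem(seed=1)


@pytest.fixture()
def chain_model():
    """EX_A (uptake only) -> A -> B -> EX_B (secretion only)."""
    return build_model(
        {
            "EX_A": {"A": -1},
            "AB": {"A": -1, "B": 1},
            "EX_B": {"B": -1},
        },
        {"EX_A": (-10, 0), "AB": (0, 1000), "EX_B": (0, 10)},
    )
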