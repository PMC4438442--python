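import pytest

from symbionet.network_io import Reaction, network_from_reactions


def rxn(rid, subs, prods, ec=(), reversible=False, spontaneous=False):
    return Reaction(
        id=rid,
        substrates=tuple(subs),
        products=tuple(prods),
        ec_numbers=tuple(ec),
        reversible=reversible,
        spontaneous=spontaneous,
    )


@pytest.fixture
def linear_net():
    """A -> B -> C chain."""
    return network_from_reactions(
        "lin", [rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["C"])]
    )


@pytest.fixture
def and_net():
    """A + B -> C; C -> D (tests all-substrate firing)."""
    return network_from_reactions(
        "and", [rxn("r1", ["A", "B"], ["C"]), rxn("r2", ["C"], ["D"])]
    )
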