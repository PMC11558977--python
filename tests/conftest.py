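"""Shared fixtures: the minicore bundle and an independent COBRApy oracle."""

import cobra
import pytest

from ecflux import make_minicore, make_minicore_ec, minicore_conditions
from ecflux.io import to_cobra
from ecflux.model_core import split_and_expand
from ecflux.simulate import set_uptake


@pytest.fixture(scope="session")
def minicore_bundle():
    """(model, kcat records, subunit table, config) for the unsplit minicore."""
    return make_minicore()


@pytest.fixture(scope="session")
def minicore_model(minicore_bundle):
    return minicore_bundle[0]


@pytest.fixture(scope="session")
def minicore_config(minicore_bundle):
    return minicore_bundle[3]


@pytest.fixture(scope="session")
def minicore_ec():
    """The enzyme-constrained minicore with all sugars closed by default."""
    ec, _ = make_minicore_ec()
    return ec


@pytest.fixture(scope="session")
def minicore_split(minicore_model):
    """Split/expanded minicore *without* the pool row, sugars closed."""
    split, sm = split_and_expand(minicore_model)
    for exch, rate in minicore_conditions().items():
        set_uptake(split, exch, rate, sm)
    return split, sm


def cobra_ec_oracle(ec) -> cobra.Model:
    """Independent enzyme-constrained formulation in COBRApy (GLPK).

    The pool constraint is encoded GECKO-style through a pseudo-metabolite
    drawn by every enzymatic reaction and supplied by a bounded source
    reaction — a different formulation and solver than the implementation
    under test.
    """
    cm = to_cobra(ec.base)
    pool = cobra.Metabolite("enzyme_pool_pseudo", compartment="c")
    supply = cobra.Reaction("POOL_SUPPLY")
    supply.lower_bound = 0.0
    supply.upper_bound = ec.pool_bound
    cm.add_metabolites([pool])
    cm.add_reactions([supply])
    supply.add_metabolites({pool: 1.0})
    for rid, entry in ec.enzymes.items():
        cm.reactions.get_by_id(rid).add_metabolites({pool: -entry.pool_coefficient})
    return cm
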