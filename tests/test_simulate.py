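"""FBA/pFBA/minimum-enzyme solvers, FVA aggregation, PhPP grids."""

import numpy as np
import pytest

from ecflux.enzyme_layer import EnzymeEntry, build_ec_model
from ecflux.model_core import MetabolicModel, Metabolite, Reaction, SplitMap
from ecflux.simulate import (
    aggregate_variability,
    alternative_optima,
    fba,
    fva,
    fva_raw,
    min_enzyme_solution,
    pfba,
    phpp,
    with_conditions,
)
from ecflux.synthetic_data import minicore_conditions


def _chain_model():
    """source (ub 10) -> a -> sink."""
    m = MetabolicModel(objective_reaction_id="SINK")
    m.metabolites = [Metabolite(id="a")]
    m.reactions = [
        Reaction(id="SRC", stoichiometry={"a": 1}, upper_bound=10),
        Reaction(id="SINK", stoichiometry={"a": -1}, upper_bound=1000),
    ]
    return m


def _parallel_model():
    """a -> b directly, or a -> c -> b; demand on b."""
    m = MetabolicModel(objective_reaction_id="SINK")
    m.metabolites = [Metabolite(id="a"), Metabolite(id="b"), Metabolite(id="c")]
    m.reactions = [
        Reaction(id="SRC", stoichiometry={"a": 1}, upper_bound=10),
        Reaction(id="DIRECT", stoichiometry={"a": -1, "b": 1}),
        Reaction(id="VIA1", stoichiometry={"a": -1, "c": 1}),
        Reaction(id="VIA2", stoichiometry={"c": -1, "b": 1}),
        Reaction(id="SINK", stoichiometry={"b": -1}, upper_bound=1000),
    ]
    return m


def test_fba_bounded_chain():
    assert fba(_chain_model()).objective_value == pytest.approx(10.0)


def test_fba_with_pool_constraint_limits_flux():
    m = _chain_model()
    ec = build_ec_model(
        m, {"SINK": EnzymeEntry("SINK", [("g", 1, 36.0)], kcat=10.0, sigma=0.5)},
        ptot=0.02, f=0.5)
    # coefficient 0.002, pool 0.01 -> optimum 5
    assert fba(ec).objective_value == pytest.approx(5.0)


def test_fba_reports_infeasible_status():
    m = _chain_model()
    m.reactions[1].lower_bound = 20.0  # sink demands more than the source allows
    m.reactions[1].upper_bound = 30.0
    sol = fba(m)
    assert sol.status == "infeasible"


def test_ec_optimum_never_exceeds_unconstrained(minicore_ec, minicore_split):
    split, _ = minicore_split
    cond = minicore_conditions(glucose=10.0)
    mu_ec = fba(with_conditions(minicore_ec, cond)).objective_value
    mu_unc = fba(with_conditions(split, cond)).objective_value
    assert mu_ec <= mu_unc + 1e-9


def test_pfba_prefers_shorter_route():
    sol = pfba(_parallel_model())
    assert sol.objective_value == pytest.approx(10.0)
    assert sol.fluxes["DIRECT"] == pytest.approx(10.0)
    assert sol.fluxes["VIA1"] == pytest.approx(0.0, abs=1e-9)


def test_pfba_objective_matches_fba(minicore_ec):
    m = with_conditions(minicore_ec, minicore_conditions(glucose=3.0))
    assert pfba(m).objective_value == pytest.approx(fba(m).objective_value, abs=1e-9)


def test_pfba_minimal_among_sampled_optima(minicore_ec):
    m = with_conditions(minicore_ec, minicore_conditions(glucose=3.0))
    psol = pfba(m)
    ptotal = sum(abs(v) for v in psol.fluxes.values())
    alts = alternative_optima(m, n_samples=20, seed=42)
    assert len(alts) == 20
    for alt in alts:
        assert alt.objective_value == pytest.approx(psol.objective_value, abs=1e-6)
        assert ptotal <= sum(abs(v) for v in alt.fluxes.values()) + 1e-6
    ratios = [sum(abs(v) for v in a.fluxes.values()) / ptotal for a in alts]
    assert min(ratios) >= 1.0 - 1e-9


def test_min_enzyme_picks_fast_isozyme_route():
    m = _parallel_model()
    enz = {
        "DIRECT": EnzymeEntry("DIRECT", [("g1", 1, 100.0)], kcat=10.0, sigma=0.5),
        "VIA1": EnzymeEntry("VIA1", [("g2", 1, 100.0)], kcat=100.0, sigma=0.5),
        "VIA2": EnzymeEntry("VIA2", [("g3", 1, 100.0)], kcat=100.0, sigma=0.5),
    }
    ec = build_ec_model(m, enz, ptot=1.0, f=1.0)
    sol = min_enzyme_solution(ec, {"SINK": 1.0})
    assert sol.ok
    # two cheap steps (2 x 100/180000) still beat one slow step (100/18000)
    assert sol.objective_value == pytest.approx(2 * 100.0 / 180000.0)
    assert sol.fluxes["DIRECT"] == pytest.approx(0.0, abs=1e-9)
    assert min_enzyme_solution(ec, {"SINK": 0.0}).objective_value == pytest.approx(0.0)


def test_min_enzyme_monotone_in_demand(minicore_ec):
    m = with_conditions(minicore_ec, minicore_conditions(glucose=5.0))
    emins = []
    for mu in (0.0, 0.1, 0.2, 0.4, 0.6):
        sol = min_enzyme_solution(m, {"BIOMASS": mu})
        assert sol.ok
        emins.append(sol.objective_value)
    assert emins == sorted(emins)


def test_min_enzyme_infeasible_fixing_reported(minicore_ec):
    m = with_conditions(minicore_ec, minicore_conditions(glucose=0.0))
    sol = min_enzyme_solution(m, {"BIOMASS": 1.0})
    assert sol.status == "infeasible"


# -- FVA ---------------------------------------------------------------------

def test_fva_collapses_on_forced_chain():
    raw = fva_raw(_chain_model(), fraction_of_optimum=1.0)
    for vmin, vmax in raw.values():
        assert vmax - vmin == pytest.approx(0.0, abs=1e-6)


def test_fva_dead_end_branch_is_zero():
    m = _chain_model()
    m.metabolites.append(Metabolite(id="dead"))
    m.reactions.append(Reaction(id="IN_D", stoichiometry={"a": -1, "dead": 1}))
    raw = fva_raw(m, ["IN_D"], fraction_of_optimum=0.0)
    assert raw["IN_D"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))


@pytest.mark.parametrize(
    "raw, copies, expected_fv",
    [
        # isozyme copies: the maximal range wins
        ({"R_num1": (0, 3), "R_num2": (0, 5)},
         {"R_num1": ("R", 1), "R_num2": ("R", 1)}, 5.0),
        # reversible: forward range minus reverse range
        ({"R": (0, 5), "R_reverse": (0, 2)},
         {"R": ("R", 1), "R_reverse": ("R", -1)}, 3.0),
        # irreversible single copy: plain range
        ({"R": (1, 4)}, {"R": ("R", 1)}, 3.0),
        # negative result clamps to zero
        ({"R": (0, 1), "R_reverse": (0, 4)},
         {"R": ("R", 1), "R_reverse": ("R", -1)}, 0.0),
    ],
)
def test_variability_aggregation_rules(raw, copies, expected_fv):
    sm = SplitMap(copies=copies)
    ranges = aggregate_variability(raw, sm)
    assert len(ranges) == 1
    assert ranges[0].fv == pytest.approx(expected_fv)


def test_aggregation_missing_copy_rejected():
    sm = SplitMap(copies={"R": ("R", 1), "R_reverse": ("R", -1)})
    with pytest.raises(KeyError):
        aggregate_variability({"R": (0, 1)}, sm)


def test_fva_matches_cobra_oracle(minicore_ec):
    """Per-split-reaction ranges agree with COBRApy FVA (GLPK) to 1e-6."""
    from cobra.flux_analysis import flux_variability_analysis
    from conftest import cobra_ec_oracle

    m = with_conditions(minicore_ec, minicore_conditions(glucose=10.0))
    raw = fva_raw(m, fraction_of_optimum=1.0)
    cm = cobra_ec_oracle(m)
    df = flux_variability_analysis(cm, fraction_of_optimum=1.0, processes=1)
    for rid, (vmin, vmax) in raw.items():
        assert vmin == pytest.approx(df.loc[rid, "minimum"], abs=1e-6)
        assert vmax == pytest.approx(df.loc[rid, "maximum"], abs=1e-6)


def test_net_fva_never_below_verbatim(minicore_ec):
    m = with_conditions(minicore_ec, minicore_conditions(glucose=10.0))
    verbatim = {r.reaction_id: r.fv for r in fva(m, minicore_ec.split_map)}
    net = {r.reaction_id: r.fv for r in fva(m, minicore_ec.split_map, method="net")}
    for rid in verbatim:
        # the net range bounds the verbatim (reverse-subtracted) statistic
        assert net[rid] >= verbatim[rid] - 1e-6


# -- PhPP --------------------------------------------------------------------

def test_phpp_shape_and_zero_substrate_column(minicore_ec):
    sub, o2, growth = phpp(minicore_ec, "EX_glc_e", (0, 10), "EX_o2_e", (0, 50),
                           steps=(6, 11))
    assert growth.shape == (6, 11)
    assert np.allclose(growth[0, :], 0.0, atol=1e-9)


def test_phpp_growth_monotone_in_each_uptake(minicore_ec):
    _, _, growth = phpp(minicore_ec, "EX_glc_e", (0, 10), "EX_o2_e", (0, 50),
                        steps=(6, 6))
    assert np.all(np.diff(growth, axis=0) >= -1e-8)
    assert np.all(np.diff(growth, axis=1) >= -1e-8)
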