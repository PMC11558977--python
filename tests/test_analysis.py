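"""Overflow staging, hierarchy rules, target prediction."""

import numpy as np
import pandas as pd
import pytest

from ecflux.analysis import (
    adjustment_scan,
    hierarchy_order,
    precursor_efficiency,
    targets_hglp_lghp,
    targets_top_cost,
)
from ecflux.simulate import with_conditions
from ecflux.synthetic_data import minicore_conditions

SCAN_RATES = list(np.linspace(0.0, 6.0, 25))


@pytest.fixture(scope="module")
def scan(minicore_ec, minicore_config):
    cfg = minicore_config
    return adjustment_scan(
        minicore_ec, cfg["substrate_exchange_id"], SCAN_RATES, cfg["substrate_mw"],
        cfg["atp_metabolite_id"], cfg["oxphos_reaction_ids"],
        cfg["overflow_exchange_ids"],
    )


def test_stages_appear_in_canonical_order(scan):
    labels = [p.stage for p in scan]
    assert set(labels) == {"substrate_limited", "metabolic_adjustment",
                           "metabolic_overflow"}
    # contiguous runs in the canonical order
    order = {"substrate_limited": 0, "metabolic_adjustment": 1,
             "metabolic_overflow": 2}
    codes = [order[s] for s in labels]
    assert codes == sorted(codes)


def test_overflow_has_a_critical_uptake(scan, minicore_config):
    onset = [p.uptake for p in scan if p.overflow_flux > 1e-6]
    silent = [p.uptake for p in scan if p.overflow_flux <= 1e-6]
    assert onset and silent
    u_crit = min(onset)
    assert max(silent) < u_crit
    designed = minicore_config["ground_truth"].designed_critical_uptake
    assert u_crit == pytest.approx(designed, abs=0.5)
    # overflow grows with uptake beyond the critical point
    over = [p.overflow_flux for p in scan if p.uptake >= u_crit]
    assert all(b >= a - 1e-9 for a, b in zip(over, over[1:]))


def test_yield_efficiency_tradeoff(scan):
    beyond = [p for p in scan if p.stage != "substrate_limited"]
    yields = [p.biomass_yield for p in beyond]
    effs = [p.epsilon_biomass for p in beyond]
    assert all(b <= a + 1e-9 for a, b in zip(yields, yields[1:]))
    assert all(b >= a - 1e-9 for a, b in zip(effs, effs[1:]))


def test_oxphos_share_declines_with_uptake(scan):
    active = [p for p in scan if p.growth > 1e-6]
    assert active[0].oxphos_ratio >= active[-1].oxphos_ratio
    assert all(0.0 <= p.oxphos_ratio <= 1.0 + 1e-9 for p in scan)


def test_zero_uptake_point_flagged(scan):
    p0 = scan[0]
    assert p0.uptake == 0.0 and p0.yield_undefined and p0.biomass_yield == 0.0


def test_energy_cost_single_reaction_arithmetic(minicore_ec):
    # one ATP-producing reaction with E=0.01 and v_ATP=2 -> cost 0.005
    from ecflux.analysis import _atp_production

    m = with_conditions(minicore_ec, minicore_conditions(glucose=1.0))
    fluxes = {"PYK": 2.0}
    atp = _atp_production(m, fluxes, "atp_c")
    assert atp == {"PYK": 2.0}
    assert 0.01 / atp["PYK"] == pytest.approx(0.005)


# -- hierarchy ---------------------------------------------------------------

def test_carbon_scaled_uptake_bounds(minicore_config):
    cc = {name: info["carbon_count"]
          for name, info in minicore_config["substrates"].items()}
    bounds = {name: 15.0 / c for name, c in cc.items()}
    assert bounds == {
        "glucose": 2.5, "cellobiose": 1.25, "xylose": 3.0,
        "galactose": 2.5, "arabinose": 3.0,
    }


def test_efficiency_scale_invariance():
    # doubling flux and minimal enzyme together leaves efficiency unchanged
    assert 2.0 / 0.004 == pytest.approx((2 * 2.0) / (2 * 0.004))


def test_hierarchy_rule_full_dominance():
    eff = pd.DataFrame({"p1": [2.0, 1.0], "p2": [3.0, 2.0]}, index=["a", "b"])
    res = hierarchy_order(eff)
    assert res.dominance[("a", "b")] == "first_preferred"
    assert res.dominance[("b", "a")] == "second_preferred"
    assert res.tiers == [{"a"}, {"b"}]


def test_hierarchy_rule_mixed_and_tied_is_co_utilization():
    mixed = pd.DataFrame({"p1": [2.0, 1.0], "p2": [1.0, 2.0]}, index=["a", "b"])
    assert hierarchy_order(mixed).dominance[("a", "b")] == "co_utilized"
    tied = pd.DataFrame({"p1": [2.0, 2.0], "p2": [3.0, 1.0]}, index=["a", "b"])
    res = hierarchy_order(tied)
    assert res.dominance[("a", "b")] == "co_utilized"
    assert res.tiers == [{"a", "b"}]


def test_dominance_is_irreflexive_and_antisymmetric(minicore_ec, minicore_config):
    cfg = minicore_config
    eff = {}
    for name, info in cfg["substrates"].items():
        eff[name] = precursor_efficiency(
            minicore_ec, info["exchange"], info["carbon_count"],
            cfg["precursor_ids"][:4])  # a precursor subset keeps this test fast
    res = hierarchy_order(pd.DataFrame(eff).T)
    for (a, b), verdict in res.dominance.items():
        assert (a, a) not in res.dominance
        mirror = res.dominance[(b, a)]
        if verdict == "first_preferred":
            assert mirror == "second_preferred"
        elif verdict == "second_preferred":
            assert mirror == "first_preferred"
        else:
            assert mirror == "co_utilized"


def test_phosphorolytic_route_beats_glucose_on_g6p(minicore_ec, minicore_config):
    """The ATP-saving cellobiose cleavage yields higher G6P efficiency."""
    cfg = minicore_config
    e_cel = precursor_efficiency(minicore_ec, "EX_cel_e", 12, ["g6p_c"])["g6p_c"]
    e_glc = precursor_efficiency(minicore_ec, "EX_glc_e", 6, ["g6p_c"])["g6p_c"]
    assert e_cel > e_glc


def test_unreachable_precursor_scores_zero(minicore_ec):
    # with no substrate open, nothing can be made
    eff = precursor_efficiency(minicore_ec, "EX_glc_e", 6, ["g6p_c"],
                               carbon_uptake=0.0)
    assert eff["g6p_c"] == 0.0


# -- targets -----------------------------------------------------------------

def test_top_cost_ranks_by_descending_demand(minicore_ec, minicore_config):
    cond = minicore_conditions(glucose=minicore_config["target_glucose_uptake"])
    rep = targets_top_cost(minicore_ec, "EX_etoh_e", cond, n=2)
    assert len(rep.entries) == 2
    assert rep.entries[0].score >= rep.entries[1].score
    assert all(e.direction == "enhance" for e in rep.entries)


def test_top_cost_n_larger_than_gene_count(minicore_ec, minicore_config):
    cond = minicore_conditions(glucose=minicore_config["target_glucose_uptake"])
    rep = targets_top_cost(minicore_ec, "EX_etoh_e", cond, n=10000)
    assert len(rep.entries) <= len(minicore_ec.base.genes)


def test_top_cost_zero_product_flagged(minicore_ec):
    rep = targets_top_cost(minicore_ec, "EX_etoh_e", minicore_conditions(), n=5)
    assert rep.entries == [] and rep.flag is not None


def test_fermentation_genes_in_top_set(minicore_ec, minicore_config):
    cfg = minicore_config
    cond = minicore_conditions(glucose=cfg["target_glucose_uptake"])
    rep = targets_top_cost(minicore_ec, cfg["product_exchange_id"], cond, n=15)
    top = {e.identifier for e in rep.entries}
    for gene in cfg["ground_truth"].designed_targets["enhance_genes"]:
        assert gene in top


def test_hglp_lghp_directions_match_design(minicore_ec, minicore_config):
    cfg = minicore_config
    cond = minicore_conditions(glucose=cfg["target_glucose_uptake"])
    rep = targets_hglp_lghp(minicore_ec, cfg["product_exchange_id"], cond,
                            flux_threshold=1.0, low_biomass_fraction=0.1)
    directions = {e.identifier: e.direction for e in rep.entries}
    designed = cfg["ground_truth"].designed_targets
    for rid in designed["enhance_reactions"]:
        assert directions.get(rid) == "enhance"
    for rid in designed["weaken_reactions"]:
        assert directions.get(rid) == "weaken"
    # sorted by effect size
    scores = [abs(e.score) for e in rep.entries]
    assert scores == sorted(scores, reverse=True)


def test_hglp_threshold_excludes_small_fluxes(minicore_ec, minicore_config):
    cfg = minicore_config
    cond = minicore_conditions(glucose=cfg["target_glucose_uptake"])
    rep = targets_hglp_lghp(minicore_ec, cfg["product_exchange_id"], cond,
                            flux_threshold=1e9)
    assert rep.entries == []
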