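"""Proteome-allocation analyses on an enzyme-constrained model.

Three headline analyses:

* :func:`adjustment_scan` — sweep substrate uptake and record, per point,
  growth, biomass yield (gDW per g substrate), enzyme efficiency for biomass
  (growth per g of minimal enzyme), the energy-synthesis enzyme cost (summed
  enzyme-per-ATP over ATP-producing reactions), the share of ATP made by
  oxidative phosphorylation, and the overflow (fermentation-product)
  secretion flux.  Points are staged as substrate-limited (enzyme pool
  slack), metabolic adjustment (pool binding, no overflow) or metabolic
  overflow (overflow product secreted).
* :func:`precursor_efficiency` + :func:`hierarchy_order` — the enzyme
  efficiency of making each of the 12 biomass precursors from each sugar at
  equal carbon uptake predicts the order in which mixed substrates are
  consumed: a sugar whose efficiencies strictly dominate another's on every
  precursor is consumed first; mixed dominance means co-utilization.
* :func:`targets_top_cost` / :func:`targets_hglp_lghp` — engineering-target
  prediction by top enzyme demand at maximal product synthesis, and by
  enzyme-cost differences between a high-growth/low-product state and a
  low-growth/high-product state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .enzyme_layer import ECModel
from .model_core import Reaction, net_fluxes
from .simulate import fba, min_enzyme_solution, pfba, set_uptake, with_conditions

__all__ = [
    "AdjustmentPoint",
    "HierarchyResult",
    "TargetEntry",
    "TargetReport",
    "STAGES",
    "adjustment_scan",
    "precursor_efficiency",
    "hierarchy_order",
    "targets_top_cost",
    "targets_hglp_lghp",
]

_TOL = 1e-6

STAGES = ("substrate_limited", "metabolic_adjustment", "metabolic_overflow")


@dataclass
class AdjustmentPoint:
    uptake: float
    growth: float
    biomass_yield: float  # gDW per g substrate
    epsilon_biomass: float  # growth per (g enzyme/gDW)
    energy_cost: float  # g enzyme per (mmol ATP/gDW/h)
    oxphos_ratio: float
    overflow_flux: float
    stage: str
    yield_undefined: bool = False


def _atp_production(ec: ECModel, fluxes: Mapping[str, float], atp_id: str) -> dict:
    """ATP generated per reaction: positive ATP coefficient x carried flux."""
    out = {}
    for rxn in ec.base.reactions:
        coef = rxn.stoichiometry.get(atp_id, 0.0)
        v = fluxes.get(rxn.id, 0.0)
        if coef > 0 and v > _TOL:
            out[rxn.id] = coef * v
    return out


def adjustment_scan(
    ec: ECModel,
    substrate_exchange_id: str,
    uptake_rates: Sequence[float],
    substrate_mw: float,
    atp_metabolite_id: str,
    oxphos_reaction_ids: Iterable[str],
    overflow_exchange_ids: Iterable[str],
) -> list:
    """Metabolic-adjustment sweep over substrate uptake rates.

    Per rate, growth is solved by pFBA; the minimal enzyme demand at that
    growth (for the efficiency metric) comes from a minimum-enzyme LP with
    the biomass flux fixed.  Stage labels come from pool slack and overflow
    secretion, not dual values.
    """
    oxphos = set(oxphos_reaction_ids)
    overflow = set(overflow_exchange_ids)
    biomass_id = ec.base.objective_reaction_id
    rates = list(uptake_rates)
    if any(b < a - 1e-12 for a, b in zip(rates, rates[1:])):
        raise ValueError("uptake_rates must be ascending")
    points = []
    for u in rates:
        m = with_conditions(ec, {substrate_exchange_id: u})
        sol = pfba(m)
        growth = sol.objective_value if sol.ok else 0.0
        fluxes = sol.fluxes if sol.ok else {}
        yield_undef = u <= _TOL
        byield = 0.0 if yield_undef else growth / (u * substrate_mw)
        if growth > _TOL:
            emin_sol = min_enzyme_solution(m, {biomass_id: growth})
            emin = emin_sol.objective_value if emin_sol.ok else np.nan
            eps = growth / emin if emin and emin > 0 else 0.0
        else:
            eps = 0.0
        atp = _atp_production(ec, fluxes, atp_metabolite_id)
        total_atp = sum(atp.values())
        energy_cost = sum(
            sol.enzyme_usage.get(rid, 0.0) / v_atp for rid, v_atp in atp.items()
        ) if atp else 0.0
        ox_ratio = (
            sum(v for rid, v in atp.items() if rid in oxphos) / total_atp
            if total_atp > _TOL else 0.0
        )
        over = sum(fluxes.get(rid, 0.0) for rid in overflow)
        pool_slack = ec.pool_bound * (1.0 - sol.pool_utilization) if sol.ok else ec.pool_bound
        if pool_slack > _TOL:
            stage = "substrate_limited"
        elif over > _TOL:
            stage = "metabolic_overflow"
        else:
            stage = "metabolic_adjustment"
        points.append(
            AdjustmentPoint(
                uptake=u, growth=growth, biomass_yield=byield, epsilon_biomass=eps,
                energy_cost=energy_cost, oxphos_ratio=ox_ratio, overflow_flux=over,
                stage=stage, yield_undefined=yield_undef,
            )
        )
    return points


# ---------------------------------------------------------------------------
# substrate hierarchy
# ---------------------------------------------------------------------------

def precursor_efficiency(
    ec: ECModel,
    substrate_exchange_id: str,
    carbon_count: int,
    precursor_ids: Sequence[str],
    carbon_uptake: float = 15.0,
) -> dict:
    """Enzyme efficiency of making each precursor from one substrate.

    The substrate uptake bound is ``carbon_uptake / carbon_count`` (equal
    carbon supply across substrates).  Per precursor a temporary enzyme-free
    drain is added, its flux maximized, the minimal enzyme demand at that
    flux computed, and the efficiency reported as flux / enzyme.  An
    unreachable precursor gets efficiency 0.
    """
    if carbon_count <= 0:
        raise ValueError("carbon_count must be > 0")
    met_ids = set(ec.base.metabolite_ids)
    for pid in precursor_ids:
        if pid not in met_ids:
            raise KeyError(f"precursor {pid!r} not in model")
    uptake = carbon_uptake / carbon_count
    out = {}
    for pid in precursor_ids:
        m = ec.copy()
        set_uptake(m, substrate_exchange_id, uptake)
        drain = Reaction(id=f"DM_{pid}", name=f"{pid} drain",
                         stoichiometry={pid: -1.0}, lower_bound=0.0, upper_bound=1000.0)
        m.base.reactions.append(drain)
        sol = fba(m, objective_id=drain.id)
        v = sol.objective_value if sol.ok else 0.0
        if v <= _TOL:
            out[pid] = 0.0
            continue
        emin_sol = min_enzyme_solution(m, {drain.id: v})
        emin = emin_sol.objective_value if emin_sol.ok else np.nan
        out[pid] = v / emin if emin and emin > 0 else 0.0
    return out


@dataclass
class HierarchyResult:
    efficiency: pd.DataFrame  # substrates x precursors
    dominance: dict  # (a, b) -> first_preferred | second_preferred | co_utilized
    tiers: list  # ordered list of substrate sets


def hierarchy_order(efficiency) -> HierarchyResult:
    """Dominance ordering and utilization tiers from an efficiency matrix.

    Substrate a is preferred over b iff its efficiency is strictly higher on
    *every* precursor; any tie or mixed comparison means co-utilization.
    Tiers are extracted by repeatedly taking the substrates not strictly
    dominated by any remaining substrate.
    """
    eff = pd.DataFrame(efficiency) if not isinstance(efficiency, pd.DataFrame) else efficiency
    subs = list(eff.index)
    if eff.isna().any().any():
        raise ValueError("efficiency matrix is incomplete")

    def dominates(a, b):
        return bool((eff.loc[a] > eff.loc[b]).all())

    dominance = {}
    for a in subs:
        for b in subs:
            if a == b:
                continue
            if dominates(a, b):
                dominance[(a, b)] = "first_preferred"
            elif dominates(b, a):
                dominance[(a, b)] = "second_preferred"
            else:
                dominance[(a, b)] = "co_utilized"
    tiers = []
    remaining = list(subs)
    while remaining:
        tier = {
            s for s in remaining
            if not any(dominates(t, s) for t in remaining if t != s)
        }
        if not tier:  # dominance cycles cannot occur with strict inequality
            tier = set(remaining)
        tiers.append(tier)
        remaining = [s for s in remaining if s not in tier]
    return HierarchyResult(efficiency=eff, dominance=dominance, tiers=tiers)


# ---------------------------------------------------------------------------
# engineering targets
# ---------------------------------------------------------------------------

@dataclass
class TargetEntry:
    identifier: str  # gene id (method 1) or reaction id (method 2)
    score: float  # g enzyme/gDW, or LGHP-HGLP cost difference
    direction: str  # enhance | weaken | none
    rank: int


@dataclass
class TargetReport:
    product_id: str
    method: str  # top_cost | hglp_lghp
    entries: list = field(default_factory=list)
    flag: Optional[str] = None


def targets_top_cost(
    ec: ECModel,
    product_exchange_id: str,
    conditions: Mapping[str, float],
    n: int = 15,
) -> TargetReport:
    """Top-demanded proteins at maximal product synthesis (overexpression set).

    pFBA maximizes the product exchange; each reaction's enzyme demand is
    split among its complex's genes by subunit mass share and summed per
    gene; the n most demanded genes are the enhancement candidates.
    """
    m = with_conditions(ec, conditions)
    sol = pfba(m, objective_id=product_exchange_id)
    if not sol.ok or sol.objective_value <= _TOL:
        return TargetReport(product_exchange_id, "top_cost", [],
                            flag="zero product optimum")
    cost: dict = {}
    for rid, e in sol.enzyme_usage.items():
        if e <= 0:
            continue
        for gene, share in ec.enzymes[rid].gene_mass_share().items():
            cost[gene] = cost.get(gene, 0.0) + e * share
    ranked = sorted(cost.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    entries = [
        TargetEntry(identifier=g, score=s, direction="enhance", rank=i + 1)
        for i, (g, s) in enumerate(ranked)
    ]
    return TargetReport(product_exchange_id, "top_cost", entries)


def _state_profile(ec: ECModel, biomass_value: float, product_exchange_id: str):
    """Fluxes/enzyme costs with biomass pinned and product maximized."""
    m = ec.copy()
    biomass_id = m.base.objective_reaction_id
    rxn = m.base.reaction(biomass_id)
    rxn.lower_bound = max(biomass_value - 1e-9, 0.0)
    rxn.upper_bound = biomass_value + 1e-9
    sol = pfba(m, objective_id=product_exchange_id)
    if not sol.ok:
        raise RuntimeError(f"biomass fixing at {biomass_value} is {sol.status}")
    net = net_fluxes(
        {rid: v for rid, v in sol.fluxes.items() if rid in ec.split_map.copies},
        ec.split_map,
    ) if ec.split_map else dict(sol.fluxes)
    cost: dict = {}
    for rid, e in sol.enzyme_usage.items():
        oid = ec.split_map.copies[rid][0] if ec.split_map else rid
        cost[oid] = cost.get(oid, 0.0) + e
    return net, cost


def targets_hglp_lghp(
    ec: ECModel,
    product_exchange_id: str,
    conditions: Mapping[str, float],
    flux_threshold: float = 1.0,
    low_biomass_fraction: float = 0.1,
) -> TargetReport:
    """Enhance/weaken targets from high-growth vs low-growth product states.

    HGLP pins biomass at 100% of its maximum and maximizes the product;
    LGHP pins biomass at ``low_biomass_fraction`` of the maximum.  Reactions
    carrying more than ``flux_threshold`` in either state are candidates;
    those with higher enzyme cost (and flux) in the low-growth/high-product
    state are enhancement targets, those with lower are weakening targets.
    """
    m = with_conditions(ec, conditions)
    mu_max = fba(m).objective_value
    if not np.isfinite(mu_max) or mu_max <= _TOL:
        raise RuntimeError("biomass optimum is zero under the given conditions")
    net_h, cost_h = _state_profile(m, mu_max, product_exchange_id)
    net_l, cost_l = _state_profile(m, low_biomass_fraction * mu_max, product_exchange_id)
    entries = []
    for oid in sorted(set(net_h) | set(net_l)):
        fh, fl = abs(net_h.get(oid, 0.0)), abs(net_l.get(oid, 0.0))
        if max(fh, fl) <= flux_threshold:
            continue
        ch, cl = cost_h.get(oid, 0.0), cost_l.get(oid, 0.0)
        dcost = cl - ch
        if dcost > _TOL and fl > fh + _TOL:
            direction = "enhance"
        elif dcost < -_TOL and fl < fh - _TOL:
            direction = "weaken"
        else:
            direction = "none"
        entries.append(TargetEntry(identifier=oid, score=dcost, direction=direction, rank=0))
    entries.sort(key=lambda e: (-abs(e.score), e.identifier))
    for i, e in enumerate(entries):
        e.rank = i + 1
    return TargetReport(product_exchange_id, "hglp_lghp", entries)
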