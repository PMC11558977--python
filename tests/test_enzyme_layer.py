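"""Enzyme mass fraction, complex assembly, kcat merging and the pool row."""

import pytest

from ecflux.enzyme_layer import (
    EnzymeEntry,
    KcatRecord,
    ProteomicsRecord,
    assemble_mw,
    build_ec_model,
    enzyme_mass_fraction,
    enzyme_usage,
    merge_kcat,
)
from ecflux.model_core import MetabolicModel, Metabolite, Reaction
from ecflux.simulate import fba, with_conditions
from ecflux.synthetic_data import minicore_conditions


# -- mass fraction (abundance-weighted MW ratio) -----------------------------

def test_mass_fraction_partial_coverage():
    prot = [ProteomicsRecord("p1", 1.0, 10.0), ProteomicsRecord("p2", 1.0, 30.0)]
    assert enzyme_mass_fraction(prot, {"p1"}) == pytest.approx(0.25)


def test_mass_fraction_full_and_zero_coverage():
    prot = [ProteomicsRecord("p1", 2.0, 10.0), ProteomicsRecord("p2", 1.0, 30.0)]
    assert enzyme_mass_fraction(prot, {"p1", "p2"}) == 1.0
    assert enzyme_mass_fraction(prot, set()) == 0.0


def test_mass_fraction_empty_proteome_rejected():
    with pytest.raises(ValueError):
        enzyme_mass_fraction([], {"p1"})


# -- complex MW assembly -----------------------------------------------------

def test_assemble_mw_homodimer_and_heterocomplex():
    assert assemble_mw([("g1", 2, 50.0)]) == 100.0
    assert assemble_mw([("g1", 2, 50.0), ("g2", 1, 30.0)]) == 130.0


def test_assemble_mw_missing_count_defaults_to_one():
    assert assemble_mw([("g1", None, 50.0)]) == 50.0


def test_assemble_mw_empty_complex_rejected():
    with pytest.raises(ValueError):
        assemble_mw([])


# -- kcat merging ------------------------------------------------------------

def test_merge_prefers_higher_priority_source():
    recs = [KcatRecord("R1", 5.0, "turnup_predicted"), KcatRecord("R1", 7.0, "database")]
    out = merge_kcat(recs, ("database", "turnup_predicted"), ["R1"], "none")
    assert out["R1"].value == 7.0


def test_merge_median_imputation():
    recs = [KcatRecord("R1", 1.0, "database"), KcatRecord("R2", 4.0, "database"),
            KcatRecord("R3", 100.0, "database")]
    out = merge_kcat(recs, ("database",), ["R1", "R2", "R3", "R4"], "median")
    assert out["R4"].value == 4.0
    assert out["R4"].source == "imputed"


def test_merge_no_imputation_leaves_gap():
    recs = [KcatRecord("R1", 1.0, "database")]
    out = merge_kcat(recs, ("database",), ["R1", "R2"], "none")
    assert "R2" not in out


def test_merge_empty_records_with_median_rejected():
    with pytest.raises(ValueError):
        merge_kcat([], ("database",), ["R1"], "median")


# -- pool constraint ---------------------------------------------------------

def test_pool_bound_is_ptot_times_f(minicore_ec):
    assert minicore_ec.pool_bound == pytest.approx(0.4653 * 0.55)
    assert minicore_ec.pool_bound == pytest.approx(0.255915)


def test_pool_coefficient_units():
    # MW 36 kDa, sigma 0.5, kcat 10/s -> 36/(0.5*10*3600) = 0.002 g.h/mmol
    entry = EnzymeEntry("R", [("g", 1, 36.0)], kcat=10.0, sigma=0.5)
    assert entry.pool_coefficient == pytest.approx(0.002)


def test_enzyme_usage_arithmetic():
    m = MetabolicModel(objective_reaction_id="R")
    m.metabolites = [Metabolite(id="a")]
    m.reactions = [Reaction(id="R", stoichiometry={"a": 0})]
    # zero-coefficient stoichiometry is invalid; use a throughput reaction
    m.reactions = [
        Reaction(id="SRC", stoichiometry={"a": 1}),
        Reaction(id="R", stoichiometry={"a": -1}),
    ]
    ec = build_ec_model(
        m, {"R": EnzymeEntry("R", [("g", 1, 100.0)], kcat=10.0, sigma=0.5)},
        ptot=0.4653, f=0.55)
    usage, total = enzyme_usage(ec, {"R": 1.0, "SRC": 1.0})
    assert usage["R"] == pytest.approx(100.0 / 18000.0)
    assert total == pytest.approx(100.0 / 18000.0)
    usage0, total0 = enzyme_usage(ec, {"R": 0.0, "SRC": 0.0})
    assert total0 == 0.0


def test_enzyme_usage_rejects_negative_flux(minicore_ec):
    with pytest.raises(ValueError):
        enzyme_usage(minicore_ec, {rid: -1.0 for rid in minicore_ec.enzymes})


def test_ec_model_rejects_unknown_enzyme_reaction(minicore_model):
    from ecflux.model_core import split_and_expand

    split, _ = split_and_expand(minicore_model)
    with pytest.raises(KeyError):
        build_ec_model(split, {"NOPE": EnzymeEntry("NOPE", [("g", 1, 10.0)], kcat=1.0)})


def test_ec_model_rejects_nonpositive_pool(minicore_model):
    from ecflux.model_core import split_and_expand

    split, _ = split_and_expand(minicore_model)
    with pytest.raises(ValueError):
        build_ec_model(split, {}, ptot=0.0, f=0.55)


def test_pool_binds_at_saturating_substrate(minicore_ec):
    m = with_conditions(minicore_ec, minicore_conditions(glucose=10.0))
    sol = fba(m)
    assert sol.ok
    assert sol.pool_utilization == pytest.approx(1.0, abs=1e-6)


def test_kcat_monotonicity(minicore_ec):
    """Raising any single kcat never lowers growth; lowering never raises it."""
    base = with_conditions(minicore_ec, minicore_conditions(glucose=4.0))
    mu0 = fba(base).objective_value
    for rid in sorted(minicore_ec.enzymes)[::5]:  # sampled subset, deterministic
        for fac, sense in ((2.0, 1), (0.5, -1)):
            mod = base.copy()
            mod.enzymes[rid].kcat *= fac
            mu = fba(mod).objective_value
            if sense > 0:
                assert mu >= mu0 - 1e-9
            else:
                assert mu <= mu0 + 1e-9


def test_pool_monotone_in_bound_and_unbounded_limit(minicore_ec, minicore_split):
    split, _ = minicore_split
    cond = minicore_conditions(glucose=5.0)
    mus = []
    for f in (0.2, 0.4, 0.55, 0.8):
        ec = minicore_ec.copy()
        ec.f = f
        mus.append(fba(with_conditions(ec, cond)).objective_value)
    assert mus == sorted(mus)
    # enormous pool reproduces the unconstrained optimum
    ec = minicore_ec.copy()
    ec.f = 1e6
    mu_free = fba(with_conditions(ec, cond)).objective_value
    mu_unc = fba(with_conditions(split, cond)).objective_value
    assert mu_free == pytest.approx(mu_unc, abs=1e-6)
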