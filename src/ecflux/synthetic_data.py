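"""Deterministic generators for all model and table inputs.

The central fixture, the *minicore*, is a small lumped central-carbon
network engineered to exhibit the phenomena an enzyme-constrained model is
built to capture:

* five sugar uptake routes — glucose, cellobiose (with both a hydrolytic and
  an ATP-saving phosphorolytic cleavage), xylose, galactose and arabinose
  (two extra enzymatic steps on top of the xylose route);
* glycolysis, an abstract pentose-phosphate shunt, TCA cycle;
* two respiratory modes — a high-ATP-yield oxidative-phosphorylation complex
  with a large molecular weight (expensive enzyme per unit flux) and a
  cheaper low-yield alternative oxidase route — plus low-cost ethanol
  fermentation, so that growth saturates and overflow metabolism appears as
  substrate uptake rises;
* a biomass reaction drawing on the 12 classic precursor metabolites.

Enzyme-cost contrasts are encoded through kcat/MW choices: respiration is
far more expensive per ATP than fermentation, the phosphorolytic cellobiose
route spares ATP (and hence respiration enzyme), and the arabinose entry
enzymes are slow.  All generators are pure functions of their arguments;
repeated calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .calibrate import FluxMeasurement
from .enzyme_layer import (
    DEFAULT_F,
    DEFAULT_PTOT,
    DEFAULT_SIGMA,
    ECModel,
    KcatRecord,
    ProteomicsRecord,
    build_ec_model,
    build_enzyme_entries,
    merge_kcat,
)
from .model_core import (
    Gene,
    MetabolicModel,
    Metabolite,
    Reaction,
    net_fluxes,
    split_and_expand,
)
from .simulate import pfba, with_conditions

__all__ = [
    "GroundTruth",
    "make_minicore",
    "make_minicore_ec",
    "minicore_conditions",
    "make_random_toy",
    "synth_proteome",
    "perturb_kcats",
    "synth_c13_fluxes",
]


@dataclass
class GroundTruth:
    """Designed facts recorded before any perturbation; the recovery surface."""

    planted_f: Optional[float] = None
    original_kcats: dict = field(default_factory=dict)
    designed_tiers: list = field(default_factory=list)
    designed_critical_uptake: Optional[float] = None
    designed_targets: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# the minicore fixture
# ---------------------------------------------------------------------------

# metabolite id -> (name, compartment, carbon count or None for cofactors)
_MINICORE_METS = {
    "glc_e": ("glucose (ext)", "e", 6),
    "cel_e": ("cellobiose (ext)", "e", 12),
    "xyl_e": ("xylose (ext)", "e", 5),
    "gal_e": ("galactose (ext)", "e", 6),
    "ara_e": ("arabinose (ext)", "e", 5),
    "o2_e": ("oxygen (ext)", "e", 0),
    "etoh_e": ("ethanol (ext)", "e", 2),
    "co2_e": ("CO2 (ext)", "e", 1),
    "glc_c": ("glucose", "c", 6),
    "cel_c": ("cellobiose", "c", 12),
    "g1p_c": ("glucose 1-phosphate", "c", 6),
    "gal_c": ("galactose", "c", 6),
    "galint_c": ("galactose-1P/UDP intermediate", "c", 6),
    "xyl_c": ("xylose", "c", 5),
    "ara_c": ("arabinose", "c", 5),
    "araint_c": ("arabitol intermediate", "c", 5),
    "g6p_c": ("glucose 6-phosphate", "c", 6),
    "f6p_c": ("fructose 6-phosphate", "c", 6),
    "g3p_c": ("glyceraldehyde 3-phosphate", "c", 3),
    "pg3_c": ("glycerate 3-phosphate", "c", 3),
    "pep_c": ("phosphoenolpyruvate", "c", 3),
    "pyr_c": ("pyruvate", "c", 3),
    "accoa_c": ("acetyl-CoA", "c", 2),
    "oaa_c": ("oxaloacetate", "c", 4),
    "akg_c": ("2-oxoglutarate", "c", 5),
    "succ_c": ("succinate", "c", 4),
    "e4p_c": ("erythrose 4-phosphate", "c", 4),
    "r5p_c": ("ribose 5-phosphate", "c", 5),
    "x5p_c": ("xylulose 5-phosphate", "c", 5),
    "acd_c": ("acetaldehyde", "c", 2),
    "etoh_c": ("ethanol", "c", 2),
    "o2_c": ("oxygen", "c", 0),
    "co2_c": ("CO2", "c", 1),
    "atp_c": ("ATP", "c", None),
    "adp_c": ("ADP", "c", None),
    "nadh_c": ("NADH", "c", None),
    "nad_c": ("NAD+", "c", None),
}

_PRECURSORS = [
    "g6p_c", "f6p_c", "g3p_c", "pg3_c", "pep_c", "pyr_c",
    "accoa_c", "oaa_c", "akg_c", "succ_c", "e4p_c", "r5p_c",
]

# biomass draw per unit growth (mmol precursor / g biomass, toy scale)
_BIOMASS = {
    "g6p_c": -0.6, "f6p_c": -0.3, "g3p_c": -0.3, "pg3_c": -0.45,
    "pep_c": -0.45, "pyr_c": -0.75, "accoa_c": -0.9, "oaa_c": -0.6,
    "akg_c": -0.45, "succ_c": -0.15, "e4p_c": -0.15, "r5p_c": -0.3,
    "atp_c": -60.0, "adp_c": 60.0,
}

# id -> (name, stoichiometry, lb, ub, gpr)
_MINICORE_RXNS = [
    # exchanges (uptake = negative flux)
    ("EX_glc_e", "glucose exchange", {"glc_e": -1}, -1000, 1000, ""),
    ("EX_cel_e", "cellobiose exchange", {"cel_e": -1}, -1000, 1000, ""),
    ("EX_xyl_e", "xylose exchange", {"xyl_e": -1}, -1000, 1000, ""),
    ("EX_gal_e", "galactose exchange", {"gal_e": -1}, -1000, 1000, ""),
    ("EX_ara_e", "arabinose exchange", {"ara_e": -1}, -1000, 1000, ""),
    ("EX_o2_e", "oxygen exchange", {"o2_e": -1}, -1000, 0, ""),
    ("EX_etoh_e", "ethanol exchange", {"etoh_e": -1}, 0, 1000, ""),
    ("EX_co2_e", "CO2 exchange", {"co2_e": -1}, 0, 1000, ""),
    # sugar entry
    ("GLCt", "glucose transport", {"glc_e": -1, "glc_c": 1}, 0, 1000, "hxt"),
    ("HEX", "hexokinase", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
     0, 1000, "hxk1 or glk1"),
    ("CELt", "cellobiose transport", {"cel_e": -1, "cel_c": 1}, 0, 1000, "celt"),
    ("CELH", "cellobiose hydrolysis (beta-glucosidase)",
     {"cel_c": -1, "glc_c": 2}, 0, 1000, "bgl"),
    ("CELP", "cellobiose phosphorolysis",
     {"cel_c": -1, "glc_c": 1, "g1p_c": 1}, 0, 1000, "cbp"),
    ("PGMT", "phosphoglucomutase", {"g1p_c": -1, "g6p_c": 1}, 0, 1000, "pgm"),
    ("GALt", "galactose transport", {"gal_e": -1, "gal_c": 1}, 0, 1000, "galt"),
    ("GAL1", "galactokinase", {"gal_c": -1, "atp_c": -1, "galint_c": 1, "adp_c": 1},
     0, 1000, "gal1"),
    ("GAL2", "galactose interconversion (Leloir, lumped)",
     {"galint_c": -1, "g6p_c": 1}, 0, 1000, "gal7"),
    ("XYLt", "xylose transport", {"xyl_e": -1, "xyl_c": 1}, 0, 1000, "xylt"),
    ("XYL1", "xylose assimilation (lumped, ATP-consuming)",
     {"xyl_c": -1, "atp_c": -1, "x5p_c": 1, "adp_c": 1}, 0, 1000, "xyl123"),
    ("ARAt", "arabinose transport", {"ara_e": -1, "ara_c": 1}, 0, 1000, "arat"),
    ("ARA1", "arabinose reduction (lumped)", {"ara_c": -1, "araint_c": 1}, 0, 1000, "ara1"),
    ("ARA2", "arabitol oxidation (lumped)", {"araint_c": -1, "xyl_c": 1}, 0, 1000, "ara2"),
    # glycolysis
    ("PGI", "phosphoglucose isomerase", {"g6p_c": -1, "f6p_c": 1}, -1000, 1000, "pgi"),
    ("PFK_ALD", "upper glycolysis (PFK+aldolase)",
     {"f6p_c": -1, "atp_c": -1, "g3p_c": 2, "adp_c": 1}, 0, 1000, "pfk"),
    ("GAPD_PGK", "lower glycolysis (GAPDH+PGK)",
     {"g3p_c": -1, "nad_c": -1, "adp_c": -1, "pg3_c": 1, "nadh_c": 1, "atp_c": 1},
     0, 1000, "gap"),
    ("ENO", "enolase (lumped PGM+ENO)", {"pg3_c": -1, "pep_c": 1}, -1000, 1000, "eno"),
    ("PYK", "pyruvate kinase", {"pep_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1},
     0, 1000, "pyk"),
    ("PDH", "pyruvate dehydrogenase",
     {"pyr_c": -1, "nad_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
     0, 1000, "pda1 and pdb1"),
    # pentose phosphate (abstract)
    ("G6PDH", "oxidative PPP (lumped)", {"g6p_c": -1, "x5p_c": 1, "co2_c": 1},
     0, 1000, "zwf"),
    ("RPI", "ribose-5P isomerase", {"x5p_c": -1, "r5p_c": 1}, -1000, 1000, "rpi"),
    ("TKT", "transketolase (pentose->hexose, lumped)",
     {"x5p_c": -1.2, "f6p_c": 1}, 0, 1000, "tkt"),
    ("TAL", "transaldolase (E4P-forming, lumped)",
     {"f6p_c": -1, "g3p_c": -1, "e4p_c": 1, "x5p_c": 1}, 0, 1000, "tal"),
    # TCA + anaplerosis
    ("PPC", "PEP carboxylase", {"pep_c": -1, "co2_c": -1, "oaa_c": 1}, 0, 1000, "ppc"),
    ("CS_IDH", "citrate synthase + IDH (lumped)",
     {"oaa_c": -1, "accoa_c": -1, "nad_c": -1, "akg_c": 1, "co2_c": 1, "nadh_c": 1},
     0, 1000, "cit"),
    ("AKGDH", "2-oxoglutarate dehydrogenase complex (lumped, SL-phosphorylation)",
     {"akg_c": -1, "nad_c": -1, "adp_c": -1, "succ_c": 1, "co2_c": 1, "nadh_c": 1,
      "atp_c": 1}, 0, 1000, "kgd1 and lpd1"),
    ("SDH_MDH", "succinate->oxaloacetate (lumped SDH+FUM+MDH)",
     {"succ_c": -1, "nad_c": -2, "oaa_c": 1, "nadh_c": 2}, 0, 1000, "sdh"),
    # energy
    ("OXPHOS_HY", "oxidative phosphorylation, high yield (complexes I-V)",
     {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2.5, "nad_c": 1, "atp_c": 2.5},
     0, 1000, "nda1 and cyc1 and atp1"),
    ("OXPHOS_LY", "alternative oxidase route, low yield",
     {"nadh_c": -1, "o2_c": -0.5, "adp_c": -1.5, "nad_c": 1, "atp_c": 1.5},
     0, 1000, "aox"),
    ("O2t", "oxygen diffusion", {"o2_e": -1, "o2_c": 1}, 0, 1000, ""),
    ("CO2t", "CO2 diffusion", {"co2_c": -1, "co2_e": 1}, 0, 1000, ""),
    # fermentation
    ("PDC", "pyruvate decarboxylase", {"pyr_c": -1, "acd_c": 1, "co2_c": 1},
     0, 1000, "pdc"),
    ("ADH", "alcohol dehydrogenase",
     {"acd_c": -1, "nadh_c": -1, "etoh_c": 1, "nad_c": 1}, 0, 1000, "adh"),
    ("ETOHt", "ethanol diffusion", {"etoh_c": -1, "etoh_e": 1}, 0, 1000, ""),
    # maintenance / biomass
    ("ATPH", "ATP hydrolysis (non-enzymatic sink)", {"atp_c": -1, "adp_c": 1},
     0, 1000, ""),
    ("BIOMASS", "biomass synthesis", dict(_BIOMASS), 0, 1000, ""),
]

# gene -> (subunit MW in kDa, subunit count per complex)
_MINICORE_SUBUNITS = {
    "hxt": (60.0, 1), "hxk1": (54.0, 1), "glk1": (108.0, 1),
    "celt": (70.0, 1), "bgl": (110.0, 1), "cbp": (90.0, 1), "pgm": (55.0, 1),
    "galt": (65.0, 1), "gal1": (58.0, 1), "gal7": (62.0, 1),
    "xylt": (65.0, 1), "xyl123": (140.0, 1),
    "arat": (65.0, 1), "ara1": (95.0, 1), "ara2": (98.0, 1),
    "pgi": (61.0, 1), "pfk": (85.0, 1), "gap": (36.0, 1), "eno": (47.0, 1),
    "pyk": (55.0, 1), "pda1": (120.0, 1), "pdb1": (80.0, 1),
    "zwf": (110.0, 1), "rpi": (25.0, 1), "tkt": (75.0, 1), "tal": (36.0, 1),
    "ppc": (100.0, 1), "cit": (85.0, 1), "kgd1": (115.0, 1), "lpd1": (55.0, 1),
    "sdh": (140.0, 1),
    "nda1": (400.0, 1), "cyc1": (250.0, 1), "atp1": (350.0, 1),
    "aox": (70.0, 1),
    "pdc": (60.0, 4), "adh": (37.5, 4),
}

# kcat in 1/s, keyed by original reaction id except the hexokinase isozymes,
# which carry per-copy values (post-split ids)
_MINICORE_KCATS = {
    "GLCt": 33.0, "HEX_num1": 45.0, "HEX_num2": 30.0,
    "CELt": 28.0, "CELH": 15.0, "CELP": 31.0, "PGMT": 50.0,
    "GALt": 36.0, "GAL1": 27.0, "GAL2": 29.0,
    "XYLt": 36.0, "XYL1": 22.0,
    "ARAt": 36.0, "ARA1": 13.0, "ARA2": 13.5,
    "PGI": 42.0, "PFK_ALD": 39.0, "GAPD_PGK": 25.0, "ENO": 33.0, "PYK": 38.0,
    "PDH": 74.0, "G6PDH": 31.0, "RPI": 17.0, "TKT": 17.0, "TAL": 13.0,
    "PPC": 37.0, "CS_IDH": 39.0, "AKGDH": 63.0, "SDH_MDH": 52.0,
    "OXPHOS_HY": 28.0, "OXPHOS_LY": 4.0,
    "PDC": 300.0, "ADH": 250.0,
}

_SUGARS = {
    "glucose": ("EX_glc_e", 6),
    "cellobiose": ("EX_cel_e", 12),
    "xylose": ("EX_xyl_e", 5),
    "galactose": ("EX_gal_e", 6),
    "arabinose": ("EX_ara_e", 5),
}

_DESIGNED_TIERS = [
    {"glucose", "cellobiose"},
    {"xylose", "galactose"},
    {"arabinose"},
]

_DESIGNED_TARGETS = {
    "enhance_reactions": ["PDC", "ADH"],
    "weaken_reactions": ["OXPHOS_LY", "CS_IDH", "AKGDH", "SDH_MDH"],
    "enhance_genes": ["pdc", "adh"],
}

#: glucose uptake (mmol/gDW/h) at which ethanol overflow begins on the
#: designed fixture; recorded from the design sweep
_DESIGNED_CRITICAL_UPTAKE = 3.9


def make_minicore():
    """The fixed central-carbon fixture.

    Returns ``(model, kcat_records, subunit_table, config)`` where the model
    is the *unsplit* reversible network, kcat_records is a list of
    :class:`KcatRecord`, subunit_table maps gene -> (mw_kda, count) and
    config carries the analysis designations (ATP metabolite, oxphos and
    overflow reaction sets, precursor list, sugar carbon counts, designed
    ground truth).
    """
    model = MetabolicModel(id="minicore", objective_reaction_id="BIOMASS")
    for mid, (name, comp, ccount) in _MINICORE_METS.items():
        model.metabolites.append(
            Metabolite(id=mid, name=name, compartment=comp, carbon_count=ccount)
        )
    for rid, name, stoich, lb, ub, gpr in _MINICORE_RXNS:
        model.reactions.append(
            Reaction(id=rid, name=name, stoichiometry=dict(stoich),
                     lower_bound=float(lb), upper_bound=float(ub), gpr=gpr)
        )
    for gene, (mw, count) in _MINICORE_SUBUNITS.items():
        model.genes.append(Gene(id=gene, protein=f"P_{gene}", mw_kda=mw * count))
    kcat_records = [
        KcatRecord(rid, val, "turnup_predicted") for rid, val in _MINICORE_KCATS.items()
    ]
    config = {
        "atp_metabolite_id": "atp_c",
        "oxphos_reaction_ids": {"OXPHOS_HY", "OXPHOS_LY"},
        "overflow_exchange_ids": {"EX_etoh_e"},
        "precursor_ids": list(_PRECURSORS),
        "substrates": {name: {"exchange": ex, "carbon_count": cc}
                       for name, (ex, cc) in _SUGARS.items()},
        "biomass_id": "BIOMASS",
        "product_exchange_id": "EX_etoh_e",
        "substrate_exchange_id": "EX_glc_e",
        "target_glucose_uptake": 5.0,
        "c13_glucose_uptake": 2.0,
        "substrate_mw": 0.180,  # g/mmol glucose
        "o2_exchange_id": "EX_o2_e",
        "c13_reaction_ids": ["PGI", "PFK_ALD", "GAPD_PGK", "ENO", "PYK",
                             "PDH", "CS_IDH", "AKGDH", "SDH_MDH", "PPC"],
        "ground_truth": GroundTruth(
            planted_f=DEFAULT_F,
            original_kcats=dict(_MINICORE_KCATS),
            designed_tiers=[set(t) for t in _DESIGNED_TIERS],
            designed_critical_uptake=_DESIGNED_CRITICAL_UPTAKE,
            designed_targets={k: list(v) for k, v in _DESIGNED_TARGETS.items()},
        ),
    }
    return model, kcat_records, dict(_MINICORE_SUBUNITS), config


def minicore_conditions(glucose: float = 0.0, cellobiose: float = 0.0,
                        xylose: float = 0.0, galactose: float = 0.0,
                        arabinose: float = 0.0, o2: float = 1000.0) -> dict:
    """Uptake-bound map for the minicore: all sugars closed unless opened."""
    return {
        "EX_glc_e": glucose, "EX_cel_e": cellobiose, "EX_xyl_e": xylose,
        "EX_gal_e": galactose, "EX_ara_e": arabinose, "EX_o2_e": o2,
    }


def make_minicore_ec(ptot: float = DEFAULT_PTOT, f: float = DEFAULT_F,
                     sigma: float = DEFAULT_SIGMA):
    """Full construction pipeline on the minicore.

    Splits reversible reactions, expands isozymes, attaches kcat/MW data and
    the pool constraint.  Returns ``(ec_model, config)``.
    """
    from .simulate import set_uptake

    model, kcat_records, subunits, config = make_minicore()
    split, sm = split_and_expand(model)
    kcats = merge_kcat(kcat_records, reactions=[], imputation="none")
    entries = build_enzyme_entries(split, kcats, subunits, split_map=sm,
                                   default_sigma=sigma)
    ec = build_ec_model(split, entries, ptot=ptot, f=f, split_map=sm)
    # study-condition defaults: all sugars closed, oxygen unlimited
    for exch, rate in minicore_conditions().items():
        set_uptake(ec, exch, rate)
    return ec, config


# ---------------------------------------------------------------------------
# random toy models
# ---------------------------------------------------------------------------

def make_random_toy(n_metabolites: int, n_reactions: int, seed: int) -> MetabolicModel:
    """A connected random toy model with a guaranteed positive FBA optimum.

    A substrate-to-biomass chain ensures feasibility; remaining reactions
    are random sparse conversions between interior metabolites.
    """
    if n_metabolites < 3 or n_reactions < n_metabolites + 1:
        raise ValueError(
            f"impossible sizes: need n_metabolites >= 3 and "
            f"n_reactions >= n_metabolites + 1, got {n_metabolites}/{n_reactions}"
        )
    rng = np.random.default_rng(seed)
    model = MetabolicModel(id=f"toy_{seed}", objective_reaction_id="BIOMASS")
    mets = [f"m{i}" for i in range(n_metabolites)]
    for mid in mets:
        model.metabolites.append(Metabolite(id=mid, name=mid, compartment="c"))
    model.reactions.append(
        Reaction(id="EX_sub", name="substrate exchange", stoichiometry={mets[0]: -1},
                 lower_bound=-10.0, upper_bound=1000.0)
    )
    for i in range(n_metabolites - 1):
        model.reactions.append(
            Reaction(id=f"R{i}", name=f"chain {i}",
                     stoichiometry={mets[i]: -1, mets[i + 1]: 1},
                     lower_bound=0.0, upper_bound=1000.0)
        )
    model.reactions.append(
        Reaction(id="BIOMASS", name="biomass drain",
                 stoichiometry={mets[-1]: -1}, lower_bound=0.0, upper_bound=1000.0)
    )
    extra = n_reactions - len(model.reactions)
    for k in range(extra):
        a, b = rng.choice(n_metabolites, size=2, replace=False)
        coef = float(np.round(rng.uniform(0.5, 2.0), 3))
        model.reactions.append(
            Reaction(id=f"X{k}", name=f"random conversion {k}",
                     stoichiometry={mets[a]: -1.0, mets[b]: coef},
                     lower_bound=0.0, upper_bound=1000.0)
        )
    return model


# ---------------------------------------------------------------------------
# synthetic proteomes, kcat perturbations, 13C-style flux tables
# ---------------------------------------------------------------------------

def synth_proteome(model: MetabolicModel, planted_f: float = DEFAULT_F,
                   n_extra_proteins: int = 200, seed: int = 0):
    """A proteome whose model-protein mass fraction is exactly ``planted_f``.

    Model proteins get random mole-ratio abundances; background proteins are
    scaled so the mass-fraction ratio recovers ``planted_f`` to machine
    precision.  Returns ``(records, ground_truth)``.
    """
    if not (0 < planted_f <= 1):
        raise ValueError("planted_f must be in (0, 1]")
    if planted_f == 1 and n_extra_proteins > 0:
        raise ValueError("planted_f = 1 is inconsistent with background proteins")
    if planted_f < 1 and n_extra_proteins == 0:
        raise ValueError("planted_f < 1 requires background proteins")
    rng = np.random.default_rng(seed)
    records = []
    model_mass = 0.0
    for gene in model.genes:
        mw = gene.mw_kda if gene.mw_kda else float(rng.uniform(20, 120))
        ab = float(rng.uniform(0.5, 2.0))
        records.append(ProteomicsRecord(gene.protein or gene.id, ab, mw))
        model_mass += ab * mw
    if model_mass <= 0:
        raise ValueError("model has no proteins to plant a proteome on")
    if n_extra_proteins:
        bg_mw = rng.uniform(20, 120, size=n_extra_proteins)
        bg_ab = rng.uniform(0.5, 2.0, size=n_extra_proteins)
        bg_mass = float(bg_ab @ bg_mw)
        scale = model_mass * (1.0 / planted_f - 1.0) / bg_mass
        for i in range(n_extra_proteins):
            records.append(
                ProteomicsRecord(f"BG_{i:04d}", float(bg_ab[i] * scale), float(bg_mw[i]))
            )
    return records, GroundTruth(planted_f=planted_f)


def perturb_kcats(ec: ECModel, factor: float, subset: Optional[Sequence[str]] = None,
                  seed: Optional[int] = None):
    """Multiply kcats by ``factor`` (default: all), recording the originals."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    out = ec.copy()
    targets = set(subset) if subset is not None else set(out.enzymes)
    gt = GroundTruth(original_kcats={rid: out.enzymes[rid].kcat for rid in sorted(targets)})
    for rid in targets:
        out.enzymes[rid].kcat *= factor
    return out, gt


def synth_c13_fluxes(ec: ECModel, conditions: Mapping[str, float],
                     noise_cv: float = 0.0, seed: int = 0,
                     reaction_ids: Optional[Sequence[str]] = None) -> list:
    """Noisy net-flux measurements emulating a 13C flux table.

    pFBA net fluxes of the designated central reactions are multiplied by
    unit-mean lognormal noise with coefficient of variation ``noise_cv``;
    relative tolerances are ``max(2*noise_cv, 0.05)``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    sol = pfba(with_conditions(ec, conditions))
    if not sol.ok:
        raise RuntimeError("model infeasible under the given conditions")
    net = net_fluxes(sol.fluxes, ec.split_map)
    if reaction_ids is None:
        reaction_ids = sorted(rid for rid, v in net.items() if abs(v) > 1e-6
                              and not rid.startswith("EX_"))
    rng = np.random.default_rng(seed)
    tol = max(2.0 * noise_cv, 0.05)
    out = []
    for rid in reaction_ids:
        v = net[rid]
        if noise_cv > 0:
            s2 = np.log1p(noise_cv ** 2)
            noise = float(rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2)))
        else:
            noise = 1.0
        out.append(FluxMeasurement(reaction_id=rid, measured_flux=v * noise, tolerance=tol))
    return out
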