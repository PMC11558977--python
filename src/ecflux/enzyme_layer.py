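"""Per-reaction enzyme data and the proteome pool constraint.

The enzyme-constrained model used throughout this package adds a single
linear row to an (irreversible, isozyme-expanded) stoichiometric model:

    sum_i  v_i * MW_i / (sigma_i * kcat_i)  <=  ptot * f

where ``v_i`` is the flux of reaction i (mmol/gDW/h), ``MW_i`` the molecular
weight of the catalysing enzyme complex (kDa = g/mmol), ``kcat_i`` its
turnover number and ``sigma_i`` the saturation coefficient (uniform 0.5 by
default).  ``ptot`` is the total protein mass per gram dry weight and ``f``
the fraction of that protein which is metabolic enzyme, estimated from
proteomics as a mass-fraction ratio (see :func:`enzyme_mass_fraction`).

kcat values are stored in 1/s and converted to 1/h (x3600) inside the
constraint, so the pool coefficient ``MW/(sigma*kcat*3600)`` has units
g.h/mmol and ``coefficient * flux`` is g enzyme per gDW.
"""

from __future__ import annotations

import copy
import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model_core import MetabolicModel, SplitMap, parse_gpr

__all__ = [
    "ProteomicsRecord",
    "KcatRecord",
    "EnzymeEntry",
    "ECModel",
    "KCAT_SOURCES",
    "DEFAULT_SOURCE_PRIORITY",
    "DEFAULT_PTOT",
    "DEFAULT_F",
    "DEFAULT_SIGMA",
    "enzyme_mass_fraction",
    "assemble_mw",
    "merge_kcat",
    "build_enzyme_entries",
    "build_ec_model",
    "enzyme_usage",
    "read_kcat_table",
    "read_subunit_table",
    "read_proteome_table",
    "write_ec_model",
    "read_ec_model",
]

logger = logging.getLogger(__name__)

KCAT_SOURCES = ("database", "dl_predicted", "turnup_predicted", "imputed", "calibrated")
#: measured database values outrank ML predictions; calibrated outranks everything
DEFAULT_SOURCE_PRIORITY = ("calibrated", "database", "turnup_predicted", "dl_predicted", "imputed")

DEFAULT_PTOT = 0.4653  # g total protein / gDW
DEFAULT_F = 0.55  # enzyme mass fraction of total protein
DEFAULT_SIGMA = 0.5  # uniform average saturation

_SECONDS_PER_HOUR = 3600.0


@dataclass
class ProteomicsRecord:
    """One protein in a quantitative proteome: mole-ratio abundance and MW (kDa)."""

    protein_id: str
    abundance: float
    mw: float

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"{self.protein_id}: abundance must be >= 0")
        if self.mw <= 0:
            raise ValueError(f"{self.protein_id}: mw must be > 0")


@dataclass
class KcatRecord:
    reaction_id: str
    value: float  # 1/s
    source: str = "database"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"kcat for {self.reaction_id} must be > 0, got {self.value}")
        if self.source not in KCAT_SOURCES:
            raise ValueError(f"unknown kcat source {self.source!r}")


@dataclass
class EnzymeEntry:
    """Enzyme data attached to one (post-split) reaction."""

    reaction_id: str
    complex: list  # [(gene_id, subunit_count, subunit_mw_kda), ...]
    kcat: float  # 1/s
    sigma: float = DEFAULT_SIGMA
    assembled_mw: float = None  # kDa; computed from the complex if omitted
    kcat_source: str = "database"

    def __post_init__(self) -> None:
        if self.assembled_mw is None:
            self.assembled_mw = assemble_mw(self.complex) if self.complex else 0.0
        if self.kcat <= 0:
            raise ValueError(f"{self.reaction_id}: kcat must be > 0")
        if not (0 < self.sigma <= 1):
            raise ValueError(f"{self.reaction_id}: sigma must be in (0, 1]")

    @property
    def pool_coefficient(self) -> float:
        """g.h/mmol: enzyme mass demanded per unit flux."""
        return self.assembled_mw / (self.sigma * self.kcat * _SECONDS_PER_HOUR)

    def gene_mass_share(self) -> dict:
        """Fraction of the complex mass contributed by each gene product."""
        if not self.complex or self.assembled_mw <= 0:
            return {}
        return {g: n * mw / self.assembled_mw for g, n, mw in self.complex}


@dataclass
class ECModel:
    """An irreversible, isozyme-expanded model plus the enzyme pool constraint."""

    base: MetabolicModel
    enzymes: dict = field(default_factory=dict)  # reaction_id -> EnzymeEntry
    ptot: float = DEFAULT_PTOT
    f: float = DEFAULT_F
    split_map: Optional[SplitMap] = None

    def __post_init__(self) -> None:
        if self.ptot * self.f <= 0:
            raise ValueError("pool bound ptot*f must be positive")
        rxn_ids = set(self.base.reaction_ids)
        for rid in self.enzymes:
            if rid not in rxn_ids:
                raise KeyError(f"enzyme entry for unknown reaction {rid!r}")

    @property
    def pool_bound(self) -> float:
        """Enzyme pool in g enzyme / gDW (= ptot * f)."""
        return self.ptot * self.f

    def pool_coefficients(self) -> dict:
        """Pool-row coefficient per reaction (0 for enzyme-free reactions)."""
        return {
            r.id: (self.enzymes[r.id].pool_coefficient if r.id in self.enzymes else 0.0)
            for r in self.base.reactions
        }

    def copy(self) -> "ECModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Eq. 1: enzyme mass fraction from proteomics
# ---------------------------------------------------------------------------

def enzyme_mass_fraction(
    proteome: Sequence[ProteomicsRecord], model_protein_ids: Iterable[str]
) -> float:
    """Mass fraction of the proteome covered by model proteins.

    ``sum(A_i * MW_i, i in model) / sum(A_j * MW_j, j in proteome)`` with
    mole-ratio abundances A and molecular weights MW.  Model proteins absent
    from the proteome are excluded from the numerator (logged).
    """
    if not proteome:
        raise ValueError("empty proteome")
    ids = set(model_protein_ids)
    present = {rec.protein_id for rec in proteome}
    missing = ids - present
    if missing:
        logger.info("proteome lacks %d model proteins (excluded from numerator)", len(missing))
    denom = sum(rec.abundance * rec.mw for rec in proteome)
    if denom <= 0:
        raise ValueError("total proteome mass is zero")
    numer = sum(rec.abundance * rec.mw for rec in proteome if rec.protein_id in ids)
    return numer / denom


def assemble_mw(complex: Sequence) -> float:
    """Molecular weight (kDa) of an enzyme complex: sum of count x subunit MW.

    Entries are ``(gene_id, subunit_count, subunit_mw)``; a missing (None)
    count defaults to 1 with a logged warning.
    """
    if not complex:
        raise ValueError("cannot assemble an empty complex")
    total = 0.0
    for gene_id, count, mw in complex:
        if count is None:
            logger.warning("no subunit count for %s; assuming 1", gene_id)
            count = 1
        if count < 1:
            raise ValueError(f"{gene_id}: subunit count must be >= 1")
        if mw <= 0:
            raise ValueError(f"{gene_id}: subunit MW must be > 0")
        total += count * mw
    return total


# ---------------------------------------------------------------------------
# kcat merging and imputation
# ---------------------------------------------------------------------------

def merge_kcat(
    records: Sequence[KcatRecord],
    source_priority: Sequence[str] = DEFAULT_SOURCE_PRIORITY,
    reactions: Sequence[str] = (),
    imputation: str = "median",
) -> dict:
    """Resolve one kcat per reaction by source priority, optionally imputing.

    Per reaction the record from the highest-priority source wins.  With
    ``imputation='median'`` reactions without any record receive the median
    of all kept values, tagged ``source='imputed'``; with ``'none'`` they are
    simply absent (their pool coefficient downstream is 0).
    """
    if imputation not in ("median", "none"):
        raise ValueError(f"unknown imputation mode {imputation!r}")
    rank = {s: i for i, s in enumerate(source_priority)}
    for rec in records:
        if rec.source not in rank:
            raise ValueError(f"source {rec.source!r} not covered by the priority order")
    kept: dict = {}
    for rec in records:
        cur = kept.get(rec.reaction_id)
        if cur is None or rank[rec.source] < rank[cur.source]:
            kept[rec.reaction_id] = rec
    if imputation == "median":
        if not kept:
            raise ValueError("no kcat records to impute a median from")
        med = statistics.median(rec.value for rec in kept.values())
        for rid in reactions:
            if rid not in kept:
                kept[rid] = KcatRecord(rid, med, "imputed")
    return kept


# ---------------------------------------------------------------------------
# building the EC model
# ---------------------------------------------------------------------------

def build_enzyme_entries(
    model: MetabolicModel,
    kcats: Mapping[str, KcatRecord],
    subunits: Mapping[str, tuple],
    split_map: Optional[SplitMap] = None,
    default_sigma: float = DEFAULT_SIGMA,
) -> dict:
    """Assemble :class:`EnzymeEntry` objects for every enzymatic reaction.

    ``subunits`` maps gene id to ``(subunit_mw_kda, subunit_count)``.  kcat
    lookup tries the post-split reaction id first, then falls back to the
    original reaction id via ``split_map`` (a record keyed by the original id
    applies to all its copies).  Reactions with an empty GPR, or without any
    kcat record, get no entry and stay outside the pool constraint.
    """
    entries: dict = {}
    for rxn in model.reactions:
        dnf = parse_gpr(rxn.gpr)
        if not dnf:
            continue
        if len(dnf) > 1:
            raise ValueError(
                f"reaction {rxn.id} still has {len(dnf)} isozymes; expand_isozymes first"
            )
        rec = kcats.get(rxn.id)
        if rec is None and split_map is not None:
            orig = split_map.copies.get(rxn.id, (None, 0))[0]
            if orig is not None:
                rec = kcats.get(orig)
        if rec is None:
            logger.info("no kcat for %s; excluded from the pool constraint", rxn.id)
            continue
        cplx = []
        for gene in sorted(dnf[0]):
            if gene not in subunits:
                logger.warning("gene %s has no subunit data; skipping reaction %s", gene, rxn.id)
                break
            mw, count = subunits[gene]
            cplx.append((gene, count, mw))
        else:
            entries[rxn.id] = EnzymeEntry(
                reaction_id=rxn.id,
                complex=cplx,
                kcat=rec.value,
                sigma=default_sigma,
                kcat_source=rec.source,
            )
    return entries


def build_ec_model(
    model: MetabolicModel,
    enzymes: Mapping[str, EnzymeEntry],
    ptot: float = DEFAULT_PTOT,
    f: float = DEFAULT_F,
    default_sigma: float = DEFAULT_SIGMA,
    split_map: Optional[SplitMap] = None,
) -> ECModel:
    """Attach the pool constraint to an irreversible, isozyme-expanded model."""
    for rxn in model.reactions:
        if rxn.lower_bound < 0:
            raise ValueError(
                f"reaction {rxn.id} has a negative lower bound; run to_irreversible first"
            )
    enzymes = dict(enzymes)
    for entry in enzymes.values():
        if entry.sigma is None:
            entry.sigma = default_sigma
    return ECModel(base=model.copy(), enzymes=enzymes, ptot=ptot, f=f, split_map=split_map)


def enzyme_usage(ec: ECModel, fluxes: Mapping[str, float]):
    """Per-reaction enzyme demand E_i = v_i*MW_i/(sigma_i*kcat_i*3600), and its sum.

    Fluxes must be non-negative (the EC model is irreversible).
    """
    usage = {}
    total = 0.0
    for rid, entry in ec.enzymes.items():
        v = fluxes.get(rid, 0.0)
        if v < -1e-9:
            raise ValueError(f"negative flux {v} on irreversible reaction {rid}")
        e = max(v, 0.0) * entry.pool_coefficient
        usage[rid] = e
        total += e
    return usage, total


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def read_kcat_table(path) -> list:
    """CSV/TSV with columns reaction_id, kcat_s, source -> list of KcatRecord."""
    df = _read_table(path)
    return [
        KcatRecord(str(row.reaction_id), float(row.kcat_s), str(row.source))
        for row in df.itertuples(index=False)
    ]


def read_subunit_table(path) -> dict:
    """CSV/TSV with columns gene_id, subunit_mw_kda, subunit_count -> gene map."""
    df = _read_table(path)
    out = {}
    for row in df.itertuples(index=False):
        count = int(row.subunit_count) if pd.notna(row.subunit_count) else None
        out[str(row.gene_id)] = (float(row.subunit_mw_kda), count)
    return out


def read_proteome_table(path) -> list:
    """CSV/TSV with columns protein_id, abundance_mole_ratio, mw_kda."""
    df = _read_table(path)
    return [
        ProteomicsRecord(str(row.protein_id), float(row.abundance_mole_ratio), float(row.mw_kda))
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# EC model serialization: COBRA JSON + enzyme annotation keys
# ---------------------------------------------------------------------------

def write_ec_model(ec: ECModel, path) -> None:
    """Serialize as COBRA-style JSON with per-reaction enzyme annotations."""
    from .io import write_model

    model = ec.base.copy()
    for rxn in model.reactions:
        entry = ec.enzymes.get(rxn.id)
        if entry is not None:
            rxn.annotation.update(
                kcat_s=entry.kcat,
                mw_kda=entry.assembled_mw,
                sigma=entry.sigma,
                kcat_source=entry.kcat_source,
                enzyme_complex=[[g, n, mw] for g, n, mw in entry.complex],
            )
    model.annotation["ptot"] = ec.ptot
    model.annotation["f"] = ec.f
    if ec.split_map is not None:
        sm = ec.split_map
        model.annotation["split_map"] = {
            "forward_of": sm.forward_of,
            "reverse_of": sm.reverse_of,
            "isozyme_copies": sm.isozyme_copies,
            "copies": {k: list(v) for k, v in sm.copies.items()},
        }
    write_model(model, path, format="cobra-json")


def read_ec_model(path) -> ECModel:
    from .io import read_model

    model = read_model(path, format="cobra-json")
    ptot = model.annotation.pop("ptot", DEFAULT_PTOT)
    f = model.annotation.pop("f", DEFAULT_F)
    sm_doc = model.annotation.pop("split_map", None)
    split_map = None
    if sm_doc is not None:
        split_map = SplitMap(
            forward_of=sm_doc["forward_of"],
            reverse_of=sm_doc["reverse_of"],
            isozyme_copies=sm_doc["isozyme_copies"],
            copies={k: (v[0], int(v[1])) for k, v in sm_doc["copies"].items()},
        )
    enzymes = {}
    for rxn in model.reactions:
        ann = rxn.annotation
        if "kcat_s" in ann:
            cplx = [(g, int(n), float(mw)) for g, n, mw in ann.pop("enzyme_complex", [])]
            enzymes[rxn.id] = EnzymeEntry(
                reaction_id=rxn.id,
                complex=cplx,
                kcat=float(ann.pop("kcat_s")),
                sigma=float(ann.pop("sigma", DEFAULT_SIGMA)),
                assembled_mw=float(ann.pop("mw_kda")),
                kcat_source=ann.pop("kcat_source", "database"),
            )
    return ECModel(base=model, enzymes=enzymes, ptot=ptot, f=f, split_map=split_map)
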