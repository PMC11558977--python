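"""Constraint-based model data structures and structural transformations.

The in-memory containers here are deliberately lightweight: a stoichiometric
network is a list of metabolites, a list of reactions (each a sparse
stoichiometry map plus flux bounds and a gene-protein-reaction rule), a gene
table and one designated objective reaction.  Two structural transformations
prepare a network for enzyme-constraint integration:

* :func:`to_irreversible` — every reversible reaction is replaced by a
  forward/reverse pair of irreversible reactions, so that each direction can
  carry its own enzyme cost.
* :func:`expand_isozymes` — a reaction catalysed by alternative enzymes
  (an ``or`` in its GPR) is duplicated into one copy per isozyme, each with a
  single ``and``-complex, so that each copy can carry that complex's kcat and
  molecular weight.

A :class:`SplitMap` records how split/expanded reaction ids map back to the
original network, which is what lets solutions be reported as net fluxes of
the original reactions.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "Metabolite",
    "Reaction",
    "Gene",
    "MetabolicModel",
    "SplitMap",
    "GPRError",
    "parse_gpr",
    "gpr_to_string",
    "to_irreversible",
    "expand_isozymes",
    "split_and_expand",
    "net_fluxes",
    "validate_model",
    "carbon_count_from_formula",
]

_MAX_DNF_CONJUNCTS = 64

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_count_from_formula(formula: str) -> int:
    """Number of carbon atoms implied by a chemical formula string."""
    total = 0
    for element, count in _ELEMENT_RE.findall(formula or ""):
        if element == "C":
            total += int(count) if count else 1
    return total


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    carbon_count: Optional[int] = None
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.carbon_count is not None and self.carbon_count < 0:
            raise ValueError(f"metabolite {self.id}: carbon_count must be >= 0")


@dataclass
class Reaction:
    """A (possibly reversible) reaction with flux bounds in mmol/gDW/h.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``gpr`` is a boolean gene rule string using ``and``/``or``
    and parentheses; the empty string means "no enzyme associated".
    """

    id: str
    name: str = ""
    stoichiometry: dict = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""
    subsystem: Optional[str] = None
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stoichiometry = {m: float(c) for m, c in self.stoichiometry.items()}
        self.lower_bound = float(self.lower_bound)
        self.upper_bound = float(self.upper_bound)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Exchanges are identified structurally: single-metabolite stoichiometry."""
        return len(self.stoichiometry) == 1

    def genes(self) -> set:
        try:
            return {g for conj in parse_gpr(self.gpr) for g in conj}
        except GPRError:
            return set()


@dataclass
class Gene:
    id: str
    protein: Optional[str] = None
    mw_kda: Optional[float] = None


class GPRError(ValueError):
    """Raised when a gene-protein-reaction rule cannot be parsed."""


def _tokenize_gpr(expr: str) -> list:
    tokens = []
    for tok in re.findall(r"\(|\)|[^\s()]+", expr):
        low = tok.lower()
        if low in ("and", "or"):
            tokens.append(low)
        else:
            tokens.append(tok)
    return tokens


def parse_gpr(expr: str) -> list:
    """Parse a GPR rule into disjunctive normal form.

    Returns a list of conjuncts, each a sorted tuple of gene ids; one
    conjunct per isozyme.  The empty rule parses to an empty list.
    ``and``/``or`` are case-insensitive and parentheses are honoured.  DNF
    expansion is capped at 64 conjuncts to avoid combinatorial blow-up.
    """
    expr = (expr or "").strip()
    if not expr:
        return []
    tokens = _tokenize_gpr(expr)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() == "or":
            pos += 1
            terms.append(parse_and())
        # DNF union
        out = []
        for t in terms:
            out.extend(t)
        return out

    def parse_and():
        nonlocal pos
        factors = [parse_atom()]
        while peek() == "and":
            pos += 1
            factors.append(parse_atom())
        # DNF product: cross every conjunct with every other
        result = [frozenset()]
        for f in factors:
            result = [a | b for a in result for b in f]
            if len(result) > _MAX_DNF_CONJUNCTS:
                raise GPRError(f"GPR rule expands beyond {_MAX_DNF_CONJUNCTS} conjuncts: {expr!r}")
        return result

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRError(f"unexpected end of GPR rule: {expr!r}")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise GPRError(f"unbalanced parenthesis in GPR rule: {expr!r}")
            pos += 1
            return inner
        if tok in (")", "and", "or"):
            raise GPRError(f"unexpected token {tok!r} in GPR rule: {expr!r}")
        pos += 1
        return [frozenset([tok])]

    dnf = parse_or()
    if pos != len(tokens):
        raise GPRError(f"trailing tokens in GPR rule: {expr!r}")
    if len(dnf) > _MAX_DNF_CONJUNCTS:
        raise GPRError(f"GPR rule expands beyond {_MAX_DNF_CONJUNCTS} conjuncts: {expr!r}")
    # deterministic order: by sorted gene tuple, preserving first-appearance order
    seen = []
    for conj in dnf:
        tup = tuple(sorted(conj))
        if tup not in seen:
            seen.append(tup)
    return seen


def gpr_to_string(dnf: Sequence[Sequence[str]]) -> str:
    parts = []
    for conj in dnf:
        if len(conj) == 1:
            parts.append(conj[0])
        else:
            parts.append("(" + " and ".join(conj) + ")")
    return " or ".join(parts)


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, GPR rules and an objective."""

    metabolites: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    objective_reaction_id: str = ""
    id: str = "model"
    annotation: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite {mid!r} in model {self.id}")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id}")

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites]

    def exchanges(self) -> list:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def stoichiometric_matrix(self):
        """Dense S matrix (|metabolites| x |reactions|) as a numpy array."""
        import numpy as np

        mindex = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                S[mindex[mid], j] = float(coef)
        return S


@dataclass
class SplitMap:
    """Bookkeeping from original reaction ids to split/expanded copies.

    ``forward_of``/``reverse_of`` record the direction split; ``isozyme_copies``
    records the isozyme expansion.  ``copies`` is the composed view used by
    :func:`net_fluxes`: every final reaction id maps to ``(original_id, sign)``
    where sign is -1 for reverse-direction copies.
    """

    forward_of: dict = field(default_factory=dict)
    reverse_of: dict = field(default_factory=dict)
    isozyme_copies: dict = field(default_factory=dict)
    copies: dict = field(default_factory=dict)

    @classmethod
    def identity(cls, model: MetabolicModel) -> "SplitMap":
        sm = cls()
        for r in model.reactions:
            sm.forward_of[r.id] = r.id
            sm.reverse_of[r.id] = None
            sm.isozyme_copies[r.id] = [r.id]
            sm.copies[r.id] = (r.id, 1)
        return sm

    def original_of(self, split_id: str) -> str:
        return self.copies[split_id][0]

    def copies_of(self, original_id: str):
        """All final copies of an original reaction as (split_id, sign) pairs."""
        return [(sid, sign) for sid, (oid, sign) in self.copies.items() if oid == original_id]

    def compose(self, later: "SplitMap") -> "SplitMap":
        """Composition: ``self`` maps A->B ids, ``later`` maps B->C ids."""
        out = SplitMap()
        for orig, fwd in self.forward_of.items():
            out.forward_of[orig] = later.forward_of.get(fwd, fwd)
        for orig, rev in self.reverse_of.items():
            out.reverse_of[orig] = later.forward_of.get(rev, rev) if rev is not None else None
        for orig in self.forward_of:
            mids = [self.forward_of[orig]]
            if self.reverse_of.get(orig):
                mids.append(self.reverse_of[orig])
            finals = []
            for mid in mids:
                finals.extend(later.isozyme_copies.get(mid, [mid]))
            out.isozyme_copies[orig] = finals
        for cid, (mid, sign) in later.copies.items():
            oid, sign0 = self.copies[mid]
            out.copies[cid] = (oid, sign * sign0)
        return out


def to_irreversible(model: MetabolicModel):
    """Split reversible reactions into forward/reverse irreversible pairs.

    A reaction with bounds ``(lb, ub)`` and ``lb < 0`` becomes a forward copy
    with bounds ``[max(0, lb'), ub]`` (``lb'`` clipped to 0) and a reverse copy
    ``<id>_reverse`` with negated stoichiometry and bounds ``[0, -lb]``.
    Already-irreversible reactions pass through unchanged, which makes the
    operation idempotent.  Returns ``(new_model, split_map)``.
    """
    out = model.copy()
    out.reactions = []
    sm = SplitMap()
    for rxn in model.reactions:
        fwd = copy.deepcopy(rxn)
        if rxn.lower_bound < 0:
            fwd.lower_bound = 0.0
            rev = copy.deepcopy(rxn)
            rev.id = rxn.id + "_reverse"
            rev.name = (rxn.name + " (reverse)") if rxn.name else rev.id
            rev.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
            rev.lower_bound = 0.0
            rev.upper_bound = -rxn.lower_bound
            out.reactions.append(fwd)
            out.reactions.append(rev)
            sm.reverse_of[rxn.id] = rev.id
            sm.copies[rev.id] = (rxn.id, -1)
        else:
            out.reactions.append(fwd)
            sm.reverse_of[rxn.id] = None
        sm.forward_of[rxn.id] = fwd.id
        sm.isozyme_copies[rxn.id] = [fwd.id]
        sm.copies[fwd.id] = (rxn.id, 1)
    return out, sm


def expand_isozymes(model: MetabolicModel):
    """Duplicate each multi-isozyme reaction into one copy per isozyme.

    A reaction whose GPR is an ``or`` of k conjuncts becomes k reactions
    ``<id>_num1 .. <id>_numk`` with identical stoichiometry and bounds, each
    carrying a single ``and``-complex.  Single-conjunct and enzyme-free
    reactions pass through unchanged (idempotence).  Returns
    ``(new_model, split_map)``.
    """
    out = model.copy()
    out.reactions = []
    sm = SplitMap()
    for rxn in model.reactions:
        try:
            dnf = parse_gpr(rxn.gpr)
        except GPRError as exc:
            raise GPRError(f"reaction {rxn.id}: {exc}") from exc
        sm.forward_of[rxn.id] = rxn.id
        sm.reverse_of[rxn.id] = None
        if len(dnf) <= 1:
            out.reactions.append(copy.deepcopy(rxn))
            sm.isozyme_copies[rxn.id] = [rxn.id]
            sm.copies[rxn.id] = (rxn.id, 1)
            continue
        cids = []
        for j, conj in enumerate(dnf, start=1):
            cp = copy.deepcopy(rxn)
            cp.id = f"{rxn.id}_num{j}"
            cp.gpr = gpr_to_string([conj])
            out.reactions.append(cp)
            cids.append(cp.id)
            sm.copies[cp.id] = (rxn.id, 1)
        sm.isozyme_copies[rxn.id] = cids
        sm.forward_of[rxn.id] = cids[0]
    return out, sm


def split_and_expand(model: MetabolicModel):
    """Direction split followed by isozyme expansion, with the composed map."""
    irr, sm1 = to_irreversible(model)
    exp, sm2 = expand_isozymes(irr)
    return exp, sm1.compose(sm2)


def net_fluxes(fluxes: Mapping[str, float], split_map: SplitMap) -> dict:
    """Fold split-model fluxes back onto the original reactions.

    Net flux of an original reaction = sum of its forward-copy fluxes minus
    the sum of its reverse-copy fluxes.
    """
    net: dict = {oid: 0.0 for oid, _ in split_map.copies.values()}
    for sid, v in fluxes.items():
        if sid not in split_map.copies:
            raise KeyError(f"flux for unknown split reaction {sid!r}")
        oid, sign = split_map.copies[sid]
        net[oid] += sign * v
    return net


def validate_model(model: MetabolicModel) -> list:
    """Structural findings: dangling references, inverted bounds, duplicates.

    Returns a list of human-readable finding strings (prefixed with a short
    code); the list is empty iff the model invariants hold.
    """
    findings = []
    met_ids = [m.id for m in model.metabolites]
    met_set = set(met_ids)
    if len(met_ids) != len(met_set):
        dups = sorted({m for m in met_ids if met_ids.count(m) > 1})
        findings.append(f"duplicate-metabolite: {', '.join(dups)}")
    rxn_ids = [r.id for r in model.reactions]
    if len(rxn_ids) != len(set(rxn_ids)):
        dups = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        findings.append(f"duplicate-reaction: {', '.join(dups)}")
    gene_ids = [g.id for g in model.genes]
    gene_set = set(gene_ids)
    if len(gene_ids) != len(gene_set):
        dups = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        findings.append(f"duplicate-gene: {', '.join(dups)}")
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            findings.append(
                f"inverted-bounds: {rxn.id} has lb={rxn.lower_bound} > ub={rxn.upper_bound}"
            )
        for mid, coef in rxn.stoichiometry.items():
            if mid not in met_set:
                findings.append(f"dangling-metabolite: {rxn.id} references {mid}")
            if coef == 0:
                findings.append(f"zero-coefficient: {rxn.id} has zero coefficient for {mid}")
        try:
            for conj in parse_gpr(rxn.gpr):
                for g in conj:
                    if g not in gene_set:
                        findings.append(f"dangling-gene: {rxn.id} references {g}")
        except GPRError as exc:
            findings.append(f"gpr-parse: {exc}")
    if model.objective_reaction_id and model.objective_reaction_id not in set(rxn_ids):
        findings.append(f"missing-objective: {model.objective_reaction_id}")
    for met in model.metabolites:
        if met.carbon_count is not None and met.formula:
            implied = carbon_count_from_formula(met.formula)
            if implied != met.carbon_count:
                findings.append(
                    f"carbon-mismatch: {met.id} declares {met.carbon_count} C, formula implies {implied}"
                )
    return findings
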