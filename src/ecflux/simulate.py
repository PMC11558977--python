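"""LP-based solvers for plain and enzyme-constrained models.

All solvers share one formulation: steady-state mass balance ``S v = 0``,
flux bounds, and (for an :class:`~ecflux.enzyme_layer.ECModel`) the single
enzyme-pool row ``sum_i c_i v_i <= pool_bound`` with
``c_i = MW_i/(sigma_i*kcat_i*3600)``.  LPs are solved with scipy's HiGHS
backend, which is deterministic for a fixed variable ordering (the model's
reaction order).

Flux variability analysis follows the modified aggregation used for
enzyme-constrained models: the variability of a reaction split into isozyme
copies is the maximal range over the copies, and the variability of an
originally reversible reaction is the forward-direction range minus the
reverse-direction range (clamped at zero).  A net-flux variant
(``max(v_fwd - v_rev) - min(v_fwd - v_rev)``) is available as
``method="net"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linprog

from .enzyme_layer import ECModel, enzyme_usage
from .model_core import MetabolicModel, SplitMap

__all__ = [
    "FluxSolution",
    "VariabilityRange",
    "fba",
    "pfba",
    "min_enzyme_solution",
    "fva_raw",
    "aggregate_variability",
    "fva",
    "phpp",
    "set_uptake",
    "with_conditions",
    "alternative_optima",
]

FEAS_TOL = 1e-9  # requested from the solver
ASSERT_TOL = 1e-6  # asserted on returned solutions

AnyModel = Union[MetabolicModel, ECModel]


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float = 0.0
    fluxes: dict = field(default_factory=dict)
    enzyme_usage: dict = field(default_factory=dict)
    pool_utilization: float = 0.0

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class VariabilityRange:
    reaction_id: str
    v_min: float
    v_max: float
    fv: float


def _base_of(model: AnyModel) -> MetabolicModel:
    return model.base if isinstance(model, ECModel) else model


def _pool_of(model: AnyModel):
    """(coefficient vector, bound) of the pool row, or (None, None)."""
    if not isinstance(model, ECModel):
        return None, None
    base = model.base
    coefs = model.pool_coefficients()
    vec = np.array([coefs[r.id] for r in base.reactions])
    return vec, model.pool_bound


class _LP:
    """Shared LP scaffolding for one model: S matrix, bounds, pool row."""

    def __init__(self, model: AnyModel):
        self.model = model
        self.base = _base_of(model)
        self.index = {r.id: j for j, r in enumerate(self.base.reactions)}
        self.n = len(self.base.reactions)
        self.S = self.base.stoichiometric_matrix()
        self.bounds = [(r.lower_bound, r.upper_bound) for r in self.base.reactions]
        self.pool_vec, self.pool_bound = _pool_of(model)

    def objective_vector(self, objective_id: Optional[str]) -> np.ndarray:
        rid = objective_id or self.base.objective_reaction_id
        if rid not in self.index:
            raise KeyError(f"objective reaction {rid!r} not in model")
        c = np.zeros(self.n)
        c[self.index[rid]] = 1.0
        return c

    def solve(
        self,
        c: np.ndarray,
        maximize: bool = True,
        bounds=None,
        extra_ub: Sequence = (),
        extra_eq: Sequence = (),
    ):
        """Optimize ``c.v`` subject to Sv=0, bounds, pool, and extra rows.

        ``extra_ub``/``extra_eq`` are (row, rhs) pairs over the flux vector.
        Returns (status, x, objective_value) with the objective on the
        requested (max/min) sense.
        """
        A_ub_rows, b_ub = [], []
        if self.pool_vec is not None:
            A_ub_rows.append(self.pool_vec)
            b_ub.append(self.pool_bound)
        for row, rhs in extra_ub:
            A_ub_rows.append(row)
            b_ub.append(rhs)
        A_eq_rows = [self.S]
        b_eq = [np.zeros(self.S.shape[0])]
        for row, rhs in extra_eq:
            A_eq_rows.append(np.atleast_2d(row))
            b_eq.append(np.atleast_1d(rhs))
        res = linprog(
            c=-c if maximize else c,
            A_ub=np.vstack(A_ub_rows) if A_ub_rows else None,
            b_ub=np.array(b_ub) if b_ub else None,
            A_eq=np.vstack(A_eq_rows),
            b_eq=np.concatenate(b_eq),
            bounds=bounds if bounds is not None else self.bounds,
            method="highs",
            options={"primal_feasibility_tolerance": FEAS_TOL,
                     "dual_feasibility_tolerance": FEAS_TOL},
        )
        if res.status == 0:
            obj = float(c @ res.x)
            return "optimal", res.x, obj
        if res.status == 2:
            return "infeasible", None, np.nan
        if res.status == 3:
            return "unbounded", None, np.inf if maximize else -np.inf
        return "infeasible", None, np.nan

    def solution(self, status: str, x, objective_value: float) -> FluxSolution:
        if x is None:
            return FluxSolution(status=status, objective_value=objective_value)
        fluxes = {r.id: float(v) for r, v in zip(self.base.reactions, x)}
        usage, total, util = {}, 0.0, 0.0
        if isinstance(self.model, ECModel):
            usage, total = enzyme_usage(self.model, fluxes)
            util = total / self.model.pool_bound
        return FluxSolution(
            status=status,
            objective_value=float(objective_value),
            fluxes=fluxes,
            enzyme_usage=usage,
            pool_utilization=util,
        )


# ---------------------------------------------------------------------------
# core solvers
# ---------------------------------------------------------------------------

def fba(model: AnyModel, objective_id: Optional[str] = None, direction: str = "max") -> FluxSolution:
    """Flux balance analysis: optimize one reaction's flux.

    Infeasibility/unboundedness is reported in ``status``, not raised.
    """
    lp = _LP(model)
    c = lp.objective_vector(objective_id)
    status, x, obj = lp.solve(c, maximize=(direction == "max"))
    return lp.solution(status, x, obj)


def _min_total_flux_at(lp: _LP, c_obj: np.ndarray, optimum: float) -> FluxSolution:
    """Stage 2 of pFBA: minimize sum |v| with the objective held at its optimum.

    Absolute values enter through auxiliary variables t_i >= |v_i| so that
    the original flux bounds are kept untouched.
    """
    n = lp.n
    big = [max(abs(lb), abs(ub)) for lb, ub in lp.bounds]
    # variables: [v (n), t (n)]
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = [np.hstack([lp.S, np.zeros_like(lp.S)])]
    b_eq = [np.zeros(lp.S.shape[0])]
    # hold the primary objective (>= optimum for max sense; tiny relaxation
    # absorbs stage-1 solver tolerance)
    hold = np.concatenate([-c_obj, np.zeros(n)])
    A_ub = [hold]
    b_ub = [-(optimum - 1e-9)]
    if lp.pool_vec is not None:
        A_ub.append(np.concatenate([lp.pool_vec, np.zeros(n)]))
        b_ub.append(lp.pool_bound)
    # t - v >= 0 and t + v >= 0
    eye = np.eye(n)
    A_ub.append(np.hstack([eye, -eye]))
    b_ub.extend(np.zeros(n))
    A_ub.append(np.hstack([-eye, -eye]))
    b_ub.extend(np.zeros(n))
    bounds = list(lp.bounds) + [(0.0, b) for b in big]
    res = linprog(
        c=c,
        A_ub=np.vstack(A_ub),
        b_ub=np.array(b_ub, dtype=float).ravel() if np.ndim(b_ub) else np.array(b_ub),
        A_eq=np.vstack(A_eq),
        b_eq=np.concatenate(b_eq),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEAS_TOL,
                 "dual_feasibility_tolerance": FEAS_TOL},
    )
    if res.status != 0:
        return lp.solution("infeasible", None, np.nan)
    x = res.x[:n]
    sol = lp.solution("optimal", x, float(c_obj @ x))
    return sol


def pfba(model: AnyModel, objective_id: Optional[str] = None) -> FluxSolution:
    """Parsimonious FBA: maximize the objective, then minimize total |flux|.

    Implemented as a lexicographic two-stage LP so the primary optimum is
    preserved exactly (to solver tolerance).
    """
    lp = _LP(model)
    c = lp.objective_vector(objective_id)
    status, x, obj = lp.solve(c, maximize=True)
    if status != "optimal":
        return lp.solution(status, x, obj)
    return _min_total_flux_at(lp, c, obj)


def min_enzyme_solution(ec: ECModel, fixed: Mapping[str, float]) -> FluxSolution:
    """Minimize total enzyme usage subject to fixed fluxes.

    ``objective_value`` of the returned solution is E_min (g enzyme/gDW).
    """
    lp = _LP(ec)
    bounds = list(lp.bounds)
    for rid, val in fixed.items():
        if rid not in lp.index:
            raise KeyError(f"cannot fix unknown reaction {rid!r}")
        bounds[lp.index[rid]] = (val, val)
    c = lp.pool_vec.copy()
    status, x, obj = lp.solve(c, maximize=False, bounds=bounds)
    return lp.solution(status, x, obj)


def alternative_optima(
    model: AnyModel,
    objective_id: Optional[str] = None,
    n_samples: int = 20,
    seed: int = 0,
) -> list:
    """Alternative optimal flux vectors via random secondary objectives.

    The primary objective is held at its optimum while a random linear
    secondary objective is optimized; used as a sampling oracle for pFBA
    minimality checks.
    """
    lp = _LP(model)
    c = lp.objective_vector(objective_id)
    status, x, obj = lp.solve(c, maximize=True)
    if status != "optimal":
        return []
    rng = np.random.default_rng(seed)
    out = []
    hold_row = (-c, -(obj - 1e-9))
    for _ in range(n_samples):
        w = rng.uniform(-1.0, 1.0, size=lp.n)
        st, xs, _ = lp.solve(w, maximize=False, extra_ub=[hold_row])
        if st == "optimal":
            out.append(lp.solution("optimal", xs, float(c @ xs)))
    return out


# ---------------------------------------------------------------------------
# flux variability
# ---------------------------------------------------------------------------

def fva_raw(
    model: AnyModel,
    reaction_ids: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 1.0,
) -> dict:
    """Per-reaction (min, max) flux at >= fraction_of_optimum of the objective."""
    lp = _LP(model)
    c = lp.objective_vector(None)
    status, x, obj = lp.solve(c, maximize=True)
    if status != "optimal":
        raise RuntimeError(f"FVA base problem is {status}")
    hold = [(-c, -(fraction_of_optimum * obj - 1e-9))]
    targets = list(reaction_ids) if reaction_ids is not None else [r.id for r in lp.base.reactions]
    out = {}
    for rid in targets:
        if rid not in lp.index:
            raise KeyError(f"unknown reaction {rid!r}")
        e = np.zeros(lp.n)
        e[lp.index[rid]] = 1.0
        _, _, vmin = lp.solve(e, maximize=False, extra_ub=hold)
        _, _, vmax = lp.solve(e, maximize=True, extra_ub=hold)
        out[rid] = (float(vmin), float(vmax))
    return out


def aggregate_variability(raw: Mapping[str, tuple], split_map: SplitMap) -> list:
    """Fold per-copy FVA ranges onto original reactions.

    Within a direction, isozyme copies aggregate by the maximal range; for
    an originally reversible reaction the reverse-direction range is
    subtracted from the forward one and the result clamped at zero.
    """
    by_orig: dict = {}
    for sid, (oid, sign) in split_map.copies.items():
        by_orig.setdefault(oid, {1: [], -1: []})[sign].append(sid)
    out = []
    for oid in sorted(by_orig):
        fwd_ids = by_orig[oid][1]
        rev_ids = by_orig[oid][-1]
        for sid in fwd_ids + rev_ids:
            if sid not in raw:
                raise KeyError(f"FVA range missing for split reaction {sid!r}")

        def _direction_range(ids):
            # maximal range over isozyme copies; representative bounds from
            # the copy attaining it
            best = max(ids, key=lambda s: raw[s][1] - raw[s][0])
            return raw[best][0], raw[best][1]

        vmin, vmax = _direction_range(fwd_ids)
        fv = vmax - vmin
        if rev_ids:
            rmin, rmax = _direction_range(rev_ids)
            fv = fv - (rmax - rmin)
            if fv < 0:
                fv = 0.0
        out.append(VariabilityRange(reaction_id=oid, v_min=vmin, v_max=vmax, fv=fv))
    return out


def fva(
    model: AnyModel,
    split_map: SplitMap,
    reaction_ids: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 1.0,
    method: str = "verbatim",
) -> list:
    """FVA on a split model, aggregated to original reactions.

    ``method="verbatim"`` applies the max-isozyme-range / forward-minus-
    reverse rules; ``method="net"`` optimizes the net flux
    ``sum(forward copies) - sum(reverse copies)`` directly.
    """
    if method == "verbatim":
        raw = fva_raw(model, None, fraction_of_optimum)
        ranges = aggregate_variability(raw, split_map)
        if reaction_ids is not None:
            keep = set(reaction_ids)
            ranges = [r for r in ranges if r.reaction_id in keep]
        return ranges
    if method != "net":
        raise ValueError(f"unknown FVA method {method!r}")
    lp = _LP(model)
    c = lp.objective_vector(None)
    status, x, obj = lp.solve(c, maximize=True)
    if status != "optimal":
        raise RuntimeError(f"FVA base problem is {status}")
    hold = [(-c, -(fraction_of_optimum * obj - 1e-9))]
    origs = sorted({oid for oid, _ in split_map.copies.values()})
    if reaction_ids is not None:
        keep = set(reaction_ids)
        origs = [o for o in origs if o in keep]
    out = []
    for oid in origs:
        w = np.zeros(lp.n)
        for sid, sign in split_map.copies_of(oid):
            if sid in lp.index:
                w[lp.index[sid]] += sign
        _, _, vmin = lp.solve(w, maximize=False, extra_ub=hold)
        _, _, vmax = lp.solve(w, maximize=True, extra_ub=hold)
        out.append(VariabilityRange(oid, float(vmin), float(vmax), float(vmax - vmin)))
    return out


# ---------------------------------------------------------------------------
# uptake conditions and phenotype phase plane
# ---------------------------------------------------------------------------

def set_uptake(model: AnyModel, exchange_id: str, rate: float,
               split_map: Optional[SplitMap] = None) -> None:
    """Set the maximal uptake of an exchange reaction, in place.

    On an unsplit model uptake is a negative exchange flux, so the lower
    bound becomes ``-rate``.  On a split model the uptake direction is the
    ``_reverse`` copy, whose upper bound becomes ``rate``.
    """
    if rate < 0:
        raise ValueError("uptake rate must be >= 0")
    if isinstance(model, ECModel):
        sm = split_map or model.split_map
        base = model.base
    else:
        sm = split_map
        base = model
    ids = set(base.reaction_ids)
    if exchange_id in ids and base.reaction(exchange_id).lower_bound < 0:
        base.reaction(exchange_id).lower_bound = -rate
        return
    rev = None
    if sm is not None:
        rev = sm.reverse_of.get(exchange_id)
    if rev is None and exchange_id + "_reverse" in ids:
        rev = exchange_id + "_reverse"
    if rev is None or rev not in ids:
        raise KeyError(f"no uptake direction found for exchange {exchange_id!r}")
    rxn = base.reaction(rev)
    rxn.lower_bound = 0.0
    rxn.upper_bound = rate


def with_conditions(model: AnyModel, conditions: Mapping[str, float]) -> AnyModel:
    """Copy of the model with uptake bounds applied (exchange id -> max uptake)."""
    out = model.copy()
    for exch, rate in conditions.items():
        set_uptake(out, exch, rate)
    return out


def phpp(
    model: AnyModel,
    substrate_exchange_id: str,
    substrate_range: tuple = (0.0, 10.0),
    o2_exchange_id: str = "EX_o2_e",
    o2_range: tuple = (0.0, 50.0),
    steps: Union[int, tuple] = 21,
    objective_id: Optional[str] = None,
) -> tuple:
    """Phenotype phase plane: pFBA growth over a substrate x O2 uptake grid.

    Returns ``(substrate_rates, o2_rates, growth)`` where ``growth`` has
    shape ``(len(substrate_rates), len(o2_rates))``; infeasible cells are 0.
    """
    ns, no = (steps, steps) if isinstance(steps, int) else steps
    sub_rates = np.linspace(substrate_range[0], substrate_range[1], ns)
    o2_rates = np.linspace(o2_range[0], o2_range[1], no)
    growth = np.zeros((ns, no))
    for i, su in enumerate(sub_rates):
        for j, o2 in enumerate(o2_rates):
            m = with_conditions(model, {substrate_exchange_id: su, o2_exchange_id: o2})
            sol = pfba(m, objective_id)
            growth[i, j] = sol.objective_value if sol.ok else 0.0
    return sub_rates, o2_rates, growth
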