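"""Iterative kcat calibration.

Predicted turnover numbers are systematically underestimated for some
reactions, which over-constrains the enzyme pool and depresses predicted
growth and central fluxes.  Two relaxation procedures are provided, both of
which only ever *increase* kcats:

* :func:`calibrate_enzyme_usage` — while predicted growth falls short of the
  measured rate, the reaction holding the largest share of the enzyme pool
  has its kcat multiplied by a fixed factor.
* :func:`calibrate_c13` — while a predicted net flux falls short of its
  measured value beyond tolerance, the enzyme-cost-dominant split copy of
  that reaction is relaxed the same way.

Both terminate on convergence, an iteration cap, or stagnation (no progress
over three consecutive steps), and return a complete step log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .enzyme_layer import ECModel
from .model_core import SplitMap, net_fluxes
from .simulate import pfba, with_conditions

__all__ = [
    "CalibrationStep",
    "FluxMeasurement",
    "calibrate_enzyme_usage",
    "calibrate_c13",
    "KCAT_CAP",
]

#: upper cap for any calibrated kcat (1/s); prevents runaway relaxation
KCAT_CAP = 1e6

_EPS_FLUX = 1e-6  # mmol/gDW/h; guards relative-error division
_STAGNATION_STEPS = 3
_STAGNATION_TOL = 1e-9


@dataclass
class CalibrationStep:
    iteration: int
    reaction_id: str
    old_kcat: float
    new_kcat: float
    criterion: str  # enzyme_usage | c13_consistency
    metric_after: float  # growth (1/h) or max relative flux error
    converged: bool = False
    stagnated: bool = False


def _solve_growth(ec: ECModel, conditions: Mapping[str, float]):
    sol = pfba(with_conditions(ec, conditions))
    return sol


def calibrate_enzyme_usage(
    ec: ECModel,
    target_growth: float,
    conditions: Mapping[str, float],
    factor: float = 2.0,
    max_iter: int = 100,
    growth_tol: float = 0.05,
):
    """Relax kcats until predicted growth approaches the measured rate.

    Each iteration solves pFBA under ``conditions``; if growth is below
    ``target_growth*(1-growth_tol)`` the reaction with the largest enzyme
    usage share gets ``kcat *= factor`` (ties broken lexicographically by
    reaction id, source tagged ``calibrated``).  Returns the adjusted model
    and the full step log; non-convergence is flagged on the final step, not
    raised.
    """
    if target_growth <= 0:
        raise ValueError("target_growth must be > 0")
    if factor <= 1:
        raise ValueError("factor must be > 1")
    ec = ec.copy()
    steps: list = []
    recent: list = []
    sol = _solve_growth(ec, conditions)
    if not sol.ok:
        raise RuntimeError(f"base model is {sol.status} under the given conditions")
    for it in range(1, max_iter + 1):
        growth = sol.objective_value
        if growth >= target_growth * (1.0 - growth_tol):
            if steps:
                steps[-1].converged = True
            break
        # largest pool share; enzyme-free reactions carry no usage
        usable = {rid: e for rid, e in sol.enzyme_usage.items() if e > 0}
        if not usable:
            if steps:
                steps[-1].stagnated = True
            break
        best = sorted(usable.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        entry = ec.enzymes[best]
        old = entry.kcat
        entry.kcat = min(old * factor, KCAT_CAP)
        entry.kcat_source = "calibrated"
        sol = _solve_growth(ec, conditions)
        growth = sol.objective_value if sol.ok else 0.0
        steps.append(CalibrationStep(it, best, old, entry.kcat, "enzyme_usage", growth))
        recent.append(growth)
        if len(recent) > _STAGNATION_STEPS:
            recent.pop(0)
            if max(recent) - min(recent) <= _STAGNATION_TOL:
                steps[-1].stagnated = True
                break
    else:
        if steps and steps[-1].metric_after < target_growth * (1.0 - growth_tol):
            steps[-1].stagnated = True
    return ec, steps


@dataclass
class FluxMeasurement:
    """A measured net flux (13C-style) for an original-model reaction."""

    reaction_id: str
    measured_flux: float
    tolerance: float = 0.05  # relative

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError(f"{self.reaction_id}: tolerance must be > 0")


def _relative_errors(net: Mapping[str, float], measurements) -> dict:
    errs = {}
    for m in measurements:
        denom = max(abs(m.measured_flux), _EPS_FLUX)
        errs[m.reaction_id] = abs(net[m.reaction_id] - m.measured_flux) / denom
    return errs


def calibrate_c13(
    ec: ECModel,
    measurements: Sequence[FluxMeasurement],
    split_map: Optional[SplitMap] = None,
    conditions: Optional[Mapping[str, float]] = None,
    factor: float = 2.0,
    max_iter: int = 100,
):
    """Relax kcats until predicted net fluxes match measured values.

    Predicted fluxes are compared as *net* original-model quantities.  Only
    under-predictions are corrected (the pool row is an upper bound, so an
    over-prediction signals network structure rather than a slow kcat): for
    each measurement beyond tolerance with prediction < measurement, the
    split copy of that reaction carrying the largest enzyme cost has its
    kcat multiplied by ``factor``.  Returns ``(model, steps, final relative
    errors per measurement)``.
    """
    if factor <= 1:
        raise ValueError("factor must be > 1")
    ec = ec.copy()
    sm = split_map or ec.split_map
    if sm is None:
        raise ValueError("a split map is required to compare net fluxes")
    known = {oid for oid, _ in sm.copies.values()}
    for m in measurements:
        if m.reaction_id not in known:
            raise KeyError(f"measurement for unknown reaction {m.reaction_id!r}")
    conditions = conditions or {}
    steps: list = []
    recent: list = []
    errs: dict = {}
    iteration = 0
    for _round in range(max_iter):
        sol = pfba(with_conditions(ec, conditions))
        if not sol.ok:
            raise RuntimeError(f"model is {sol.status} under the given conditions")
        net = net_fluxes(sol.fluxes, sm)
        errs = _relative_errors(net, measurements)
        bad = [
            m for m in measurements
            if errs[m.reaction_id] > m.tolerance and net[m.reaction_id] < m.measured_flux
        ]
        if not bad:
            if steps:
                steps[-1].converged = True
            break
        # relax the dominant-cost copy of every under-predicted reaction
        worst_bad = max(errs[m.reaction_id] for m in bad)
        for m in sorted(bad, key=lambda m: m.reaction_id):
            copies = [sid for sid, _ in sm.copies_of(m.reaction_id) if sid in ec.enzymes]
            if not copies:
                continue
            dominant = sorted(
                copies,
                key=lambda sid: (-(sol.fluxes.get(sid, 0.0)
                                   * ec.enzymes[sid].pool_coefficient
                                   or ec.enzymes[sid].pool_coefficient), sid),
            )[0]
            entry = ec.enzymes[dominant]
            old = entry.kcat
            entry.kcat = min(old * factor, KCAT_CAP)
            entry.kcat_source = "calibrated"
            iteration += 1
            steps.append(
                CalibrationStep(iteration, dominant, old, entry.kcat,
                                "c13_consistency", errs[m.reaction_id])
            )
        recent.append(worst_bad)
        if len(recent) > _STAGNATION_STEPS:
            recent.pop(0)
            if max(recent) - min(recent) <= _STAGNATION_TOL:
                steps[-1].stagnated = True
                break
    return ec, steps, errs
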