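"""Flux balance analysis core: steady-state LP with nutrient-uptake objective.

The linear program is min c.v subject to S.v = 0 and lb <= v <= ub, solved
with the HiGHS solver through :func:`scipy.optimize.linprog`.  The biomass
flux is fixed to the growth rate and one nutrient's supply is minimized,
which emulates growth of a chemostat culture limited for that nutrient.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse
from scipy.optimize import linprog

from .model_io import NUTRIENTS, StoichiometricModel

#: Exchange bound magnitude treated as "limitless" nutrient entry
#: (mmol gDW^-1 h^-1); the constraint-based-modelling convention.
LIMITLESS_BOUND = 1000.0

FEASIBILITY_TOL = 1e-7


class InfeasibleProblemError(RuntimeError):
    """The LP has no feasible flux distribution (contradictory constraints)."""


class UnboundedProblemError(RuntimeError):
    """The LP objective is unbounded (a missing flux bound)."""


@dataclass
class FluxSolution:
    """Optimal flux vector and objective of one FBA solve.

    Only ``objective_value`` is unique; alternate optima may differ in
    ``fluxes``.
    """

    fluxes: np.ndarray
    objective_value: float
    status: str
    reaction_ids: list[str]

    def flux(self, rxn_id: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(rxn_id)])


def solve_lp(model: StoichiometricModel,
             objective: Mapping[str, float],
             fixed_fluxes: Mapping[str, float] | None = None) -> FluxSolution:
    """Minimize ``sum(objective[r] * v[r])`` subject to mass balance and bounds.

    ``fixed_fluxes`` pins reactions to exact values (within their bounds).
    Raises :class:`InfeasibleProblemError` / :class:`UnboundedProblemError`.
    """
    c = np.zeros(model.n_reactions)
    for rxn, coeff in objective.items():
        c[model.reaction_index(rxn)] = coeff
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for rxn, value in (fixed_fluxes or {}).items():
        j = model.reaction_index(rxn)
        if not (model.lower_bounds[j] - FEASIBILITY_TOL <= value
                <= model.upper_bounds[j] + FEASIBILITY_TOL):
            raise ValueError(
                f"fixed flux {value} for {rxn!r} outside bounds "
                f"[{model.lower_bounds[j]}, {model.upper_bounds[j]}]"
            )
        lb[j] = ub[j] = value
    A_eq = scipy.sparse.csr_matrix(model.S)
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(model.n_metabolites),
                  bounds=np.column_stack([lb, ub]), method="highs",
                  options={"primal_feasibility_tolerance": 1e-9,
                           "dual_feasibility_tolerance": 1e-9})
    if res.status == 2:
        raise InfeasibleProblemError(
            "no feasible flux distribution (contradictory constraints)")
    if res.status == 3:
        raise UnboundedProblemError("objective unbounded; a flux bound is missing")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    v = res.x
    residual = float(np.max(np.abs(model.S @ v))) if model.n_metabolites else 0.0
    if residual > FEASIBILITY_TOL:
        raise RuntimeError(f"mass balance residual {residual:.2e} above tolerance")
    return FluxSolution(fluxes=v, objective_value=float(res.fun),
                        status="optimal", reaction_ids=list(model.reaction_ids))


def minimize_nutrient_uptake(model: StoichiometricModel, nutrient: str,
                             growth_rate: float,
                             limitless_bound: float = LIMITLESS_BOUND) -> FluxSolution:
    """Minimal uptake U of ``nutrient`` at a fixed biomass flux.

    The biomass reaction is constrained to exactly ``growth_rate`` (h^-1),
    all three nutrient exchanges are opened to the limitless bound, and the
    named nutrient's supply into the cell is minimized.  The returned
    ``objective_value`` is U >= 0, the uptake magnitude.
    """
    if nutrient not in NUTRIENTS:
        raise ValueError(f"nutrient must be one of {NUTRIENTS}, got {nutrient!r}")
    if nutrient not in model.nutrient_exchanges:
        raise KeyError(f"model has no exchange mapped for {nutrient!r}")
    if growth_rate <= 0:
        raise ValueError("growth rate must be positive")

    work = model.copy()
    for nut, rxn in work.nutrient_exchanges.items():
        j = work.reaction_index(rxn)
        coeff = work.exchange_coefficient(rxn)
        # open the uptake direction: negative flux imports when the single
        # coefficient is negative, positive flux when it is positive
        if coeff < 0:
            work.lower_bounds[j] = min(work.lower_bounds[j], -abs(limitless_bound))
        else:
            work.upper_bounds[j] = max(work.upper_bounds[j], abs(limitless_bound))

    target = work.nutrient_exchanges[nutrient]
    # supply of the nutrient into the network is coeff * v; minimizing it
    # minimizes uptake (and would drive export if that were feasible)
    objective = {target: work.exchange_coefficient(target)}
    sol = solve_lp(work, objective, fixed_fluxes={work.biomass_reaction: growth_rate})
    sol.objective_value = max(0.0, sol.objective_value)
    return sol
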