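"""Amino acid biosynthetic cost by biomass-coefficient perturbation sweeps.

The cost of an amino acid under a nutrient limitation is the sensitivity of
the minimal nutrient uptake U to the residue's stoichiometric requirement x
in the biomass reaction: a sweep of small perturbations of x is applied, U
recomputed by FBA at each point, and the slope dU/dx (absolute mode) or
dU/dr for fractional change r (relative mode) fitted by least squares.
Dividing the slope by the growth rate at which it was measured removes the
proportional dependence on growth rate, making absolute costs unitless and
relative costs mmol gDW^-1.  The two modes are linked by the identity
relative = absolute * x.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import fba_core
from .model_io import NUTRIENTS, StoichiometricModel, get_biomass_coefficient
from .properties import RESIDUES_3

MODES = ("absolute", "relative")

#: Default symmetric perturbation sweeps: 11 points, +/-1e-4 mmol/gDW for
#: absolute mode and +/-1% of x for relative mode — small enough for
#: linearity of the LP optimum, large enough to dominate solver noise.
DEFAULT_ABSOLUTE_DELTAS = tuple(np.linspace(-1e-4, 1e-4, 11))
DEFAULT_RELATIVE_DELTAS = tuple(np.linspace(-0.01, 0.01, 11))

DEFAULT_GROWTH_RATE = 0.1
DEFAULT_GROWTH_RATES = (0.05, 0.1, 0.2)

NUTRIENT_SHORT = {"glucose": "glc", "ammonium": "nh4", "sulphate": "so4"}

LINEARITY_R2_THRESHOLD = 0.999


@dataclass
class CostEstimate:
    """One amino acid's cost for one nutrient limitation and mode."""

    residue: str
    nutrient: str
    mode: str
    growth_rate: float
    raw_slope: float
    rescaled_cost: float
    fit_r2: float
    n_points: int
    nonlinear: bool = False


@dataclass
class CostTable:
    """Residues x cost types matrix with per-column units and provenance."""

    values: pd.DataFrame
    units: dict[str, str]
    provenance: dict[str, str]

    def column(self, cost_type: str) -> pd.Series:
        return self.values[cost_type].copy()


def default_deltas(mode: str) -> tuple[float, ...]:
    return DEFAULT_ABSOLUTE_DELTAS if mode == "absolute" else DEFAULT_RELATIVE_DELTAS


def perturb_biomass_requirement(model: StoichiometricModel, residue: str,
                                delta: float, mode: str) -> StoichiometricModel:
    """Copy of ``model`` with the residue's biomass requirement perturbed.

    Absolute mode shifts x to x + delta; relative mode scales to
    x * (1 + delta).  The coefficient must remain a consumption.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    residue = residue.lower()
    x = get_biomass_coefficient(model, residue)
    new_x = x + delta if mode == "absolute" else x * (1.0 + delta)
    if new_x <= 0:
        raise ValueError(
            f"perturbation {delta} zeroes or flips the biomass coefficient of "
            f"{residue} (x={x})"
        )
    out = model.copy()
    i = out.metabolite_index(out.amino_acid_map[residue])
    j = out.reaction_index(out.biomass_reaction)
    out.S[i, j] = np.sign(model.S[i, j]) * new_x
    return out


def sweep_uptake(model: StoichiometricModel, residue: str, nutrient: str,
                 mode: str, growth_rate: float,
                 deltas: Sequence[float],
                 limitless_bound: float = fba_core.LIMITLESS_BOUND,
                 ) -> list[tuple[float, float]]:
    """Minimal uptake U at each perturbation delta of the sweep."""
    deltas = list(deltas)
    if not deltas:
        raise ValueError("empty perturbation sweep")
    if 0.0 not in deltas:
        raise ValueError("sweep must include delta = 0")
    if not np.allclose(sorted(deltas), sorted(-d for d in deltas)):
        raise ValueError("sweep must be symmetric around 0")
    points = []
    for delta in deltas:
        perturbed = perturb_biomass_requirement(model, residue, delta, mode)
        try:
            sol = fba_core.minimize_nutrient_uptake(
                perturbed, nutrient, growth_rate, limitless_bound)
        except fba_core.InfeasibleProblemError as exc:
            raise fba_core.InfeasibleProblemError(
                f"sweep point delta={delta} for {residue}/{nutrient} infeasible"
            ) from exc
        points.append((delta, sol.objective_value))
    return points


def _slope_and_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # flat response up to LP solver noise: slope 0, not an error
    if np.ptp(y) <= 1e-9 * max(1.0, float(np.abs(y).max())):
        return 0.0, 1.0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return float(slope), float(min(max(r2, 0.0), 1.0))


def estimate_cost(model: StoichiometricModel, residue: str, nutrient: str,
                  mode: str, growth_rate: float = DEFAULT_GROWTH_RATE,
                  deltas: Sequence[float] | None = None,
                  limitless_bound: float = fba_core.LIMITLESS_BOUND) -> CostEstimate:
    """Least-squares slope of the uptake sweep, rescaled by growth rate."""
    if deltas is None:
        deltas = default_deltas(mode)
    points = sweep_uptake(model, residue, nutrient, mode, growth_rate, deltas,
                          limitless_bound)
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    slope, r2 = _slope_and_r2(x, y)
    return CostEstimate(
        residue=residue.lower(), nutrient=nutrient, mode=mode,
        growth_rate=growth_rate, raw_slope=slope,
        rescaled_cost=slope / growth_rate, fit_r2=r2, n_points=len(points),
        nonlinear=r2 < LINEARITY_R2_THRESHOLD,
    )


def convert_cost(estimate: CostEstimate, x: float) -> CostEstimate:
    """Convert between absolute and relative mode via relative = absolute * x."""
    if x <= 0:
        raise ValueError("biomass coefficient x must be positive")
    if estimate.mode == "absolute":
        factor, new_mode = x, "relative"
    else:
        factor, new_mode = 1.0 / x, "absolute"
    return replace(estimate, mode=new_mode,
                   raw_slope=estimate.raw_slope * factor,
                   rescaled_cost=estimate.rescaled_cost * factor)


def cost_column_name(mode: str, nutrient: str) -> str:
    return f"{'abs' if mode == 'absolute' else 'rel'}_{NUTRIENT_SHORT[nutrient]}"


def cost_table(model: StoichiometricModel,
               nutrients: Iterable[str] = NUTRIENTS,
               modes: Iterable[str] = MODES,
               growth_rate: float = DEFAULT_GROWTH_RATE,
               deltas: Sequence[float] | None = None,
               limitless_bound: float = fba_core.LIMITLESS_BOUND) -> CostTable:
    """Cost estimates for every mapped residue, nutrient and mode.

    Returns a 20-row table (unmapped residues carry NaN) with columns named
    ``abs_glc``, ``rel_glc``, ``abs_nh4``, ...
    """
    if not model.amino_acid_map:
        raise ValueError("model maps no amino acids")
    frame = pd.DataFrame(index=pd.Index(RESIDUES_3, name="residue"), dtype=float)
    units, provenance = {}, {}
    for mode in modes:
        for nutrient in nutrients:
            col = cost_column_name(mode, nutrient)
            values = pd.Series(np.nan, index=frame.index)
            for residue in model.amino_acid_map:
                est = estimate_cost(model, residue, nutrient, mode,
                                    growth_rate, deltas, limitless_bound)
                values[residue] = est.rescaled_cost
            frame[col] = values
            units[col] = "unitless" if mode == "absolute" else "mmol/gDW"
            provenance[col] = (
                f"FBA perturbation sweep, {mode} mode, {nutrient} limitation, "
                f"growth rate {growth_rate}/h"
            )
    return CostTable(values=frame, units=units, provenance=provenance)


def growth_rate_stability(model: StoichiometricModel, residue: str,
                          nutrient: str, mode: str,
                          growth_rates: Sequence[float] = DEFAULT_GROWTH_RATES,
                          deltas: Sequence[float] | None = None) -> float:
    """Largest pairwise difference of rescaled costs across growth rates."""
    rates = list(growth_rates)
    if len(rates) < 2:
        raise ValueError("need at least two growth rates")
    costs = [estimate_cost(model, residue, nutrient, mode, mu, deltas).rescaled_cost
             for mu in rates]
    return float(max(costs) - min(costs))
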