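"""Linear-programming core: FBA, FVA and minimal-support flux distributions.

Flux balance analysis (FBA) maximizes the biomass flux v_bio subject to
steady-state mass balance S·v = 0 and the per-reaction bounds; its optimum is
the growth-rate proxy. Flux variability analysis (FVA) then minimizes and
maximizes each reaction's flux while holding biomass at (a fraction of) that
optimum. The minimal-support solution minimizes the L1 norm sum|v| at a given
biomass requirement via the standard split v = v+ - v-; its support (the
reactions with |flux| above tolerance) drives the Fast-SL search-space
reduction in :mod:`strainflux.lethality`.

All solves go through a small internal LP contract (:func:`solve_lp`) backed
by HiGHS dual simplex, so the solver is swappable and optimal solutions are
vertices (which keeps minimal-support supports small).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_core import MetabolicModel

#: Tolerance for mass balance, bound satisfaction and "carries flux" tests.
FLUX_TOL = 1e-6

#: FBA objective above this value counts as growth (see phenotyping.grows).
GROWTH_THRESHOLD = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class LPError(RuntimeError):
    """An LP solve failed or returned an unusable status."""


@dataclass
class FluxSolution:
    """Outcome of one FBA-style solve."""

    status: str
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def support(self, tol: float = FLUX_TOL) -> set[str]:
        """Reactions carrying flux of magnitude above ``tol``."""
        return {r for r, v in self.fluxes.items() if abs(v) > tol}


@dataclass
class FluxRange:
    """Per-reaction (min, max) flux from FVA."""

    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.ranges

    def carries_flux(self, rxn_id: str, tol: float = FLUX_TOL) -> bool:
        lo, hi = self.ranges[rxn_id]
        return max(abs(lo), abs(hi)) > tol


def solve_lp(
    c: np.ndarray,
    A_eq: sp.spmatrix,
    b_eq: np.ndarray,
    bounds: list[tuple[float, float]],
) -> tuple[str, float, np.ndarray | None]:
    """Minimize c·x s.t. A_eq·x = b_eq, bounds. Returns (status, objective, x)."""
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs-ds")
    status = _STATUS.get(res.status, "failed")
    x = res.x if res.status == 0 else None
    obj = float(res.fun) if res.status == 0 else float("nan")
    return status, obj, x


def stoichiometric_matrix(model: MetabolicModel) -> sp.csr_matrix:
    """S with one row per metabolite, one column per reaction (input order)."""
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(coef)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def _bounds(model: MetabolicModel) -> list[tuple[float, float]]:
    return [(r.lower_bound, r.upper_bound) for r in model.reactions]


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize biomass flux subject to S·v = 0 and the flux bounds.

    The status is reported faithfully: an infeasible or unbounded problem
    never comes back as a silent zero.
    """
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    obj_idx = model.reaction_ids.index(model.objective_reaction_id)
    c = np.zeros(n)
    c[obj_idx] = -1.0  # maximize
    status, obj, x = solve_lp(c, S, np.zeros(S.shape[0]), _bounds(model))
    if status == "optimal":
        fluxes = dict(zip(model.reaction_ids, x.tolist()))
        return FluxSolution(status="optimal", objective_value=-obj, fluxes=fluxes)
    if status in ("infeasible", "unbounded"):
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    raise LPError(f"FBA solve failed for model {model.id!r}: solver status {status}")


def _with_biomass_floor(
    model: MetabolicModel, biomass_fraction: float, eps: float = FLUX_TOL
) -> tuple[MetabolicModel, float]:
    """Copy of the model whose biomass lower bound enforces
    v_bio >= biomass_fraction * (1 - eps) * optimum."""
    wt = fba(model)
    if not wt.optimal:
        raise LPError(f"model {model.id!r}: FBA not optimal (status {wt.status})")
    floor = biomass_fraction * (1.0 - eps) * wt.objective_value
    bio = model.reaction(model.objective_reaction_id)
    constrained = model.with_reaction_bounds(
        {bio.id: (max(bio.lower_bound, floor), bio.upper_bound)}
    )
    return constrained, wt.objective_value


def fva(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    biomass_fraction: float = 1.0,
) -> FluxRange:
    """Min/max flux per reaction with biomass held at ``biomass_fraction`` of
    its FBA optimum (fraction 1 pins biomass at the maximum growth rate, up to
    solver tolerance)."""
    if reaction_ids is None:
        reaction_ids = model.reaction_ids
    unknown = sorted(set(reaction_ids) - set(model.reaction_ids))
    if unknown:
        raise KeyError(f"FVA: reactions not in model {model.id!r}: {unknown}")
    constrained, _ = _with_biomass_floor(model, biomass_fraction)
    S = stoichiometric_matrix(constrained)
    zeros = np.zeros(S.shape[0])
    bounds = _bounds(constrained)
    n = len(constrained.reactions)
    index = {r: j for j, r in enumerate(constrained.reaction_ids)}
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        j = index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        status_lo, lo, _ = solve_lp(c, S, zeros, bounds)
        c[j] = -1.0
        status_hi, hi, _ = solve_lp(c, S, zeros, bounds)
        if status_lo != "optimal" or status_hi != "optimal":
            raise LPError(
                f"FVA infeasible for {rid!r} in model {model.id!r} at biomass "
                f"fraction {biomass_fraction} (status {status_lo}/{status_hi})"
            )
        ranges[rid] = (lo, -hi)
    return FluxRange(ranges=ranges)


def minimal_support_solution(
    model: MetabolicModel, biomass_fraction: float = 1.0
) -> FluxSolution:
    """Flux distribution minimizing sum|v| subject to biomass >=
    ``biomass_fraction`` x optimum.

    Uses the split v = f - r with f, r >= 0 and minimizes sum(f + r); at a
    vertex optimum at most one of each pair is active, so the objective equals
    the L1 norm and the support is parsimonious.
    """
    constrained, opt = _with_biomass_floor(model, biomass_fraction)
    S = stoichiometric_matrix(constrained)
    m, n = S.shape
    A = sp.hstack([S, -S], format="csr")
    c = np.ones(2 * n)
    split_bounds: list[tuple[float, float]] = []
    for lb, ub in _bounds(constrained):
        split_bounds.append((max(lb, 0.0), max(ub, 0.0)))
    for lb, ub in _bounds(constrained):
        split_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))
    status, _, x = solve_lp(c, A, np.zeros(m), split_bounds)
    if status != "optimal":
        raise LPError(
            f"minimal-support solve failed for model {model.id!r} at biomass "
            f"fraction {biomass_fraction}: status {status}"
        )
    v = x[:n] - x[n:]
    fluxes = dict(zip(model.reaction_ids, v.tolist()))
    obj = fluxes[model.objective_reaction_id]
    return FluxSolution(status="optimal", objective_value=obj, fluxes=fluxes)


def mass_balance_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """The infinity norm of S·v for a solved flux vector."""
    S = stoichiometric_matrix(model)
    v = np.array([solution.fluxes[r] for r in model.reaction_ids])
    return float(np.abs(S @ v).max()) if len(v) else 0.0
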