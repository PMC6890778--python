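"""FBA/FVA/minimal-support correctness against hand-solved LPs."""

import numpy as np
import pytest

from strainflux.lp_engine import (
    FLUX_TOL,
    fba,
    fva,
    mass_balance_residual,
    minimal_support_solution,
)

from conftest import build_model, chain_model, parallel_model


def two_to_one_model():
    """2 a -> b with a-uptake 10: biomass = 5 by hand."""
    return build_model(
        "two_to_one",
        [
            ("EX_a_e", {"a_e": -1}, -10, 1000),
            ("T", {"a_e": -1, "a": 1}, 0, 1000),
            ("CONV", {"a": -2, "b": 1}, 0, 1000),
            ("BIOMASS", {"b": -1}, 0, 1000),
        ],
        "BIOMASS",
    )


def test_fba_matches_hand_values_on_chain_and_stoichiometry():
    assert fba(chain_model()).objective_value == pytest.approx(10, abs=1e-6)
    assert fba(two_to_one_model()).objective_value == pytest.approx(5, abs=1e-6)


def test_fba_reports_infeasible_not_zero():
    """A forced biomass flux with no nutrient input must surface as
    infeasible, never as a silent zero optimum."""
    model = build_model(
        "starved",
        [
            ("EX_a_e", {"a_e": -1}, 0, 1000),
            ("T", {"a_e": -1, "a": 1}, 0, 1000),
            ("BIOMASS", {"a": -1}, 1.0, 1000),  # demands growth
        ],
        "BIOMASS",
    )
    sol = fba(model)
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


def test_optimal_solutions_are_mass_balanced():
    for model in [chain_model(), two_to_one_model(), parallel_model()]:
        sol = fba(model)
        assert sol.optimal
        assert mass_balance_residual(model, sol) <= 1e-6
        for rxn in model.reactions:
            v = sol.fluxes[rxn.id]
            assert rxn.lower_bound - 1e-6 <= v <= rxn.upper_bound + 1e-6


def test_fva_unconstrained_reaction_spans_its_bounds():
    """A secretion valve decoupled from biomass keeps its full range."""
    model = build_model(
        "valve",
        [
            ("EX_a_e", {"a_e": -1}, -10, 1000),
            ("T", {"a_e": -1, "a": 1}, 0, 1000),
            ("BIOMASS", {"a": -1}, 0, 1000),
            ("EX_b_e", {"b_e": -1}, -3, 7),
            ("TB", {"b_e": -1, "b": 1}, -1000, 1000),
            ("SINK_b", {"b": -1}, -1000, 1000),
        ],
        "BIOMASS",
    )
    rng = fva(model, ["EX_b_e"], biomass_fraction=1.0)
    lo, hi = rng["EX_b_e"]
    assert lo == pytest.approx(-3, abs=1e-6)
    assert hi == pytest.approx(7, abs=1e-6)


def test_fva_parallel_routes_share_the_forced_total():
    """Two identical routes jointly carrying 10: each ranges over [0, 10]."""
    model = parallel_model()
    rng = fva(model, ["R1", "R2"], biomass_fraction=1.0)
    for rid in ("R1", "R2"):
        lo, hi = rng[rid]
        assert lo == pytest.approx(0, abs=1e-5)
        assert hi == pytest.approx(10, abs=1e-5)


def test_fva_biomass_range_collapses_at_fraction_one():
    model = chain_model()
    opt = fba(model).objective_value
    rng = fva(model, ["BIOMASS"], biomass_fraction=1.0)
    lo, hi = rng["BIOMASS"]
    assert hi == pytest.approx(opt, abs=1e-6)
    assert opt * (1 - 1e-6) - 1e-9 <= lo <= opt + 1e-9


def test_fba_optimum_lies_in_biomass_fva_range():
    for model in [chain_model(), parallel_model(), two_to_one_model()]:
        opt = fba(model).objective_value
        lo, hi = fva(model, ["BIOMASS"], biomass_fraction=0.5)["BIOMASS"]
        assert lo - 1e-6 <= opt <= hi + 1e-6


def test_relaxing_bounds_never_shrinks_fva_ranges():
    tight = parallel_model(uptake=5.0)
    loose = parallel_model(uptake=10.0)
    rt = fva(tight, ["R1", "R2", "BIOMASS"], biomass_fraction=0.0)
    rl = fva(loose, ["R1", "R2", "BIOMASS"], biomass_fraction=0.0)
    for rid in ("R1", "R2", "BIOMASS"):
        assert rl[rid][0] <= rt[rid][0] + 1e-9
        assert rl[rid][1] >= rt[rid][1] - 1e-9


def test_fva_values_are_reproducible():
    model = parallel_model()
    a = fva(model, model.reaction_ids, 1.0)
    b = fva(model, model.reaction_ids, 1.0)
    for rid in model.reaction_ids:
        assert a[rid] == b[rid]
    assert fba(model).objective_value == fba(model).objective_value


def test_minimal_support_uses_whole_chain():
    model = chain_model()
    sol = minimal_support_solution(model, biomass_fraction=1.0)
    assert sol.support() == {"EX_a_e", "T", "CONV", "BIOMASS"}


def test_minimal_support_picks_one_parallel_route():
    """With two equivalent routes, the L1-minimal vertex loads only one."""
    model = parallel_model()
    sol = minimal_support_solution(model, biomass_fraction=1.0)
    used = sol.support() & {"R1", "R2"}
    assert len(used) == 1
    assert abs(sol.fluxes[used.pop()]) == pytest.approx(10, abs=1e-4)


def test_minimal_support_silences_detached_futile_cycle():
    """A reversible 2-cycle detached from biomass carries zero flux in the
    L1-minimal solution even though nonzero loops are feasible."""
    model = build_model(
        "cycle",
        [
            ("EX_a_e", {"a_e": -1}, -10, 1000),
            ("T", {"a_e": -1, "a": 1}, 0, 1000),
            ("BIOMASS", {"a": -1}, 0, 1000),
            ("C1", {"x": -1, "y": 1}, -1000, 1000),
            ("C2", {"y": -1, "x": 1}, -1000, 1000),
        ],
        "BIOMASS",
    )
    sol = minimal_support_solution(model, biomass_fraction=1.0)
    assert abs(sol.fluxes["C1"]) <= FLUX_TOL
    assert abs(sol.fluxes["C2"]) <= FLUX_TOL


def test_minimal_support_l1_not_above_enumerated_vertices():
    """The L1 objective is minimal over the optimal face: both pure-route
    vertices of the parallel toy have norm 40; the solver must not exceed it."""
    model = parallel_model()
    sol = minimal_support_solution(model, biomass_fraction=1.0)
    l1 = sum(abs(v) for v in sol.fluxes.values())
    vertex_norms = [10 + 10 + 10 + 0 + 10, 10 + 10 + 0 + 10 + 10]
    assert l1 <= min(vertex_norms) + 1e-6
    assert sol.objective_value >= 10 * (1 - 1e-6) - 1e-9


def test_cross_check_against_independent_solver(worked_example):
    """FBA optima agree with an independent COBRA/GLPK implementation."""
    cobra = pytest.importorskip("cobra")
    from strainflux.environments import apply_environment

    model, envs, _ = worked_example
    conditioned = apply_environment(model, envs["glucose"])
    cm = cobra.Model("x")
    cm.add_metabolites(
        [cobra.Metabolite(m.id, compartment=m.compartment) for m in conditioned.metabolites]
    )
    for rxn in conditioned.reactions:
        cr = cobra.Reaction(rxn.id)
        cm.add_reactions([cr])
        cr.add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()}
        )
        cr.bounds = (rxn.lower_bound, rxn.upper_bound)
    cm.objective = conditioned.objective_reaction_id
    assert fba(conditioned).objective_value == pytest.approx(
        cm.optimize().objective_value, abs=1e-6
    )
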