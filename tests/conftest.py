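"""Shared fixtures: hand-sized LP models and one generated strain panel."""

from __future__ import annotations

import pytest

from strainflux.environments import NutrientEnvironment
from strainflux.model_core import MetabolicModel, Metabolite, Reaction
from strainflux.synthetic_data import PanelSpec, generate_panel, worked_example_fixture


def build_model(
    model_id: str,
    reactions: list[tuple[str, dict[str, float], float, float]],
    objective: str,
) -> MetabolicModel:
    """Assemble a model from (id, stoichiometry, lb, ub) rows; metabolites
    are declared implicitly, external ones by an ``_e`` suffix."""
    mets: list[str] = []
    for _, st, _, _ in reactions:
        for mid in st:
            if mid not in mets:
                mets.append(mid)
    return MetabolicModel(
        id=model_id,
        metabolites=[
            Metabolite(id=m, compartment="e" if m.endswith("_e") else "c")
            for m in mets
        ],
        reactions=[
            Reaction(
                id=rid,
                stoichiometry=st,
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=rid.startswith("EX_"),
            )
            for rid, st, lb, ub in reactions
        ],
        objective_reaction_id=objective,
    )


def chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_a (lb -uptake) -> a -> b -> biomass; optimum = uptake."""
    return build_model(
        "chain",
        [
            ("EX_a_e", {"a_e": -1}, -uptake, 1000),
            ("T", {"a_e": -1, "a": 1}, 0, 1000),
            ("CONV", {"a": -1, "b": 1}, 0, 1000),
            ("BIOMASS", {"b": -1}, 0, 1000),
        ],
        "BIOMASS",
    )


def parallel_model(uptake: float = 10.0) -> MetabolicModel:
    """Two identical routes a -> b; joint flux bound by uptake."""
    return build_model(
        "parallel",
        [
            ("EX_a_e", {"a_e": -1}, -uptake, 1000),
            ("T", {"a_e": -1, "a": 1}, 0, 1000),
            ("R1", {"a": -1, "b": 1}, 0, 1000),
            ("R2", {"a": -1, "b": 1}, 0, 1000),
            ("BIOMASS", {"b": -1}, 0, 1000),
        ],
        "BIOMASS",
    )


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def panel_seed1():
    return generate_panel(PanelSpec(seed=1))


@pytest.fixture
def glucose_env():
    return NutrientEnvironment(name="glucose", carbon_uptakes={"EX_glc_e": 10.0})
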