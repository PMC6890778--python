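"""Model types, SBML/JSON round trips, reaction-string parsing, patches."""

import pytest

from strainflux.environments import NutrientEnvironment, apply_environment
from strainflux.lp_engine import fba
from strainflux.model_core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    ModelPatch,
    Reaction,
    apply_patch,
    is_exchange_like,
    load_model,
    load_patch,
    models_equal,
    parse_reaction_string,
    save_model,
)
from strainflux.synthetic_data import PanelSpec, generate_core_shunt, generate_panel

from conftest import build_model, chain_model

MINIMAL_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="mini" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
      <compartment id="e" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="M_a_e" compartment="e" constant="false"
               boundaryCondition="false" hasOnlySubstanceUnits="false"/>
      <species id="M_a" compartment="c" constant="false"
               boundaryCondition="false" hasOnlySubstanceUnits="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_up" value="-10" constant="true"/>
      <parameter id="lb_0" value="0" constant="true"/>
      <parameter id="ub" value="1000" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="R_EX_a_e" reversible="true" fast="false"
                fbc:lowerFluxBound="lb_up" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_a_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="R_T" reversible="false" fast="false"
                fbc:lowerFluxBound="lb_0" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_a_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_a" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R_BIOMASS" reversible="false" fast="false"
                fbc:lowerFluxBound="lb_0" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_a" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="R_BIOMASS" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


def test_minimal_sbml_loads_with_objective(tmp_path):
    """A 3-reaction uptake -> transport -> biomass SBML file resolves fully."""
    p = tmp_path / "mini.xml"
    p.write_text(MINIMAL_SBML)
    model = load_model(str(p), "sbml")
    assert len(model.reactions) == 3
    assert model.objective_reaction_id == "BIOMASS"
    assert model.reaction("EX_a_e").lower_bound == -10
    assert model.reaction("EX_a_e").is_exchange
    assert fba(model).objective_value == pytest.approx(10)


@pytest.mark.parametrize("fmt,ext", [("json", "json"), ("sbml", "xml")])
def test_round_trip_is_identity(tmp_path, fmt, ext):
    """save -> load preserves stoichiometry, bounds (full precision),
    objective and exchange flags, for the core strain and a panel strain."""
    models, _ = generate_panel(PanelSpec(n_strains=2, n_groups=2, seed=3))
    for model in [generate_core_shunt(), *models]:
        path = tmp_path / f"{model.id}.{ext}"
        save_model(model, str(path), fmt)
        reloaded = load_model(str(path), fmt)
        assert models_equal(model, reloaded)
        assert {r.id for r in reloaded.exchange_reactions()} == {
            r.id for r in model.exchange_reactions()
        }


def test_undeclared_metabolite_is_named_in_error():
    with pytest.raises(ModelError, match="ghost"):
        MetabolicModel(
            id="bad",
            metabolites=[Metabolite(id="a")],
            reactions=[
                Reaction(id="R", stoichiometry={"a": -1, "ghost": 1}),
                Reaction(id="BIOMASS", stoichiometry={"a": -1}),
            ],
            objective_reaction_id="BIOMASS",
        )


def test_missing_objective_errors(tmp_path):
    p = tmp_path / "noobj.json"
    p.write_text(
        '{"id": "x", "metabolites": [{"id": "a", "compartment": "c"}], '
        '"reactions": [{"id": "R", "metabolites": {"a": -1}, '
        '"lower_bound": 0, "upper_bound": 10}]}'
    )
    with pytest.raises(ModelError, match="objective"):
        load_model(str(p), "json")


def test_exchange_detection_rule():
    assert is_exchange_like("EX_whatever", {"a": -1, "b": 1})
    assert is_exchange_like("sink", {"a": -1})
    assert not is_exchange_like("T", {"a": -1, "b": 1})
    assert not is_exchange_like("source", {"a": 1})


@pytest.mark.parametrize(
    "expr,expected,reversible",
    [
        ("1 starch_e -> 2 glc_e", {"starch_e": -1, "glc_e": 2}, False),
        ("a + b -> c", {"a": -1, "b": -1, "c": 1}, False),
        ("a <=> b", {"a": -1, "b": 1}, True),
        ("2 a ->", {"a": -2}, False),
        ("0.5 a -> 1.5 b", {"a": -0.5, "b": 1.5}, False),
    ],
)
def test_reaction_string_parsing(expr, expected, reversible):
    rxn = parse_reaction_string("R", expr)
    assert rxn.stoichiometry == expected
    assert (rxn.lower_bound < 0) == reversible


def test_empty_patch_is_identity():
    model = chain_model()
    patched = apply_patch(model, ModelPatch(strain_id="chain"))
    assert models_equal(model, patched)


def test_patch_grafts_starch_utilization(glucose_env):
    """Adding a starch exchange + hydrolysis chain converts a glucose-only
    strain into a starch grower; the original model is untouched."""
    model = generate_core_shunt("s1")
    patch = ModelPatch(
        strain_id="s1",
        added_reactions=[
            parse_reaction_string(
                "EX_starch_e", "starch_e ->", lower_bound=0, upper_bound=1000
            ),
            parse_reaction_string("STARCHt", "starch_e -> starch"),
            parse_reaction_string("AMYL", "starch -> 2 g1p"),
        ],
    )
    patched = apply_patch(model, patch)
    starch = NutrientEnvironment(name="starch", carbon_uptakes={"EX_starch_e": 10.0})
    assert fba(apply_environment(model, starch)).objective_value == pytest.approx(0)
    assert fba(apply_environment(patched, starch)).objective_value == pytest.approx(
        40 / 3
    )
    # patching is monotone in reactions and non-destructive
    assert set(patched.reaction_ids) >= set(model.reaction_ids)
    assert not model.has_reaction("AMYL")


def test_patch_id_collision_lists_ids():
    model = chain_model()
    patch = ModelPatch(
        strain_id="chain",
        added_reactions=[Reaction(id="CONV", stoichiometry={"a": -1, "b": 1})],
    )
    with pytest.raises(ModelError, match="CONV"):
        apply_patch(model, patch)


def test_patch_yaml_round_trip(tmp_path):
    p = tmp_path / "patch.yaml"
    p.write_text(
        "strain: s1\n"
        "reactions:\n"
        "  - id: EX_starch_e\n"
        "    equation: 'starch_e ->'\n"
        "    lower_bound: 0\n"
        "  - id: AMYL\n"
        "    equation: 'starch_e -> 2 glc_e'\n"
        "bound_changes:\n"
        "  AMYL: [0, 5]\n"
    )
    patch = load_patch(str(p))
    assert patch.strain_id == "s1"
    assert [r.id for r in patch.added_reactions] == ["EX_starch_e", "AMYL"]
    assert patch.bound_changes == {"AMYL": (0.0, 5.0)}


def test_bounds_must_be_ordered():
    with pytest.raises(ModelError):
        Reaction(id="R", stoichiometry={"a": -1}, lower_bound=5, upper_bound=1)


def test_knock_out_returns_copy():
    model = chain_model()
    ko = model.knock_out("CONV")
    assert ko.reaction("CONV").upper_bound == 0
    assert model.reaction("CONV").upper_bound == 1000
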