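"""Growth matrices, producer calling, shunt partitioning, knockout scans."""

import pytest

from strainflux.environments import NutrientEnvironment, rich_environment
from strainflux.lp_engine import fba
from strainflux.model_core import models_equal
from strainflux.phenotyping import (
    PhenotypeMatrix,
    classify_shunt_reactions,
    growth_matrix,
    grows,
    pooled_shunt_partition,
    producer_profile,
    producer_status,
    shunt_knockout_scan,
)
from strainflux.environments import EnvironmentPanel, apply_environment
from strainflux.synthetic_data import (
    CORE_CHAIN,
    PanelSpec,
    generate_core_shunt,
    generate_panel,
)

from conftest import build_model, chain_model


def test_grows_is_binary_and_faithful(worked_example):
    model, envs, expected = worked_example
    assert grows(model, envs["glucose"]) == 1
    assert grows(model, envs["empty"]) == expected["grows_empty"]


def test_growth_matrix_single_cell(glucose_env):
    m = growth_matrix([generate_core_shunt()], EnvironmentPanel([glucose_env]))
    assert m.values == [[1]]
    assert m.row_labels == ["core_shunt"] and m.column_labels == ["glucose"]


def test_growth_matrix_recovers_planted_truth(panel_seed1):
    models, truth = panel_seed1
    matrix = growth_matrix(models, truth.panel)
    assert matrix.values == truth.growth.values
    assert matrix.row_labels == truth.growth.row_labels
    assert matrix.column_labels == truth.growth.column_labels


def test_producer_flags_on_worked_example(worked_example):
    model, envs, expected = worked_example
    for met, want in expected["producers_glucose"].items():
        assert producer_status(model, envs["glucose"], met) == want, met


def test_producer_requires_growth(worked_example):
    model, envs, _ = worked_example
    with pytest.raises(ValueError, match="does not grow"):
        producer_status(model, envs["empty"], "EX_ac_e")


def test_producer_zero_when_yield_limited(glucose_env):
    """When biomass fixation claims all carbon, a side product that would
    divert precursor cannot flow: its FVA maximum is exactly zero."""
    model = build_model(
        "closed",
        [
            ("EX_glc_e", {"glc_e": -1}, 0, 1000),
            ("T", {"glc_e": -1, "a": 1}, 0, 1000),
            ("BIOMASS", {"a": -1}, 0, 1000),
            ("LEAK", {"a": -1, "p_e": 1}, 0, 1000),
            ("EX_p_e", {"p_e": -1}, 0, 1000),
        ],
        "BIOMASS",
    )
    assert producer_status(model, glucose_env, "EX_p_e") == 0


def test_producer_threshold_is_monotone(worked_example):
    model, envs, _ = worked_example
    for met in ["EX_ac_e", "EX_lac_e", "EX_etoh_e"]:
        flags = [
            producer_status(model, envs["glucose"], met, producer_threshold=t)
            for t in (0.01, 1.0, 5.0, 10.0)
        ]
        assert flags == sorted(flags, reverse=True)


def test_producer_profile_recovers_planted_truth(panel_seed1):
    models, truth = panel_seed1
    profile = producer_profile(models, truth.panel, ["EX_ac_e", "EX_lac_e"])
    for m in models:
        for env, grew in zip(truth.panel, truth.growth.row(m.id)):
            ac = profile.get(m.id, env.name, "EX_ac_e")
            lac = profile.get(m.id, env.name, "EX_lac_e")
            if grew:
                assert (ac, lac) == (1, 1)
            else:
                assert ac is None and lac is None
    vectors = profile.as_vectors()
    assert set(map(tuple, vectors.values)) <= {
        tuple(v) for v in vectors.values
    }  # well-formed binary matrix
    assert all(v in (0, 1) for row in vectors.values for v in row)


def test_shunt_partition_conserved_vs_peripheral(panel_seed1):
    """Core-chain reactions carry flux in every growth environment; a
    peripheral degradation chain only in its own carbon environment."""
    models, truth = panel_seed1
    model = next(
        m for m in models if sum(truth.growth.row(m.id)) >= 3
    )  # strain with >=2 peripheral pathways
    peripheral = [
        r for r in model.reaction_ids
        if r.startswith("CS") and (r.endswith("deg") or r.endswith("t"))
    ]
    shunt_ids = CORE_CHAIN + ["GLCt"] + peripheral + ["MISSING_RXN"]
    part = classify_shunt_reactions(model, truth.panel, shunt_ids)
    for rid in CORE_CHAIN:
        assert rid in part.conserved, rid
    assert "GLCt" in part.non_conserved
    for rid in peripheral:
        assert rid in part.non_conserved, rid
    assert part.missing == {"MISSING_RXN"}
    assert part.conserved | part.non_conserved == set(shunt_ids) - {"MISSING_RXN"}


def test_shunt_partition_stable_under_environment_order(panel_seed1):
    models, truth = panel_seed1
    model = models[0]
    shunt_ids = CORE_CHAIN + ["GLCt", "LDH"]
    forward = classify_shunt_reactions(model, truth.panel, shunt_ids)
    reversed_panel = EnvironmentPanel(list(truth.panel)[::-1])
    backward = classify_shunt_reactions(model, reversed_panel, shunt_ids)
    assert forward.conserved == backward.conserved
    assert forward.non_conserved == backward.non_conserved


def test_pooled_partition_is_intersection_of_strains(panel_seed1):
    models, truth = panel_seed1
    shunt_ids = CORE_CHAIN + ["GLCt", "LDH", "PFL", "ADHE"]
    pooled = pooled_shunt_partition(models, truth.panel, shunt_ids)
    per_strain = [
        classify_shunt_reactions(m, truth.panel, shunt_ids) for m in models
    ]
    for rid in pooled.conserved:
        assert all(rid in p.conserved or rid in p.missing for p in per_strain)
    for rid in pooled.non_conserved:
        assert any(rid in p.non_conserved for p in per_strain)


def test_knockout_of_sole_biomass_feeder_kills_everywhere(panel_seed1):
    models, truth = panel_seed1
    scan = shunt_knockout_scan(models, truth.panel, ["FPK"])
    growth, _ = scan["FPK"]
    assert all(v == 0 for row in growth.values for v in row)


def test_knockout_of_one_duplicate_changes_nothing(panel_seed1):
    """Deleting one copy of a duplicated parallel route leaves the growth
    phenotype identical to wild type."""
    models, truth = panel_seed1
    model = next(m for m in models if m.has_reaction("PGK_alt"))
    wt = growth_matrix([model], truth.panel)
    scan = shunt_knockout_scan([model], truth.panel, ["PGK"])
    assert scan["PGK"][0].values == wt.values


def test_ldh_knockout_redirects_fermentation(worked_example):
    """Deleting lactate dehydrogenase keeps growth (the formate/ethanol fate
    absorbs the NADH) but turns the lactate flag off, acetate staying on."""
    model, envs, _ = worked_example
    panel = EnvironmentPanel([envs["glucose"]])
    scan = shunt_knockout_scan([model], panel, ["LDH"])
    growth, producers = scan["LDH"]
    assert growth.values == [[1]]
    assert producers.get(model.id, "glucose", "EX_ac_e") == 1
    assert producers.get(model.id, "glucose", "EX_lac_e") == 0


def test_knockout_never_increases_optimum(worked_example):
    model, envs, _ = worked_example
    conditioned = apply_environment(model, envs["glucose"])
    wt = fba(conditioned).objective_value
    for rid in ["LDH", "PFL", "ADHE", "GLCt", "ACK"]:
        sol = fba(conditioned.knock_out(rid))
        assert (not sol.optimal) or sol.objective_value <= wt + 1e-9


def test_phenotype_matrix_tsv_round_trip(tmp_path, panel_seed1):
    _, truth = panel_seed1
    path = tmp_path / "m.tsv"
    truth.growth.to_tsv(str(path))
    again = PhenotypeMatrix.from_tsv(str(path))
    assert again.values == truth.growth.values
    assert again.row_labels == truth.growth.row_labels


def test_phenotype_matrix_validation():
    with pytest.raises(ValueError):
        PhenotypeMatrix(row_labels=["a"], column_labels=["x"], values=[[2]])
    with pytest.raises(ValueError):
        PhenotypeMatrix(row_labels=["a"], column_labels=["x", "y"], values=[[1]])
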