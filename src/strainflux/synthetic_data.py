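"""Synthetic strain panels with planted, desk-checkable ground truth.

The generator emulates the structure the analysis pipeline assumes of a
bifidobacterial strain panel, at toy scale:

* a shared redox-balanced fermentative core modelled on the bifid shunt —
  hexose phosphate feeds a phosphoketolase split whose acetyl-phosphate
  branch yields ATP and (obligatorily) acetate, while the NADH formed in
  lower glycolysis is re-oxidized by either lactate dehydrogenase or the
  formate/ethanol branch (pyruvate-formate lyase plus alcohol
  dehydrogenase), with the named enzymes PGMT, PGM, PGK and RPE sitting on
  the sole default route to biomass;
* strain-specific presence/absence of peripheral carbon-utilization
  pathways, shared within planted strain groups, so each carbon source is
  usable only through its pathway;
* optional duplicated parallel reactions creating synthetic-lethal pairs;
* randomized auxotrophies for universal media components (a strain either
  synthesizes the component or must import it).

All planted facts — the growth matrix, acetate/lactate producer flags,
single and double lethal sets, group labels and auxotrophies — are derived
*structurally* from the construction, without solving any linear program, so
they are an independent oracle for the whole pipeline. ``verify=True``
additionally confirms them by exhaustive knockout enumeration.

Stoichiometries use small integer (or decimal) coefficients in a single
cytosolic compartment plus an external compartment; the realism is
topological (redundancy, peripheral pathways, redox coupling), not
biochemical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environments import (
    EnvironmentPanel,
    NutrientEnvironment,
    rich_environment,
    single_carbon_panel,
)
from .model_core import MetabolicModel, Metabolite, Reaction
from .phenotyping import PhenotypeMatrix

#: Core reactions that may receive a duplicated parallel copy.
DUPLICABLE_REACTIONS = ["PGK", "PGM", "PGMT", "PYK", "XPK"]

#: Interior core-chain reactions (single lethals when not duplicated).
CORE_CHAIN = ["PGMT", "PGI", "FPK", "RPE", "XPK", "ACK", "GAPD", "PGK", "PGM", "PYK"]

#: Fraction of one biomass unit drawn per universal component.
BIOMASS_COMPONENT_COEFF = 0.1


@dataclass(frozen=True)
class PanelSpec:
    """Design of one synthetic strain panel.

    Defaults give the panel used throughout the test suite: 6 strains in 3
    groups over 8 carbon-source environments, one duplicated parallel route
    per strain, two universal components with 50% auxotrophy.
    """

    n_strains: int = 6
    n_carbon_sources: int = 8
    n_groups: int = 3
    p_pathway: float = 0.5
    n_duplicated_routes: int = 1
    n_universal_components: int = 2
    p_auxotrophy: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "n_carbon_sources", "n_groups", "n_universal_components"):
            if getattr(self, name) < 1:
                raise ValueError(f"PanelSpec.{name} must be >= 1")
        if self.n_duplicated_routes < 0 or self.n_duplicated_routes > len(DUPLICABLE_REACTIONS):
            raise ValueError(
                f"n_duplicated_routes must be in [0, {len(DUPLICABLE_REACTIONS)}]"
            )
        for name in ("p_pathway", "p_auxotrophy"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"PanelSpec.{name} must be in [0, 1]")
        if self.n_groups > self.n_strains:
            raise ValueError("n_groups cannot exceed n_strains")


@dataclass
class PanelTruth:
    """Planted facts about a generated panel, structurally derived."""

    panel: EnvironmentPanel
    universal_components: list[str]
    growth: PhenotypeMatrix
    acetate_producers: PhenotypeMatrix
    lactate_producers: PhenotypeMatrix
    singles: dict[str, set[str]]
    doubles: dict[str, set[frozenset[str]]]
    group_labels: dict[str, int]
    auxotrophies: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Core shunt fragment
# ---------------------------------------------------------------------------


def _core_reaction_table() -> list[tuple[str, dict[str, float]]]:
    return [
        ("EX_glc_e", {"glc_e": -1}),
        ("GLCt", {"glc_e": -1, "g1p": 1}),
        ("PGMT", {"g1p": -1, "g6p": 1}),
        ("PGI", {"g6p": -1, "f6p": 1}),
        ("FPK", {"f6p": -1, "actp": 1, "ru5p": 1}),
        ("RPE", {"ru5p": -1, "x5p": 1}),
        ("XPK", {"x5p": -1, "actp": 1, "g3p": 1}),
        ("ACK", {"actp": -1, "adp": -1, "ac_e": 1, "atp": 1}),
        ("GAPD", {"g3p": -1, "nad": -1, "bpg": 1, "nadh": 1}),
        ("PGK", {"bpg": -1, "adp": -1, "p3g": 1, "atp": 1}),
        ("PGM", {"p3g": -1, "p2g": 1}),
        ("PYK", {"p2g": -1, "adp": -1, "pyr": 1, "atp": 1}),
        ("LDH", {"pyr": -1, "nadh": -1, "lac_e": 1, "nad": 1}),
        ("PFL", {"pyr": -1, "for_e": 1, "acald": 1}),
        ("ADHE", {"acald": -1, "nadh": -1, "etoh_e": 1, "nad": 1}),
        ("EX_ac_e", {"ac_e": -1}),
        ("EX_lac_e", {"lac_e": -1}),
        ("EX_etoh_e", {"etoh_e": -1}),
        ("EX_for_e", {"for_e": -1}),
    ]


def _metabolites_for(stoichs: list[dict[str, float]]) -> list[Metabolite]:
    seen: list[str] = []
    for st in stoichs:
        for mid in st:
            if mid not in seen:
                seen.append(mid)
    return [
        Metabolite(id=mid, compartment="e" if mid.endswith("_e") else "c")
        for mid in seen
    ]


def _reaction(rid: str, stoich: dict[str, float]) -> Reaction:
    exchange = rid.startswith("EX_")
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=-1000.0 if exchange and rid == "EX_glc_e" else 0.0,
        upper_bound=1000.0,
        is_exchange=exchange,
    )


def generate_core_shunt(strain_id: str = "core_shunt") -> MetabolicModel:
    """The redox-balanced core as a free-standing model.

    Glucose enters as glucose-1-phosphate and reaches F6P via PGMT and PGI;
    the biomass reaction drains F6P plus 2 ATP. Per unit F6P routed through
    the shunt, the phosphoketolase split (FPK, RPE, XPK) yields two
    acetyl-phosphate and one G3P; acetate kinase converts acetyl-phosphate to
    acetate with ATP gain, and lower glycolysis (GAPD, PGK, PGM, PYK) yields
    pyruvate, two ATP and one NADH. Pyruvate and NADH are consumed 1:1 by
    lactate dehydrogenase, or equivalently by pyruvate-formate lyase plus
    alcohol dehydrogenase (formate + ethanol out). At maximal growth on 10
    glucose the optimum is 20/3: acetate secretion is forced at 20/3, and a
    total of 10/3 pyruvate is split freely between the lactate and
    formate/ethanol fates.
    """
    table = _core_reaction_table()
    reactions = [_reaction(rid, st) for rid, st in table]
    biomass = Reaction(
        id="BIOMASS",
        stoichiometry={"f6p": -1, "atp": -2, "adp": 2},
        lower_bound=0.0,
        upper_bound=1000.0,
    )
    reactions.append(biomass)
    return MetabolicModel(
        id=strain_id,
        metabolites=_metabolites_for([st for _, st in table] + [biomass.stoichiometry]),
        reactions=reactions,
        objective_reaction_id="BIOMASS",
    )


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------


def _carbon_ids(n: int) -> list[str]:
    """Exchange ids of the carbon sources; index 0 is glucose, which every
    strain can use (pathway possession applies to the rest)."""
    return ["EX_glc_e"] + [f"EX_cs{k}_e" for k in range(1, n)]


def _group_signatures(
    rng: np.random.Generator, n_groups: int, n_extra_carbons: int, p_pathway: float
) -> list[np.ndarray]:
    """Per-group possession vectors over the non-glucose carbons, re-drawn
    until pairwise distinct so planted groups are separable."""
    if n_groups > 1 and 2**n_extra_carbons < n_groups:
        raise ValueError(
            f"{n_extra_carbons} non-glucose carbon sources cannot separate "
            f"{n_groups} groups"
        )
    signatures: list[np.ndarray] = []
    for _ in range(n_groups):
        for _attempt in range(1000):
            sig = (rng.random(n_extra_carbons) < p_pathway).astype(int)
            if not any(np.array_equal(sig, s) for s in signatures):
                signatures.append(sig)
                break
        else:
            raise ValueError(
                "could not draw distinct group pathway signatures; "
                "raise n_carbon_sources or move p_pathway away from 0/1"
            )
    return signatures


def _build_strain(
    strain_id: str,
    possessed_carbons: list[str],
    duplicated: list[str],
    universal_components: list[str],
    auxotrophic: set[str],
) -> MetabolicModel:
    table = _core_reaction_table()
    stoichs = [st for _, st in table]
    reactions = [_reaction(rid, st) for rid, st in table]

    for ex_id in possessed_carbons:
        if ex_id == "EX_glc_e":
            continue  # glucose pathway is part of the core
        tag = ex_id[len("EX_"):-len("_e")]
        chain = [
            (ex_id, {f"{tag}_e": -1}),
            (f"{tag.upper()}t", {f"{tag}_e": -1, tag: 1}),
            (f"{tag.upper()}deg", {tag: -1, "g1p": 2}),
        ]
        for rid, st in chain:
            stoichs.append(st)
            reactions.append(_reaction(rid, st))

    biomass_stoich: dict[str, float] = {"f6p": -1, "atp": -2, "adp": 2}
    for comp in universal_components:
        tag = comp[len("EX_"):-len("_e")]
        uptake_chain = [
            (comp, {f"{tag}_e": -1}),
            (f"{tag.upper()}t", {f"{tag}_e": -1, tag: 1}),
        ]
        if comp not in auxotrophic:
            uptake_chain.append((f"{tag.upper()}syn", {"f6p": -1, tag: 1}))
        for rid, st in uptake_chain:
            stoichs.append(st)
            reactions.append(_reaction(rid, st))
        biomass_stoich[tag] = -BIOMASS_COMPONENT_COEFF

    for rid in duplicated:
        base = next(r for r in reactions if r.id == rid)
        reactions.append(
            Reaction(
                id=f"{rid}_alt",
                stoichiometry=dict(base.stoichiometry),
                lower_bound=base.lower_bound,
                upper_bound=base.upper_bound,
                name=f"duplicated parallel copy of {rid}",
            )
        )

    biomass = Reaction(
        id="BIOMASS", stoichiometry=biomass_stoich, lower_bound=0.0, upper_bound=1000.0
    )
    reactions.append(biomass)
    return MetabolicModel(
        id=strain_id,
        metabolites=_metabolites_for(stoichs + [biomass_stoich]),
        reactions=reactions,
        objective_reaction_id="BIOMASS",
    )


def _planted_lethals(
    possessed_carbons: list[str],
    duplicated: list[str],
    universal_components: list[str],
    auxotrophic: set[str],
) -> tuple[set[str], set[frozenset[str]]]:
    """Structural single/double lethal sets in the rich environment."""
    singles = {r for r in CORE_CHAIN if r not in duplicated}
    doubles = {frozenset((r, f"{r}_alt")) for r in duplicated}
    # pyruvate's two fates: lactate vs formate+ethanol; LDH paired with either
    # step of the alternative branch is jointly lethal
    doubles.add(frozenset(("LDH", "PFL")))
    doubles.add(frozenset(("LDH", "ADHE")))
    if len(possessed_carbons) == 1:
        singles.add("GLCt")
    elif len(possessed_carbons) == 2:
        other = next(c for c in possessed_carbons if c != "EX_glc_e")
        tag = other[len("EX_"):-len("_e")].upper()
        doubles |= {
            frozenset(("GLCt", f"{tag}t")),
            frozenset(("GLCt", f"{tag}deg")),
        }
    for comp in universal_components:
        tag = comp[len("EX_"):-len("_e")].upper()
        if comp in auxotrophic:
            singles.add(f"{tag}t")
        else:
            doubles.add(frozenset((f"{tag}syn", f"{tag}t")))
    return singles, doubles


def generate_panel(
    spec: PanelSpec, verify: bool = False
) -> tuple[list[MetabolicModel], PanelTruth]:
    """Generate the strain models and their planted truth.

    Fully reproducible from ``spec.seed``. With ``verify=True`` the planted
    single/double lethal sets are checked against exhaustive knockout
    enumeration (intended for small panels; it solves O(n^2) LPs per strain).
    """
    rng = np.random.default_rng(spec.seed)
    carbons = _carbon_ids(spec.n_carbon_sources)
    universal = [f"EX_aa{j}_e" for j in range(spec.n_universal_components)]
    signatures = _group_signatures(
        rng, spec.n_groups, spec.n_carbon_sources - 1, spec.p_pathway
    )
    group_labels = {
        f"strain_{i}": i % spec.n_groups for i in range(spec.n_strains)
    }

    models: list[MetabolicModel] = []
    growth_rows: list[list[int]] = []
    singles: dict[str, set[str]] = {}
    doubles: dict[str, set[frozenset[str]]] = {}
    auxotrophies: dict[str, set[str]] = {}
    for i in range(spec.n_strains):
        sid = f"strain_{i}"
        sig = signatures[group_labels[sid]]
        possessed = ["EX_glc_e"] + [
            carbons[k + 1] for k in range(spec.n_carbon_sources - 1) if sig[k]
        ]
        duplicated = sorted(
            rng.choice(
                DUPLICABLE_REACTIONS, size=spec.n_duplicated_routes, replace=False
            ).tolist()
        )
        auxo = {c for c in universal if rng.random() < spec.p_auxotrophy}
        models.append(_build_strain(sid, possessed, duplicated, universal, auxo))
        growth_rows.append([int(c in possessed) for c in carbons])
        s, d = _planted_lethals(possessed, duplicated, universal, auxo)
        singles[sid], doubles[sid] = s, d
        auxotrophies[sid] = auxo

    panel = single_carbon_panel(carbons, universal=universal)
    strain_ids = [m.id for m in models]
    growth = PhenotypeMatrix(
        row_labels=strain_ids, column_labels=panel.names, values=growth_rows
    )
    # the shunt construction forces both acetate and lactate secretion at
    # maximal growth wherever the strain grows at all
    producers = PhenotypeMatrix(
        row_labels=strain_ids, column_labels=panel.names, values=growth_rows
    )
    truth = PanelTruth(
        panel=panel,
        universal_components=universal,
        growth=growth,
        acetate_producers=producers,
        lactate_producers=PhenotypeMatrix(
            row_labels=strain_ids, column_labels=panel.names, values=growth_rows
        ),
        singles=singles,
        doubles=doubles,
        group_labels=group_labels,
        auxotrophies=auxotrophies,
    )
    if verify:
        _verify_truth(models, truth)
    return models, truth


def _verify_truth(models: list[MetabolicModel], truth: PanelTruth) -> None:
    from .lethality import brute_force_double_lethals, brute_force_single_lethals

    rich = rich_environment(truth.panel)
    for model in models:
        bs = brute_force_single_lethals(model, rich)
        if bs != truth.singles[model.id]:
            raise AssertionError(
                f"planted singles for {model.id} disagree with enumeration: "
                f"planted {sorted(truth.singles[model.id])}, found {sorted(bs)}"
            )
        bd = brute_force_double_lethals(model, rich, singles=bs)
        if bd != truth.doubles[model.id]:
            raise AssertionError(
                f"planted doubles for {model.id} disagree with enumeration"
            )


def random_strain(seed: int) -> tuple[MetabolicModel, NutrientEnvironment]:
    """One randomized strain plus its rich environment, for oracle tests.

    Panel parameters themselves are drawn from the seed, so consecutive
    seeds exercise different pathway counts, duplications and auxotrophies.
    """
    rng = np.random.default_rng(seed)
    spec = PanelSpec(
        n_strains=1,
        n_carbon_sources=int(rng.integers(3, 7)),
        n_groups=1,
        p_pathway=float(rng.uniform(0.3, 0.9)),
        n_duplicated_routes=int(rng.integers(0, 3)),
        n_universal_components=int(rng.integers(1, 3)),
        p_auxotrophy=0.5,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    models, truth = generate_panel(spec)
    return models[0], rich_environment(truth.panel)


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------


def worked_example_fixture() -> tuple[MetabolicModel, dict[str, NutrientEnvironment], dict]:
    """The core shunt strain with hand-computed expectations.

    On 10 glucose the LP optimum is 20/3 (F6P splits 2:1 between biomass and
    the ATP-yielding shunt); acetate secretion is forced at 20/3, while the
    10/3 of pyruvate may go to lactate or to formate + ethanol, so all four
    products are producer-positive and lactate's flux range is [0, 10/3].
    Every interior core reaction except the three fermentative-fate steps is
    a single lethal; pairing LDH with either step of the alternative fate
    (PFL or ADHE) is jointly lethal.
    """
    model = generate_core_shunt("worked_example")
    glucose = NutrientEnvironment(name="glucose", carbon_uptakes={"EX_glc_e": 10.0})
    empty = NutrientEnvironment(name="empty")
    expected = {
        "fba_optimum_glucose": 20.0 / 3.0,
        "producers_glucose": {
            "EX_ac_e": 1,
            "EX_lac_e": 1,
            "EX_etoh_e": 1,
            "EX_for_e": 1,
            "EX_succ_e": 0,
        },
        "acetate_flux_range_glucose": (20.0 / 3.0, 20.0 / 3.0),
        "lactate_flux_range_glucose": (0.0, 10.0 / 3.0),
        "single_lethals_glucose": set(CORE_CHAIN) | {"GLCt"},
        "double_lethals_glucose": {
            frozenset(("LDH", "PFL")),
            frozenset(("LDH", "ADHE")),
        },
        "grows_empty": 0,
    }
    return model, {"glucose": glucose, "empty": empty}, expected
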