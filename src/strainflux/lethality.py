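"""Single and double reaction lethality via Fast-SL search-space reduction.

A reaction is a *single lethal* (essential) if deleting it alone drops the
FBA optimum below ``cutoff_fraction`` (default 1%) of the wild-type growth
rate; a *double lethal* is an unordered pair of individually non-lethal
reactions whose joint deletion does. Exchange reactions and the biomass
reaction are never deletion candidates.

The Fast-SL reduction avoids scanning all reactions and all C(n,2) pairs:
any flux distribution v0 meeting the growth cutoff is a feasibility witness,
so a reaction outside supp(v0) cannot be a single lethal, and a pair disjoint
from supp(v0) cannot be a double lethal. Taking v0 as the L1-minimal flux
distribution keeps the witness support small. For doubles, each candidate
first member i is drawn from supp(v0); the second member is drawn from the
support of the minimal-norm solution of the i-deleted model, which any
lethal partner of i must intersect. The result is provably identical to
exhaustive enumeration, which :func:`brute_force_single_lethals` /
:func:`brute_force_double_lethals` provide as the independent oracle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .environments import NutrientEnvironment, apply_environment
from .lp_engine import FLUX_TOL, GROWTH_THRESHOLD, fba, minimal_support_solution
from .model_core import MetabolicModel
from .phenotyping import PhenotypeMatrix

logger = logging.getLogger(__name__)

#: Deletion counts as lethal when growth falls below this fraction of wild type.
LETHALITY_CUTOFF_FRACTION = 0.01


@dataclass
class LethalSets:
    """Minimal single and double lethal reaction sets of one strain."""

    singles: set[str]
    doubles: set[frozenset[str]]
    cutoff_fraction: float = LETHALITY_CUTOFF_FRACTION

    def __post_init__(self) -> None:
        for pair in self.doubles:
            if len(pair) != 2:
                raise ValueError(f"double lethal {set(pair)} is not a pair")
            if pair & self.singles:
                raise ValueError(
                    f"pair {sorted(pair)} contains a single lethal; doubles must "
                    "be minimal"
                )

    def doubles_as_sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self.doubles)

    def to_tsv(self, singles_path: str, doubles_path: str) -> None:
        with open(singles_path, "w") as fh:
            for rid in sorted(self.singles):
                fh.write(rid + "\n")
        pd.DataFrame(
            self.doubles_as_sorted_pairs(), columns=["reaction_1", "reaction_2"]
        ).to_csv(doubles_path, sep="\t", index=False)


@dataclass
class CoreEssentialSet:
    """Reactions essential in every strain and present in every strain."""

    reactions: set[str]


def deletion_candidates(model: MetabolicModel) -> list[str]:
    """Non-exchange, non-biomass reactions, in model order."""
    return [
        r.id
        for r in model.reactions
        if not r.is_exchange and r.id != model.objective_reaction_id
    ]


def _wild_type_growth(model: MetabolicModel, env: NutrientEnvironment) -> tuple[MetabolicModel, float]:
    conditioned = apply_environment(model, env)
    sol = fba(conditioned)
    if not (sol.optimal and sol.objective_value > GROWTH_THRESHOLD):
        raise ValueError(
            f"strain {model.id!r} does not grow in environment {env.name!r}; "
            "lethality is undefined"
        )
    return conditioned, sol.objective_value


def _lethal(conditioned: MetabolicModel, rxns: list[str], threshold: float) -> bool:
    sol = fba(conditioned.knock_out(rxns))
    return (not sol.optimal) or sol.objective_value < threshold


def single_lethals(
    model: MetabolicModel,
    env: NutrientEnvironment,
    cutoff_fraction: float = LETHALITY_CUTOFF_FRACTION,
    flux_tol: float = FLUX_TOL,
) -> set[str]:
    """Essential reactions of one strain in one environment (Fast-SL).

    Candidates are restricted to the support of the L1-minimal flux
    distribution meeting the growth cutoff; each is confirmed by deletion.
    """
    conditioned, wt = _wild_type_growth(model, env)
    threshold = cutoff_fraction * wt
    v0 = minimal_support_solution(conditioned, biomass_fraction=cutoff_fraction)
    candidates = set(deletion_candidates(conditioned)) & v0.support(flux_tol)
    return {rid for rid in sorted(candidates) if _lethal(conditioned, [rid], threshold)}


def double_lethals(
    model: MetabolicModel,
    env: NutrientEnvironment,
    singles: set[str] | None = None,
    cutoff_fraction: float = LETHALITY_CUTOFF_FRACTION,
    flux_tol: float = FLUX_TOL,
) -> set[frozenset[str]]:
    """Minimal synthetic-lethal pairs of one strain in one environment.

    For each first member i in the wild-type witness support (minus singles),
    the i-deleted model is re-solved for a minimal-norm witness whose support
    (minus singles) supplies the candidate partners j; the pair is confirmed
    by joint deletion. Equivalent to exhaustive pair enumeration.
    """
    conditioned, wt = _wild_type_growth(model, env)
    threshold = cutoff_fraction * wt
    if singles is None:
        singles = single_lethals(model, env, cutoff_fraction, flux_tol)
    allowed = set(deletion_candidates(conditioned)) - singles
    v0 = minimal_support_solution(conditioned, biomass_fraction=cutoff_fraction)
    first_members = sorted(v0.support(flux_tol) & allowed)
    doubles: set[frozenset[str]] = set()
    for i in first_members:
        deleted = conditioned.knock_out(i)
        # i is not a single lethal, so the deleted model still meets the cutoff
        vi = minimal_support_solution(deleted, biomass_fraction=cutoff_fraction * wt / fba(deleted).objective_value)
        partners = (vi.support(flux_tol) & allowed) - {i}
        for j in sorted(partners):
            pair = frozenset((i, j))
            if pair in doubles:
                continue
            if _lethal(conditioned, [i, j], threshold):
                doubles.add(pair)
    return doubles


def lethal_sets(
    model: MetabolicModel,
    env: NutrientEnvironment,
    cutoff_fraction: float = LETHALITY_CUTOFF_FRACTION,
) -> LethalSets:
    singles = single_lethals(model, env, cutoff_fraction)
    doubles = double_lethals(model, env, singles=singles, cutoff_fraction=cutoff_fraction)
    return LethalSets(singles=singles, doubles=doubles, cutoff_fraction=cutoff_fraction)


# ---------------------------------------------------------------------------
# Exhaustive oracles (used by tests and by synthetic-panel ground truth)
# ---------------------------------------------------------------------------


def brute_force_single_lethals(
    model: MetabolicModel,
    env: NutrientEnvironment,
    cutoff_fraction: float = LETHALITY_CUTOFF_FRACTION,
) -> set[str]:
    """One-at-a-time deletion over every candidate reaction."""
    conditioned, wt = _wild_type_growth(model, env)
    threshold = cutoff_fraction * wt
    return {
        rid
        for rid in deletion_candidates(conditioned)
        if _lethal(conditioned, [rid], threshold)
    }


def brute_force_double_lethals(
    model: MetabolicModel,
    env: NutrientEnvironment,
    singles: set[str] | None = None,
    cutoff_fraction: float = LETHALITY_CUTOFF_FRACTION,
) -> set[frozenset[str]]:
    """All C(n,2) joint deletions over individually non-lethal candidates."""
    conditioned, wt = _wild_type_growth(model, env)
    threshold = cutoff_fraction * wt
    if singles is None:
        singles = brute_force_single_lethals(model, env, cutoff_fraction)
    allowed = [r for r in deletion_candidates(conditioned) if r not in singles]
    return {
        frozenset((i, j))
        for i, j in itertools.combinations(allowed, 2)
        if _lethal(conditioned, [i, j], threshold)
    }


# ---------------------------------------------------------------------------
# Panel-level screens
# ---------------------------------------------------------------------------


@dataclass
class RichScreenResult:
    """Per-strain lethal sets on the rich environment, with the cross-strain
    union of single lethals and the binary lethality vectors over it."""

    per_strain: dict[str, LethalSets]
    skipped: list[str] = field(default_factory=list)

    @property
    def singles_union(self) -> set[str]:
        out: set[str] = set()
        for ls in self.per_strain.values():
            out |= ls.singles
        return out

    @property
    def singles_and_double_members_union(self) -> set[str]:
        """Union of single lethals plus every reaction participating in a
        double-lethal pair (the broader reading of "essential")."""
        out = self.singles_union
        for ls in self.per_strain.values():
            for pair in ls.doubles:
                out |= pair
        return out

    def lethality_vectors(self) -> PhenotypeMatrix:
        columns = sorted(self.singles_union)
        strains = list(self.per_strain)
        values = [
            [int(c in self.per_strain[s].singles) for c in columns] for s in strains
        ]
        return PhenotypeMatrix(row_labels=strains, column_labels=columns, values=values)


def rich_lethality_screen(
    models: list[MetabolicModel],
    rich_env: NutrientEnvironment,
    cutoff_fraction: float = LETHALITY_CUTOFF_FRACTION,
) -> RichScreenResult:
    """Fast-SL singles and doubles per strain on the rich environment.

    Strains that do not grow in the rich environment are skipped with a
    logged notice and listed in ``skipped``.
    """
    per_strain: dict[str, LethalSets] = {}
    skipped: list[str] = []
    for model in models:
        try:
            per_strain[model.id] = lethal_sets(model, rich_env, cutoff_fraction)
        except ValueError:
            logger.warning(
                "strain %s does not grow in %s; skipped from lethality screen",
                model.id, rich_env.name,
            )
            skipped.append(model.id)
    return RichScreenResult(per_strain=per_strain, skipped=skipped)


def core_essential(
    per_strain_singles: dict[str, set[str]],
    per_strain_reaction_sets: dict[str, set[str]],
) -> CoreEssentialSet:
    """Reactions present in every strain and essential in every strain."""
    if not per_strain_singles:
        raise ValueError("core_essential: no strains given")
    if set(per_strain_singles) != set(per_strain_reaction_sets):
        raise ValueError(
            "core_essential: strain keys of singles and reaction sets differ"
        )
    strains = list(per_strain_singles)
    core = set.intersection(*(per_strain_reaction_sets[s] for s in strains))
    core &= set.intersection(*(per_strain_singles[s] for s in strains))
    return CoreEssentialSet(reactions=core)


def pgx_essentiality_heatmap(
    models: list[MetabolicModel],
    panel,
    target_ids: list[str] = ("PGK", "PGM", "PGMT"),
    growth_threshold: float = GROWTH_THRESHOLD,
) -> pd.DataFrame:
    """Strain x target matrix of survival counts: in how many panel
    environments each strain still grows after deleting the target alone."""
    from .phenotyping import shunt_knockout_scan

    scan = shunt_knockout_scan(
        models, panel, list(target_ids), growth_threshold=growth_threshold
    )
    data = {
        target: [sum(growth.row(m.id)) for m in models]
        for target, (growth, _) in scan.items()
    }
    return pd.DataFrame(data, index=[m.id for m in models])[list(target_ids)]
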