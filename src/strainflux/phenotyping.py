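"""Strain phenotyping: growth matrices, SCFA producer calling, flux
conservation of the bifid-shunt reactions, and targeted knockout scans.

Growth is binary: a strain grows in an environment iff the FBA optimum
exceeds the growth threshold (1e-6 mmol/gDW/h, solver-tolerance scale). A
strain is a producer of a fermentation end-product (acetate, lactate,
ethanol, formate, succinate) in an environment iff, with biomass pinned at
its maximum, the FVA maximum of the product's exchange flux exceeds
0.01 mmol/gDW/h — a capability criterion, not obligate secretion; exact ties
at the threshold count as non-producers.

Bifid-shunt reactions are partitioned into *conserved* (able to carry flux in
every growth-supporting environment) and *non-conserved* (environment-
specific) sets, and single-reaction knockouts of chosen targets are scanned
across all environments with growth and acetate/lactate readouts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .environments import EnvironmentPanel, NutrientEnvironment, apply_environment
from .lp_engine import FLUX_TOL, GROWTH_THRESHOLD, LPError, fba, fva
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

#: FVA flux above which a strain counts as producing a metabolite (mmol/gDW/h).
PRODUCER_THRESHOLD = 0.01

#: The five fermentation end-products scored by default, as exchange ids.
DEFAULT_SCFA_EXCHANGES = ["EX_ac_e", "EX_lac_e", "EX_etoh_e", "EX_for_e", "EX_succ_e"]


@dataclass
class PhenotypeMatrix:
    """Binary strains x conditions matrix."""

    row_labels: list[str]
    column_labels: list[str]
    values: list[list[int]]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.row_labels):
            raise ValueError("row count does not match row labels")
        for row in self.values:
            if len(row) != len(self.column_labels):
                raise ValueError("column count does not match column labels")
            if any(v not in (0, 1) for v in row):
                raise ValueError("phenotype values must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.column_labels, dtype=int
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="strain")

    @classmethod
    def from_tsv(cls, path: str) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(
            row_labels=[str(i) for i in df.index],
            column_labels=[str(c) for c in df.columns],
            values=df.astype(int).values.tolist(),
        )

    def row(self, label: str) -> list[int]:
        return self.values[self.row_labels.index(label)]


@dataclass
class ProducerProfile:
    """Binary producer flags per (strain, environment, metabolite exchange).

    Flags exist only where the strain grows; :meth:`as_vectors` flattens each
    strain to one binary vector over (environment x metabolite), encoding
    absent growth as 0, which is the clustering input.
    """

    strains: list[str]
    environments: list[str]
    metabolites: list[str]
    flags: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def get(self, strain: str, environment: str, metabolite: str) -> int | None:
        return self.flags.get((strain, environment, metabolite))

    def as_vectors(self) -> PhenotypeMatrix:
        columns = [
            f"{env}|{met}"
            for env, met in itertools.product(self.environments, self.metabolites)
        ]
        values = [
            [
                self.flags.get((strain, env, met), 0)
                for env, met in itertools.product(self.environments, self.metabolites)
            ]
            for strain in self.strains
        ]
        return PhenotypeMatrix(
            row_labels=list(self.strains), column_labels=columns, values=values
        )

    def to_tsv(self, path: str) -> None:
        rows = [
            (s, e, m, flag) for (s, e, m), flag in sorted(self.flags.items())
        ]
        pd.DataFrame(
            rows, columns=["strain", "environment", "metabolite", "producer"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ShuntPartition:
    """Conserved vs non-conserved split of the shunt reactions present in a
    model (or pooled over a panel of models)."""

    conserved: set[str]
    non_conserved: set[str]
    missing: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.conserved & self.non_conserved:
            raise ValueError("conserved and non-conserved sets must be disjoint")


def grows(
    model: MetabolicModel,
    env: NutrientEnvironment,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> int:
    """1 iff the strain's FBA optimum in the environment exceeds the growth
    threshold. Solver failures raise; they are never reported as no-growth."""
    sol = fba(apply_environment(model, env))
    if sol.status == "unbounded":
        raise LPError(f"unbounded FBA for model {model.id!r} in {env.name!r}")
    return int(sol.optimal and sol.objective_value > growth_threshold)


def growth_matrix(
    models: list[MetabolicModel],
    panel: EnvironmentPanel,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> PhenotypeMatrix:
    """Binary growth phenotype over strains x environments, in input order."""
    if not models or len(panel) == 0:
        raise ValueError("growth_matrix needs at least one model and one environment")
    values = [
        [grows(m, env, growth_threshold) for env in panel] for m in models
    ]
    return PhenotypeMatrix(
        row_labels=[m.id for m in models], column_labels=panel.names, values=values
    )


def producer_status(
    model: MetabolicModel,
    env: NutrientEnvironment,
    metabolite_exchange: str,
    producer_threshold: float = PRODUCER_THRESHOLD,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> int:
    """1 iff the FVA maximum of the product's exchange flux, with biomass
    pinned at its optimum, strictly exceeds the producer threshold."""
    conditioned = apply_environment(model, env)
    sol = fba(conditioned)
    if not (sol.optimal and sol.objective_value > growth_threshold):
        raise ValueError(
            f"producer_status: strain {model.id!r} does not grow in {env.name!r}"
        )
    if not model.has_reaction(metabolite_exchange):
        logger.info(
            "model %s has no exchange %s; scored as non-producer",
            model.id, metabolite_exchange,
        )
        return 0
    rng = fva(conditioned, [metabolite_exchange], biomass_fraction=1.0)
    _, vmax = rng[metabolite_exchange]
    return int(vmax > producer_threshold)


def producer_profile(
    models: list[MetabolicModel],
    panel: EnvironmentPanel,
    metabolite_exchanges: list[str] | None = None,
    producer_threshold: float = PRODUCER_THRESHOLD,
    growth_threshold: float = GROWTH_THRESHOLD,
    growth: PhenotypeMatrix | None = None,
) -> ProducerProfile:
    """Producer flags for every growing (strain, environment) pair.

    ``growth`` may pass a precomputed growth matrix to avoid re-solving."""
    if metabolite_exchanges is None:
        metabolite_exchanges = list(DEFAULT_SCFA_EXCHANGES)
    if growth is None:
        growth = growth_matrix(models, panel, growth_threshold)
    profile = ProducerProfile(
        strains=[m.id for m in models],
        environments=panel.names,
        metabolites=list(metabolite_exchanges),
    )
    for m in models:
        bits = growth.row(m.id)
        for env, bit in zip(panel, bits):
            if not bit:
                continue
            for met in metabolite_exchanges:
                profile.flags[(m.id, env.name, met)] = producer_status(
                    m, env, met, producer_threshold, growth_threshold
                )
    return profile


def classify_shunt_reactions(
    model: MetabolicModel,
    panel: EnvironmentPanel,
    shunt_ids: list[str],
    flux_tol: float = FLUX_TOL,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> ShuntPartition:
    """Partition the shunt reactions of one strain.

    A reaction is conserved iff in *every* panel environment where the strain
    grows its FVA range (biomass pinned at optimum) shows flux capability
    (max(|min|, |max|) above tolerance); otherwise non-conserved. Shunt ids
    absent from the model are excluded and reported in ``missing``.
    """
    present = [rid for rid in shunt_ids if model.has_reaction(rid)]
    missing = set(shunt_ids) - set(present)
    if missing:
        logger.info("model %s lacks shunt reactions %s", model.id, sorted(missing))
    can_carry: dict[str, bool] = {rid: True for rid in present}
    any_growth = False
    for env in panel:
        conditioned = apply_environment(model, env)
        sol = fba(conditioned)
        if not (sol.optimal and sol.objective_value > growth_threshold):
            continue
        any_growth = True
        rng = fva(conditioned, present, biomass_fraction=1.0)
        for rid in present:
            if not rng.carries_flux(rid, flux_tol):
                can_carry[rid] = False
    if not any_growth:
        raise ValueError(
            f"strain {model.id!r} grows in no panel environment; shunt "
            "classification undefined"
        )
    conserved = {rid for rid in present if can_carry[rid]}
    return ShuntPartition(
        conserved=conserved,
        non_conserved=set(present) - conserved,
        missing=missing,
    )


def pooled_shunt_partition(
    models: list[MetabolicModel],
    panel: EnvironmentPanel,
    shunt_ids: list[str],
    flux_tol: float = FLUX_TOL,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> ShuntPartition:
    """Pooled mode: a shunt reaction is conserved iff it is conserved in every
    strain that carries it (i.e. it can carry flux across all strain x
    environment growth combinations)."""
    conserved: set[str] = set()
    non_conserved: set[str] = set()
    missing = set(shunt_ids)
    for model in models:
        part = classify_shunt_reactions(
            model, panel, shunt_ids, flux_tol, growth_threshold
        )
        non_conserved |= part.non_conserved
        conserved |= part.conserved
        missing &= part.missing
    conserved -= non_conserved
    return ShuntPartition(
        conserved=conserved, non_conserved=non_conserved, missing=missing
    )


def shunt_knockout_scan(
    models: list[MetabolicModel],
    panel: EnvironmentPanel,
    target_ids: list[str],
    metabolite_exchanges: tuple[str, str] = ("EX_ac_e", "EX_lac_e"),
    producer_threshold: float = PRODUCER_THRESHOLD,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> dict[str, tuple[PhenotypeMatrix, ProducerProfile]]:
    """Single knockouts of each target across all strains and environments.

    A knockout pins both bounds of the reaction to zero. Returns, per target,
    the post-knockout growth matrix and the acetate/lactate producer profile.
    Row sums of the growth matrix give per-strain survival counts (the
    essentiality heatmap data).
    """
    carried = {t for t in target_ids if any(m.has_reaction(t) for m in models)}
    absent = set(target_ids) - carried
    if absent:
        raise ValueError(f"knockout targets present in no model: {sorted(absent)}")
    out: dict[str, tuple[PhenotypeMatrix, ProducerProfile]] = {}
    for target in target_ids:
        ko_models = [
            m.knock_out(target) if m.has_reaction(target) else m for m in models
        ]
        growth = growth_matrix(ko_models, panel, growth_threshold)
        producers = producer_profile(
            ko_models,
            panel,
            list(metabolite_exchanges),
            producer_threshold,
            growth_threshold,
            growth=growth,
        )
        out[target] = (growth, producers)
    return out
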