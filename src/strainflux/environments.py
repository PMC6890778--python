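"""Nutrient environments: single-carbon media, class media, the rich
environment, and derivation of the universal media.

An environment names the exchange reactions a strain may take up and at what
rate. Applying it to a model opens the listed uptakes (lower bound set to
minus the rate: carbon sources at 10 mmol/gDW/h, universal components —
vitamins, amino acids, ions every strain may draw on — at 1 mmol/gDW/h) and
closes every other uptake; secretion bounds are untouched. A strain that
lacks an exchange named by the environment simply cannot import that
nutrient, so missing exchanges are skipped with a logged notice rather than
treated as errors.

The universal media is derived by leave-one-out essentiality: a candidate
component belongs to the universal media iff at least one strain stops
growing (on the reference carbon source, glucose by default) when that one
component is withheld.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .lp_engine import GROWTH_THRESHOLD, fba
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

#: Default uptake rates in mmol/gDW/h.
CARBON_UPTAKE_RATE = 10.0
UNIVERSAL_UPTAKE_RATE = 1.0


@dataclass(frozen=True)
class NutrientEnvironment:
    """A named medium: carbon uptakes plus universal-component uptakes,
    keyed by exchange-reaction id, rates in mmol/gDW/h (positive)."""

    name: str
    carbon_uptakes: dict[str, float] = field(default_factory=dict)
    universal_uptakes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.carbon_uptakes) & set(self.universal_uptakes)
        if overlap:
            raise ValueError(
                f"environment {self.name!r}: exchanges listed as both carbon and "
                f"universal: {sorted(overlap)}"
            )
        for rid, rate in {**self.carbon_uptakes, **self.universal_uptakes}.items():
            if rate <= 0:
                raise ValueError(
                    f"environment {self.name!r}: uptake rate for {rid!r} must be "
                    f"positive (got {rate})"
                )

    @property
    def uptakes(self) -> dict[str, float]:
        return {**self.carbon_uptakes, **self.universal_uptakes}


@dataclass
class EnvironmentPanel:
    """Ordered collection of environments (one per carbon source)."""

    environments: list[NutrientEnvironment]

    def __post_init__(self) -> None:
        names = [e.name for e in self.environments]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate environment names: {dupes}")

    def __iter__(self):
        return iter(self.environments)

    def __len__(self) -> int:
        return len(self.environments)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.environments]

    def carbon_exchange_ids(self) -> list[str]:
        seen: list[str] = []
        for env in self.environments:
            for rid in env.carbon_uptakes:
                if rid not in seen:
                    seen.append(rid)
        return seen


def apply_environment(
    model: MetabolicModel, env: NutrientEnvironment
) -> MetabolicModel:
    """Return a copy of the model constrained to the environment.

    Every exchange reaction's lower bound becomes -(rate) if the exchange is
    listed (carbon or universal), else 0; upper (secretion) bounds are left
    unchanged. Idempotent.
    """
    uptakes = env.uptakes
    present = {r.id for r in model.exchange_reactions()}
    for rid in uptakes:
        if rid not in present:
            logger.info(
                "environment %s: model %s lacks exchange %s; skipped",
                env.name, model.id, rid,
            )
    new_bounds = {
        r.id: (-uptakes.get(r.id, 0.0), r.upper_bound)
        for r in model.exchange_reactions()
    }
    return model.with_reaction_bounds(new_bounds)


def single_carbon_panel(
    carbon_exchange_ids: list[str],
    universal: dict[str, float] | list[str] | None = None,
    carbon_rate: float = CARBON_UPTAKE_RATE,
    universal_rate: float = UNIVERSAL_UPTAKE_RATE,
) -> EnvironmentPanel:
    """One environment per carbon source, each allowing that source alone
    (at ``carbon_rate``) on top of the shared universal uptakes."""
    if not carbon_exchange_ids:
        raise ValueError("carbon_exchange_ids must be non-empty")
    if len(set(carbon_exchange_ids)) != len(carbon_exchange_ids):
        dupes = sorted(
            {c for c in carbon_exchange_ids if carbon_exchange_ids.count(c) > 1}
        )
        raise ValueError(f"duplicate carbon exchange ids: {dupes}")
    uni = _as_rate_map(universal, universal_rate)
    return EnvironmentPanel(
        environments=[
            NutrientEnvironment(
                name=rid,
                carbon_uptakes={rid: carbon_rate},
                universal_uptakes=dict(uni),
            )
            for rid in carbon_exchange_ids
        ]
    )


def class_environment(
    name: str,
    class_members: list[str],
    universal: dict[str, float] | list[str] | None = None,
    carbon_rate: float = CARBON_UPTAKE_RATE,
    universal_rate: float = UNIVERSAL_UPTAKE_RATE,
) -> NutrientEnvironment:
    """One environment allowing all members of a carbohydrate class (e.g. all
    monosaccharides) simultaneously."""
    if not class_members:
        raise ValueError("class_members must be non-empty")
    return NutrientEnvironment(
        name=name,
        carbon_uptakes={rid: carbon_rate for rid in class_members},
        universal_uptakes=_as_rate_map(universal, universal_rate),
    )


def rich_environment(
    panel: EnvironmentPanel, name: str = "rich"
) -> NutrientEnvironment:
    """All of the panel's carbon sources at once, plus the union of its
    universal components."""
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    carbon: dict[str, float] = {}
    universal: dict[str, float] = {}
    for env in panel:
        carbon.update(env.carbon_uptakes)
        universal.update(env.universal_uptakes)
    return NutrientEnvironment(
        name=name, carbon_uptakes=carbon, universal_uptakes=universal
    )


def derive_universal_media(
    models: list[MetabolicModel],
    candidate_components: list[str],
    reference_carbon: str,
    carbon_rate: float = CARBON_UPTAKE_RATE,
    universal_rate: float = UNIVERSAL_UPTAKE_RATE,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> list[str]:
    """Leave-one-out derivation of the universal media.

    A candidate component is retained iff withholding it (with the reference
    carbon source and every other candidate supplied) abolishes growth of at
    least one strain. Verifies as a precondition that every strain grows with
    the full candidate set, and as a postcondition that every strain still
    grows on the returned set alone.
    """

    def _objective(model: MetabolicModel, components: list[str]) -> float:
        env = NutrientEnvironment(
            name="_universal_probe",
            carbon_uptakes={reference_carbon: carbon_rate},
            universal_uptakes={c: universal_rate for c in components},
        )
        sol = fba(apply_environment(model, env))
        return sol.objective_value if sol.optimal else 0.0

    for model in models:
        if _objective(model, candidate_components) <= growth_threshold:
            raise ValueError(
                f"strain {model.id!r} does not grow on {reference_carbon!r} even "
                "with the full candidate component set"
            )
    essential: list[str] = []
    for comp in candidate_components:
        reduced = [c for c in candidate_components if c != comp]
        if any(_objective(m, reduced) <= growth_threshold for m in models):
            essential.append(comp)
    for model in models:
        if _objective(model, essential) <= growth_threshold:
            raise ValueError(
                f"derived universal media fails to support strain {model.id!r} on "
                f"{reference_carbon!r}"
            )
    return essential


def _as_rate_map(
    universal: dict[str, float] | list[str] | None, default_rate: float
) -> dict[str, float]:
    if universal is None:
        return {}
    if isinstance(universal, dict):
        return dict(universal)
    return {rid: default_rate for rid in universal}


# ---------------------------------------------------------------------------
# TSV round trip: columns environment, exchange_id, rate, role
# ---------------------------------------------------------------------------


def panel_to_tsv(panel: EnvironmentPanel, path: str) -> None:
    import pandas as pd

    rows = []
    for env in panel:
        for rid, rate in env.carbon_uptakes.items():
            rows.append((env.name, rid, rate, "carbon"))
        for rid, rate in env.universal_uptakes.items():
            rows.append((env.name, rid, rate, "universal"))
    pd.DataFrame(
        rows, columns=["environment", "exchange_id", "rate", "role"]
    ).to_csv(path, sep="\t", index=False)


def panel_from_tsv(path: str) -> EnvironmentPanel:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    envs: list[NutrientEnvironment] = []
    for name, grp in df.groupby("environment", sort=False):
        carbon = {
            row.exchange_id: float(row.rate)
            for row in grp.itertuples()
            if row.role == "carbon"
        }
        universal = {
            row.exchange_id: float(row.rate)
            for row in grp.itertuples()
            if row.role == "universal"
        }
        envs.append(
            NutrientEnvironment(
                name=str(name), carbon_uptakes=carbon, universal_uptakes=universal
            )
        )
    return EnvironmentPanel(environments=envs)
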