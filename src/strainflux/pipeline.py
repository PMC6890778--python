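"""Configuration-driven orchestration of the full phenotyping workflow.

Stages communicate through files under the configured output directory, so
partial re-runs are cheap and the curated-model and synthetic workflows
share one code path. Every stage writes a provenance block (config hash,
package version, seed) and a run log recording solver statuses and skipped
exchanges; binary outputs are deterministic, so re-running a stage with an
identical configuration reproduces identical files.

Stage order mirrors the analysis: ``synth`` (or user-supplied models) →
``patch`` → ``media`` → ``growth`` → ``scfa`` → ``shunt`` → ``lethals`` →
``cluster``; ``all`` runs everything in order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .clustering import BinaryProfileSet, cluster_profiles, export_tree
from .environments import (
    EnvironmentPanel,
    derive_universal_media,
    panel_from_tsv,
    panel_to_tsv,
    rich_environment,
)
from .lethality import core_essential, pgx_essentiality_heatmap, rich_lethality_screen
from .model_core import MetabolicModel, apply_patch, load_model, load_patch, save_model
from .phenotyping import (
    PhenotypeMatrix,
    classify_shunt_reactions,
    growth_matrix,
    pooled_shunt_partition,
    producer_profile,
    shunt_knockout_scan,
)
from .synthetic_data import PanelSpec, generate_panel

logger = logging.getLogger(__name__)

STAGES = ["synth", "patch", "media", "growth", "scfa", "shunt", "lethals", "cluster"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """One structured-text (YAML) file drives the whole run."""

    output_dir: str
    model_paths: list[str] = field(default_factory=list)
    model_format: str | None = None
    patch_files: list[str] = field(default_factory=list)
    environment_panel: str | None = None  # TSV path
    universal_components: str | None = None  # one exchange id per line
    shunt_reactions: str | None = None  # one reaction id per line
    knockout_targets: list[str] = field(default_factory=lambda: ["PGK", "PGM", "PGMT"])
    reference_carbon: str = "EX_glc_e"
    carbon_uptake: float = 10.0
    universal_uptake: float = 1.0
    producer_threshold: float = 0.01
    growth_threshold: float = 1e-6
    lethality_cutoff_fraction: float = 0.01
    cluster_groups: int = 3
    seed: int = 0
    synth: dict | None = None  # PanelSpec fields; used by the synth stage

    def __post_init__(self) -> None:
        for name in (
            "carbon_uptake",
            "universal_uptake",
            "producer_threshold",
            "growth_threshold",
            "lethality_cutoff_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"PipelineConfig.{name} must be positive")
        for path in [*self.model_paths, *self.patch_files,
                     self.environment_panel, self.universal_components,
                     self.shunt_reactions]:
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"configured input does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_lines(config: PipelineConfig, stage: str) -> list[str]:
    return [
        f"# strainflux {__version__}",
        f"# stage: {stage}",
        f"# config_hash: {config.content_hash()}",
        f"# seed: {config.seed}",
    ]


def _write_with_provenance(path: str, body: str, config: PipelineConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance_lines(config, stage)) + "\n")
        fh.write(body)


def _frame_body(df: pd.DataFrame, index_label: str | None = "strain") -> str:
    return df.to_csv(sep="\t", index_label=index_label)


class PipelineRun:
    """Stage runner bound to one configuration."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        os.makedirs(config.output_dir, exist_ok=True)
        self.log_path = os.path.join(config.output_dir, "run.log")

    # -- helpers --------------------------------------------------------

    def _out(self, name: str) -> str:
        return os.path.join(self.config.output_dir, name)

    def _log(self, message: str) -> None:
        logger.info(message)
        with open(self.log_path, "a") as fh:
            fh.write(message + "\n")

    def _require(self, name: str, producing_stage: str) -> str:
        path = self._out(name)
        if not os.path.exists(path):
            raise PipelineError(
                f"missing {name}; run the {producing_stage!r} stage first"
            )
        return path

    def _load_models(self) -> list[MetabolicModel]:
        paths = list(self.config.model_paths)
        patched_dir = self._out("models_patched")
        synth_dir = self._out("models")
        if not paths and os.path.isdir(patched_dir):
            paths = sorted(
                os.path.join(patched_dir, p) for p in os.listdir(patched_dir)
            )
        if not paths and os.path.isdir(synth_dir):
            paths = sorted(os.path.join(synth_dir, p) for p in os.listdir(synth_dir))
        if not paths:
            raise PipelineError(
                "no models configured; set model_paths or run the 'synth' stage"
            )
        return [load_model(p, self.config.model_format) for p in paths]

    def _load_panel(self) -> EnvironmentPanel:
        if self.config.environment_panel:
            return panel_from_tsv(self.config.environment_panel)
        path = self._require("panel.tsv", "synth")
        return panel_from_tsv(path)

    def _universal_ids(self) -> list[str]:
        if self.config.universal_components:
            with open(self.config.universal_components) as fh:
                return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        panel = self._load_panel()
        seen: list[str] = []
        for env in panel:
            for rid in env.universal_uptakes:
                if rid not in seen:
                    seen.append(rid)
        return seen

    def _shunt_ids(self, models: list[MetabolicModel]) -> list[str]:
        if self.config.shunt_reactions:
            with open(self.config.shunt_reactions) as fh:
                return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        # default: the named core-shunt reactions of the synthetic generator
        from .synthetic_data import CORE_CHAIN

        return [r for r in CORE_CHAIN + ["GLCt", "LDH", "PFL", "ADHE"]
                if any(m.has_reaction(r) for m in models)]

    # -- stages ---------------------------------------------------------

    def run_stage(self, stage: str) -> None:
        if stage == "all":
            order = [s for s in STAGES if s != "synth" or self.config.synth is not None]
            if self.config.patch_files == [] and "patch" in order:
                order.remove("patch")
            if "media" in order:
                order.remove("media")  # optional analysis; run explicitly
            for s in order:
                self.run_stage(s)
            return
        handler = getattr(self, f"stage_{stage}", None)
        if handler is None:
            raise PipelineError(f"unknown stage {stage!r} (choose from {STAGES + ['all']})")
        self._log(f"stage {stage}: start (config {self.config.content_hash()})")
        handler()
        self._log(f"stage {stage}: done")

    def stage_synth(self) -> None:
        params = dict(self.config.synth or {})
        params.setdefault("seed", self.config.seed)
        spec = PanelSpec(**params)
        models, truth = generate_panel(spec)
        model_dir = self._out("models")
        os.makedirs(model_dir, exist_ok=True)
        for m in models:
            save_model(m, os.path.join(model_dir, f"{m.id}.json"), "json")
        panel_to_tsv(truth.panel, self._out("panel.tsv"))
        truth.growth.to_tsv(self._out("truth_growth.tsv"))
        truth.acetate_producers.to_tsv(self._out("truth_acetate.tsv"))
        truth.lactate_producers.to_tsv(self._out("truth_lactate.tsv"))
        pd.Series(truth.group_labels, name="group").to_csv(
            self._out("truth_groups.tsv"), sep="\t", index_label="strain"
        )
        rows = [(s, r) for s, rs in truth.singles.items() for r in sorted(rs)]
        pd.DataFrame(rows, columns=["strain", "reaction"]).to_csv(
            self._out("truth_singles.tsv"), sep="\t", index=False
        )
        rows = [
            (s, *sorted(p)) for s, ps in truth.doubles.items()
            for p in sorted(ps, key=sorted)
        ]
        pd.DataFrame(rows, columns=["strain", "reaction_1", "reaction_2"]).to_csv(
            self._out("truth_doubles.tsv"), sep="\t", index=False
        )
        self._log(f"synth: wrote {len(models)} strains, {len(truth.panel)} environments")

    def stage_patch(self) -> None:
        models = {m.id: m for m in self._load_models()}
        patched_dir = self._out("models_patched")
        os.makedirs(patched_dir, exist_ok=True)
        for patch_path in self.config.patch_files:
            patch = load_patch(patch_path)
            if patch.strain_id not in models:
                raise PipelineError(
                    f"patch {patch_path} targets unknown strain {patch.strain_id!r}"
                )
            models[patch.strain_id] = apply_patch(models[patch.strain_id], patch)
            self._log(
                f"patch: {patch.strain_id} += "
                f"{[r.id for r in patch.added_reactions]}"
            )
        for m in models.values():
            save_model(m, os.path.join(patched_dir, f"{m.id}.json"), "json")

    def stage_media(self) -> None:
        models = self._load_models()
        candidates = self._universal_ids()
        essential = derive_universal_media(
            models,
            candidates,
            self.config.reference_carbon,
            carbon_rate=self.config.carbon_uptake,
            universal_rate=self.config.universal_uptake,
            growth_threshold=self.config.growth_threshold,
        )
        body = "".join(c + "\n" for c in essential)
        _write_with_provenance(
            self._out("universal_media.txt"), body, self.config, "media"
        )
        self._log(f"media: {len(essential)}/{len(candidates)} components retained")

    def stage_growth(self) -> None:
        models = self._load_models()
        panel = self._load_panel()
        matrix = growth_matrix(models, panel, self.config.growth_threshold)
        _write_with_provenance(
            self._out("growth_matrix.tsv"),
            _frame_body(matrix.to_frame()),
            self.config,
            "growth",
        )
        self._log(
            f"growth: {len(models)} strains x {len(panel)} environments, "
            f"{sum(map(sum, matrix.values))} growth calls positive"
        )

    def stage_scfa(self) -> None:
        models = self._load_models()
        panel = self._load_panel()
        growth = PhenotypeMatrix.from_tsv(self._require("growth_matrix.tsv", "growth"))
        profile = producer_profile(
            models,
            panel,
            producer_threshold=self.config.producer_threshold,
            growth_threshold=self.config.growth_threshold,
            growth=growth,
        )
        rows = [(s, e, m, flag) for (s, e, m), flag in sorted(profile.flags.items())]
        long_df = pd.DataFrame(
            rows, columns=["strain", "environment", "metabolite", "producer"]
        )
        _write_with_provenance(
            self._out("scfa_profile.tsv"),
            long_df.to_csv(sep="\t", index=False),
            self.config,
            "scfa",
        )
        _write_with_provenance(
            self._out("scfa_vectors.tsv"),
            _frame_body(profile.as_vectors().to_frame()),
            self.config,
            "scfa",
        )
        self._log(f"scfa: {len(profile.flags)} producer calls")

    def stage_shunt(self) -> None:
        models = self._load_models()
        panel = self._load_panel()
        shunt_ids = self._shunt_ids(models)
        rows = []
        for m in models:
            part = classify_shunt_reactions(
                m, panel, shunt_ids, growth_threshold=self.config.growth_threshold
            )
            for rid in shunt_ids:
                status = (
                    "conserved" if rid in part.conserved
                    else "non_conserved" if rid in part.non_conserved
                    else "absent"
                )
                rows.append((m.id, rid, status))
        per_strain = pd.DataFrame(rows, columns=["strain", "reaction", "status"])
        _write_with_provenance(
            self._out("shunt_classification.tsv"),
            per_strain.to_csv(sep="\t", index=False),
            self.config,
            "shunt",
        )
        pooled = pooled_shunt_partition(
            models, panel, shunt_ids, growth_threshold=self.config.growth_threshold
        )
        body = "".join(
            f"{rid}\t{'conserved' if rid in pooled.conserved else 'non_conserved'}\n"
            for rid in shunt_ids
            if rid in pooled.conserved | pooled.non_conserved
        )
        _write_with_provenance(
            self._out("shunt_pooled.tsv"), body, self.config, "shunt"
        )
        targets = [
            t for t in self.config.knockout_targets
            if any(m.has_reaction(t) for m in models)
        ]
        if targets:
            heat = pgx_essentiality_heatmap(
                models, panel, targets, self.config.growth_threshold
            )
            _write_with_provenance(
                self._out("knockout_survival.tsv"),
                _frame_body(heat),
                self.config,
                "shunt",
            )
            scan = shunt_knockout_scan(
                models, panel, targets,
                producer_threshold=self.config.producer_threshold,
                growth_threshold=self.config.growth_threshold,
            )
            for target, (growth, producers) in scan.items():
                _write_with_provenance(
                    self._out(f"knockout_{target}_growth.tsv"),
                    _frame_body(growth.to_frame()),
                    self.config,
                    "shunt",
                )
        self._log(
            f"shunt: {len(pooled.conserved)} conserved / "
            f"{len(pooled.non_conserved)} non-conserved (pooled)"
        )

    def stage_lethals(self) -> None:
        models = self._load_models()
        panel = self._load_panel()
        rich = rich_environment(panel)
        screen = rich_lethality_screen(
            models, rich, self.config.lethality_cutoff_fraction
        )
        for sid in screen.skipped:
            self._log(f"lethals: strain {sid} does not grow in rich; skipped")
        rows = [(s, r) for s, ls in screen.per_strain.items() for r in sorted(ls.singles)]
        _write_with_provenance(
            self._out("single_lethals.tsv"),
            pd.DataFrame(rows, columns=["strain", "reaction"]).to_csv(sep="\t", index=False),
            self.config,
            "lethals",
        )
        rows = [
            (s, *p) for s, ls in screen.per_strain.items()
            for p in ls.doubles_as_sorted_pairs()
        ]
        _write_with_provenance(
            self._out("double_lethals.tsv"),
            pd.DataFrame(rows, columns=["strain", "reaction_1", "reaction_2"]).to_csv(
                sep="\t", index=False
            ),
            self.config,
            "lethals",
        )
        _write_with_provenance(
            self._out("lethality_vectors.tsv"),
            _frame_body(screen.lethality_vectors().to_frame()),
            self.config,
            "lethals",
        )
        core = core_essential(
            {s: ls.singles for s, ls in screen.per_strain.items()},
            {s: set(m.reaction_ids) for m in models for s in [m.id]
             if s in screen.per_strain},
        )
        summary = {
            "singles_union": len(screen.singles_union),
            "singles_and_double_members_union": len(
                screen.singles_and_double_members_union
            ),
            "core_essential": len(core.reactions),
        }
        body = "".join(f"{k}\t{v}\n" for k, v in summary.items())
        _write_with_provenance(
            self._out("lethality_summary.tsv"), body, self.config, "lethals"
        )
        body = "".join(r + "\n" for r in sorted(core.reactions))
        _write_with_provenance(
            self._out("core_essential.txt"), body, self.config, "lethals"
        )
        self._log(f"lethals: union {summary['singles_union']} singles, "
                  f"core {summary['core_essential']}")

    def stage_cluster(self) -> None:
        inputs = {
            "growth": self._require("growth_matrix.tsv", "growth"),
            "scfa": self._require("scfa_vectors.tsv", "scfa"),
            "lethals": self._require("lethality_vectors.tsv", "lethals"),
        }
        for name, path in inputs.items():
            matrix = PhenotypeMatrix.from_tsv(path)
            profiles = BinaryProfileSet.from_phenotype_matrix(matrix)
            if len(profiles.row_labels) < 2:
                self._log(f"cluster: {name} has <2 strains; skipped")
                continue
            tree = cluster_profiles(profiles)
            export_tree(tree, self._out(f"tree_{name}.nwk"), "newick")
            export_tree(tree, self._out(f"tree_{name}_linkage.tsv"), "merge-table")
            k = min(self.config.cluster_groups, len(profiles.row_labels))
            cut = tree.cut(k)
            body = "".join(f"{s}\t{c}\n" for s, c in cut.items())
            _write_with_provenance(
                self._out(f"clusters_{name}.tsv"), body, self.config, "cluster"
            )
        self._log("cluster: trees and assignments written")


def run_stage(config: PipelineConfig, stage: str) -> None:
    PipelineRun(config).run_stage(stage)
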