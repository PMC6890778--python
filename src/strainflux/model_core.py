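"""Domain types for genome-scale metabolic models and their serialization.

A :class:`MetabolicModel` holds the stoichiometry, flux bounds and biomass
objective of one strain. Models are read and written in SBML Level 3 with the
FBC package (via libsbml) and in a COBRA-style JSON dialect, and can be
extended with curation patches (:class:`ModelPatch`) that add reactions or
change bounds, e.g. to graft a starch-degradation chain onto a strain whose
genome encodes the enzymes but whose draft reconstruction lacks them.

Sign conventions follow AGORA/VMH: an exchange reaction has a single
metabolite with coefficient -1, negative flux is uptake into the system and
positive flux is secretion. "Unbounded" fluxes are capped at +/-1000
mmol/gDW/h so every linear program stays bounded.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace

import libsbml

#: Default magnitude used for "unbounded" fluxes, in mmol/gDW/h.
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """A model, patch or serialized file violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """One chemical species in one compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds in mmol/gDW/h.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed). ``is_exchange`` marks boundary pseudo-reactions; see
    :func:`is_exchange_like` for the detection rule.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str | None = None
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


def is_exchange_like(rxn_id: str, stoichiometry: dict[str, float]) -> bool:
    """An exchange reaction has exactly one metabolite with coefficient -1,
    or an id beginning ``EX_``."""
    if rxn_id.startswith("EX_"):
        return True
    if len(stoichiometry) == 1:
        (coef,) = stoichiometry.values()
        return coef == -1
    return False


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds and biomass objective of one strain.

    The induced stoichiometric matrix S has one row per metabolite and one
    column per reaction; :mod:`strainflux.lp_engine` builds it on demand.
    """

    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookup helpers -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelError(f"model {self.id!r}: duplicate metabolite ids {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelError(f"model {self.id!r}: duplicate reaction ids {dupes}")
        known = set(met_ids)
        for r in self.reactions:
            missing = sorted(set(r.stoichiometry) - known)
            if missing:
                raise ModelError(
                    f"model {self.id!r}: reaction {r.id!r} references undeclared "
                    f"metabolite(s) {missing}"
                )
        if not self.objective_reaction_id:
            raise ModelError(f"model {self.id!r}: no biomass objective set")
        if self.objective_reaction_id not in set(rxn_ids):
            raise ModelError(
                f"model {self.id!r}: objective reaction "
                f"{self.objective_reaction_id!r} not found"
            )

    # -- mutation-free editing ------------------------------------------

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel.__new__(MetabolicModel)
        m.id = self.id
        m.metabolites = list(self.metabolites)
        m.reactions = list(self.reactions)
        m.objective_reaction_id = self.objective_reaction_id
        return m

    def with_reaction_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Return a copy with the listed reactions re-bounded."""
        unknown = sorted(set(bounds) - set(self.reaction_ids))
        if unknown:
            raise ModelError(f"model {self.id!r}: cannot re-bound unknown reactions {unknown}")
        m = self.copy()
        m.reactions = [
            r.with_bounds(*bounds[r.id]) if r.id in bounds else r for r in m.reactions
        ]
        return m

    def knock_out(self, rxn_ids: str | list[str]) -> "MetabolicModel":
        """Delete reactions by pinning both bounds to zero."""
        if isinstance(rxn_ids, str):
            rxn_ids = [rxn_ids]
        return self.with_reaction_bounds({r: (0.0, 0.0) for r in rxn_ids})


@dataclass
class ModelPatch:
    """Curation patch: reactions (with any new metabolites) to add to one
    strain, plus bound changes, applied by :func:`apply_patch`."""

    strain_id: str
    added_reactions: list[Reaction] = field(default_factory=list)
    added_metabolites: list[Metabolite] = field(default_factory=list)
    bound_changes: dict[str, tuple[float, float]] = field(default_factory=dict)


def apply_patch(model: MetabolicModel, patch: ModelPatch) -> MetabolicModel:
    """Return a new model with the patch applied; the input is unmodified."""
    if patch.strain_id != model.id:
        raise ModelError(
            f"patch targets strain {patch.strain_id!r}, model is {model.id!r}"
        )
    colliding = sorted(
        {r.id for r in patch.added_reactions} & set(model.reaction_ids)
    )
    if colliding:
        raise ModelError(
            f"patch for {model.id!r}: reaction id(s) already present: {colliding}"
        )
    new = model.copy()
    present = set(new.metabolite_ids)
    for met in patch.added_metabolites:
        if met.id not in present:
            new.metabolites.append(met)
            present.add(met.id)
    # metabolites referenced by added reactions but not declared get a bare stub
    for r in patch.added_reactions:
        for mid in r.stoichiometry:
            if mid not in present:
                new.metabolites.append(Metabolite(id=mid, compartment=_infer_compartment(mid)))
                present.add(mid)
    new.reactions = new.reactions + list(patch.added_reactions)
    new.validate()
    if patch.bound_changes:
        new = new.with_reaction_bounds(dict(patch.bound_changes))
    return new


def _infer_compartment(met_id: str) -> str:
    m = re.search(r"\[(\w+)\]$|_(\w)$", met_id)
    if m:
        return m.group(1) or m.group(2)
    return "c"


# ---------------------------------------------------------------------------
# Reaction-string parsing ("1 starch[e] -> 2 glc[e]")
# ---------------------------------------------------------------------------

_ARROWS = ["<=>", "<->", "-->", "<--", "->", "="]


def parse_reaction_string(
    rxn_id: str,
    expr: str,
    lower_bound: float | None = None,
    upper_bound: float | None = None,
    name: str = "",
    subsystem: str | None = None,
) -> Reaction:
    """Build a :class:`Reaction` from a human-readable stoichiometry string.

    ``"1 starch[e] -> 2 glc[e]"`` consumes one starch and yields two glucose.
    ``<=>`` (or ``<->``) marks a reversible reaction; a one-sided arrow
    defaults the bounds to irreversible forward.
    """
    arrow = next((a for a in _ARROWS if a in expr), None)
    if arrow is None:
        raise ModelError(f"reaction {rxn_id!r}: no arrow in {expr!r}")
    lhs, rhs = expr.split(arrow, 1)
    reversible = arrow in ("<=>", "<->", "=")
    stoich: dict[str, float] = {}

    def _accumulate(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split(None, 1)
            if len(parts) == 2 and _is_number(parts[0]):
                coef, mid = float(parts[0]), parts[1].strip()
            else:
                coef, mid = 1.0, term
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    _accumulate(lhs, -1.0)
    _accumulate(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if lower_bound is None:
        lower_bound = -DEFAULT_BOUND if reversible else 0.0
    if upper_bound is None:
        upper_bound = DEFAULT_BOUND
    return Reaction(
        id=rxn_id,
        stoichiometry=stoich,
        lower_bound=lower_bound,
        upper_bound=upper_bound,
        name=name,
        subsystem=subsystem,
        is_exchange=is_exchange_like(rxn_id, stoich),
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def load_patch(path: str) -> ModelPatch:
    """Read a YAML patch file: ``strain``, ``reactions`` (id, equation,
    optional bounds), ``bound_changes`` (id -> [lb, ub])."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    reactions = []
    for entry in doc.get("reactions", []):
        reactions.append(
            parse_reaction_string(
                entry["id"],
                entry["equation"],
                lower_bound=entry.get("lower_bound"),
                upper_bound=entry.get("upper_bound"),
                name=entry.get("name", ""),
                subsystem=entry.get("subsystem"),
            )
        )
    bound_changes = {
        rid: (float(lb), float(ub))
        for rid, (lb, ub) in (doc.get("bound_changes") or {}).items()
    }
    return ModelPatch(
        strain_id=doc["strain"], added_reactions=reactions, bound_changes=bound_changes
    )


# ---------------------------------------------------------------------------
# JSON dialect (COBRA community schema)
# ---------------------------------------------------------------------------


def model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                **({"subsystem": r.subsystem} if r.subsystem else {}),
                "objective_coefficient": 1.0
                if r.id == model.objective_reaction_id
                else 0.0,
            }
            for r in model.reactions
        ],
    }


def model_from_json_dict(doc: dict) -> MetabolicModel:
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
        )
        for m in doc.get("metabolites", [])
    ]
    reactions = []
    objective_id = ""
    for r in doc.get("reactions", []):
        stoich = {mid: float(c) for mid, c in r["metabolites"].items()}
        reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry=stoich,
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                name=r.get("name", ""),
                subsystem=r.get("subsystem"),
                is_exchange=is_exchange_like(r["id"], stoich),
            )
        )
        if r.get("objective_coefficient", 0):
            objective_id = r["id"]
    if not objective_id:
        raise ModelError(
            f"model {doc.get('id', '?')!r}: no biomass objective "
            "(no reaction with objective_coefficient != 0)"
        )
    return MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=objective_id,
    )


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

_SBML_ID_FIX = re.compile(r"[^A-Za-z0-9_]")


def _sbml_id(raw: str) -> str:
    """SBML SIds admit only [A-Za-z_][A-Za-z0-9_]*; encode everything else."""
    s = _SBML_ID_FIX.sub("__", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return s


def _model_to_sbml_string(model: MetabolicModel) -> str:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sbml_id(model.id))
    sm.setName(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for cid in compartments:
        c = sm.createCompartment()
        c.setId(_sbml_id(cid))
        c.setConstant(True)

    id_map: dict[str, str] = {}
    for met in model.metabolites:
        s = sm.createSpecies()
        sid = "M_" + _sbml_id(met.id)
        id_map[met.id] = sid
        s.setId(sid)
        s.setName(met.name or met.id)
        s.setCompartment(_sbml_id(met.compartment))
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        if met.formula:
            s.getPlugin("fbc").setChemicalFormula(met.formula)

    # one global parameter per distinct bound value, FBC style
    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            p = sm.createParameter()
            pid = f"fb_{len(bound_params)}"
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        r = sm.createReaction()
        rid = "R_" + _sbml_id(rxn.id)
        r.setId(rid)
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            if coef < 0:
                sr = r.createReactant()
            else:
                sr = r.createProduct()
            sr.setSpecies(id_map[mid])
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if rxn.subsystem:
            r.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'><p>SUBSYSTEM: {rxn.subsystem}</p></body>")

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction("R_" + _sbml_id(model.objective_reaction_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")
    return libsbml.writeSBMLToString(doc)


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _model_from_sbml(doc: "libsbml.SBMLDocument", path: str) -> MetabolicModel:
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelError(
                    f"SBML parse failure in {path}: {err.getMessage().strip()} "
                    f"(line {err.getLine()})"
                )
    sm = doc.getModel()
    if sm is None:
        raise ModelError(f"SBML file {path} contains no model element")
    mplug = sm.getPlugin("fbc")
    if mplug is None:
        raise ModelError(f"SBML file {path}: FBC package information missing")

    metabolites = []
    sid_to_mid: dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        mid = _strip_prefix(sp.getId(), "M_")
        sid_to_mid[sp.getId()] = mid
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        metabolites.append(
            Metabolite(
                id=mid,
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=formula,
            )
        )

    def _param_value(pid: str, rid: str) -> float:
        p = sm.getParameter(pid)
        if p is None or not p.isSetValue():
            raise ModelError(
                f"SBML file {path}: reaction {rid!r} references missing "
                f"flux-bound parameter {pid!r}"
            )
        return p.getValue()

    reactions = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        rid = _strip_prefix(rx.getId(), "R_")
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            mid = sid_to_mid[sr.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            mid = sid_to_mid[sr.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound():
            raise ModelError(
                f"SBML file {path}: reaction {rid!r} has no FBC flux bounds"
            )
        lb = _param_value(rplug.getLowerFluxBound(), rid)
        ub = _param_value(rplug.getUpperFluxBound(), rid)
        subsystem = None
        if rx.isSetNotes():
            notes = rx.getNotesString()
            m = re.search(r"SUBSYSTEM:\s*([^<]+)", notes)
            if m:
                subsystem = m.group(1).strip()
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rx.getName() or "",
                subsystem=subsystem,
                is_exchange=is_exchange_like(rid, stoich),
            )
        )

    objective_id = ""
    active = mplug.getActiveObjective()
    if active is not None and active.getNumFluxObjectives() > 0:
        for j in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(j)
            if fo.getCoefficient() != 0:
                objective_id = _strip_prefix(fo.getReaction(), "R_")
                break
    if not objective_id:
        raise ModelError(f"SBML file {path}: no biomass objective declared")

    return MetabolicModel(
        id=sm.getName() or sm.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=objective_id,
    )


# ---------------------------------------------------------------------------
# Public load/save
# ---------------------------------------------------------------------------


def load_model(path: str, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML (Level 3 + FBC) or COBRA-style JSON.

    ``format`` is ``"sbml"`` or ``"json"``; when omitted it is inferred from
    the file extension (``.xml``/``.sbml`` vs ``.json``).
    """
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelError(f"JSON parse failure in {path}: {exc}") from exc
        return model_from_json_dict(doc)
    if fmt == "sbml":
        doc = libsbml.readSBMLFromFile(path)
        return _model_from_sbml(doc, path)
    raise ModelError(f"unknown model format {fmt!r} (expected 'sbml' or 'json')")


def save_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    """Write a model so that :func:`load_model` reproduces it exactly."""
    model.validate()
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_json_dict(model), fh, indent=1)
            fh.write("\n")
    elif fmt == "sbml":
        with open(path, "w") as fh:
            fh.write(_model_to_sbml_string(model))
    else:
        raise ModelError(f"unknown model format {fmt!r} (expected 'sbml' or 'json')")


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".json"):
        return "json"
    if p.endswith((".xml", ".sbml")):
        return "sbml"
    raise ModelError(f"cannot infer model format from path {path!r}")


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 0.0) -> bool:
    """Equality on the analysis-relevant content: stoichiometry, bounds,
    objective and exchange flags (names/formulas ignored)."""
    if a.objective_reaction_id != b.objective_reaction_id:
        return False
    if set(a.metabolite_ids) != set(b.metabolite_ids):
        return False
    ra = {r.id: r for r in a.reactions}
    rb = {r.id: r for r in b.reactions}
    if set(ra) != set(rb):
        return False
    for rid, x in ra.items():
        y = rb[rid]
        if x.is_exchange != y.is_exchange:
            return False
        if set(x.stoichiometry) != set(y.stoichiometry):
            return False
        for mid, c in x.stoichiometry.items():
            if not math.isclose(c, y.stoichiometry[mid], abs_tol=tol, rel_tol=tol):
                return False
        if not (
            math.isclose(x.lower_bound, y.lower_bound, abs_tol=tol, rel_tol=tol)
            and math.isclose(x.upper_bound, y.upper_bound, abs_tol=tol, rel_tol=tol)
        ):
            return False
    return True
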