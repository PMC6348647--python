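"""Model data structures, SBML I/O, search, editing and purge operations.

The in-memory :class:`Model` is a plain constraint-based reconstruction:
compartments, species, reactions with net signed stoichiometry and flux
bounds, plus an optional biomass designation.  Reversibility is reconciled
against the bounds (``lb < 0  <=>  reversible``) because the bounds are what
every linear programme downstream actually sees.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

import libsbml

__all__ = [
    "Compartment",
    "Species",
    "Reaction",
    "Model",
    "EditPatch",
    "PurgeReport",
    "ValidationError",
    "PatchError",
    "read_sbml",
    "write_sbml",
    "apply_patch",
    "purge_boundary_species",
    "purge_disconnected_clusters",
    "purge_isolated_nodes",
    "search",
    "stoichiometric_matrix",
]

#: default flux bound magnitude (mmol·gDW⁻¹·h⁻¹ by convention)
DEFAULT_BOUND = 1000.0

#: id suffix conventionally marking boundary species in older models
BOUNDARY_SUFFIX = "_b"


class ValidationError(ValueError):
    """A model (or edit) violates a structural invariant."""


class PatchError(ValidationError):
    """An edit patch could not be applied; the model is unchanged."""


@dataclass
class Compartment:
    id: str
    name: str = ""

    def copy(self) -> "Compartment":
        return Compartment(self.id, self.name)


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = ""
    boundary: bool = False

    def copy(self) -> "Species":
        return Species(self.id, self.name, self.compartment, self.boundary)


@dataclass
class Reaction:
    """A reaction with net signed stoichiometry.

    ``stoich`` maps species id to a signed coefficient: negative means the
    species is consumed when flux is positive, positive means produced.
    A species occurring on both sides is stored with the summed (net)
    coefficient; an exact zero drops the species.
    """

    id: str
    name: str = ""
    stoich: dict = field(default_factory=dict)
    lb: float = 0.0
    ub: float = DEFAULT_BOUND

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValidationError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def reactants(self) -> list:
        """Species ids with negative coefficient (consumed on forward flux)."""
        return [s for s, c in self.stoich.items() if c < 0]

    @property
    def products(self) -> list:
        return [s for s, c in self.stoich.items() if c > 0]

    def copy(self) -> "Reaction":
        return Reaction(self.id, self.name, dict(self.stoich), self.lb, self.ub)


class Model:
    """A metabolic reconstruction: compartments, species, reactions."""

    def __init__(
        self,
        id: str = "model",
        name: str = "",
        compartments: Iterable[Compartment] = (),
        species: Iterable[Species] = (),
        reactions: Iterable[Reaction] = (),
        biomass: Optional[str] = None,
    ):
        self.id = id
        self.name = name
        self.compartments: dict = {c.id: c for c in compartments}
        self.species: dict = {s.id: s for s in species}
        self.reactions: dict = {r.id: r for r in reactions}
        self.biomass = biomass

    # -- construction helpers -------------------------------------------------

    def add_compartment(self, comp: Compartment) -> None:
        if comp.id in self.compartments:
            raise ValidationError(f"duplicate compartment id {comp.id!r}")
        self.compartments[comp.id] = comp

    def add_species(self, sp: Species) -> None:
        if sp.id in self.species:
            raise ValidationError(f"duplicate species id {sp.id!r}")
        self.species[sp.id] = sp

    def add_reaction(self, rx: Reaction) -> None:
        if rx.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rx.id!r}")
        self.reactions[rx.id] = rx

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every dangling reference."""
        problems = []
        for sp in self.species.values():
            if sp.compartment and sp.compartment not in self.compartments:
                problems.append(
                    f"species {sp.id!r} references unknown compartment {sp.compartment!r}"
                )
        for rx in self.reactions.values():
            missing = sorted(s for s in rx.stoich if s not in self.species)
            if missing:
                problems.append(
                    f"reaction {rx.id!r} references undeclared species: {', '.join(missing)}"
                )
            if rx.lb > rx.ub:
                problems.append(f"reaction {rx.id!r}: lb > ub")
        if self.biomass is not None and self.biomass not in self.reactions:
            problems.append(f"biomass {self.biomass!r} is not a reaction in the model")
        if problems:
            raise ValidationError("; ".join(problems))

    def copy(self) -> "Model":
        return Model(
            self.id,
            self.name,
            [c.copy() for c in self.compartments.values()],
            [s.copy() for s in self.species.values()],
            [r.copy() for r in self.reactions.values()],
            self.biomass,
        )

    def equal_fields(self, other: "Model") -> bool:
        """Field-level equality on ids, names, stoichiometry, bounds, biomass."""
        if set(self.compartments) != set(other.compartments):
            return False
        if set(self.species) != set(other.species):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        for cid, c in self.compartments.items():
            if c.name != other.compartments[cid].name:
                return False
        for sid, s in self.species.items():
            o = other.species[sid]
            if (s.name, s.compartment, s.boundary) != (o.name, o.compartment, o.boundary):
                return False
        for rid, r in self.reactions.items():
            o = other.reactions[rid]
            if r.name != o.name or r.stoich != o.stoich:
                return False
            if not (math.isclose(r.lb, o.lb) and math.isclose(r.ub, o.ub)):
                return False
        return self.biomass == other.biomass

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Model {self.id!r}: {len(self.compartments)} compartments, "
            f"{len(self.species)} species, {len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------


def _reconcile(lb: float, ub: float, flag_reversible: bool) -> tuple:
    """Bounds win over the SBML reversible flag: lb < 0 defines reversible."""
    if lb is None and ub is None:
        lb = -DEFAULT_BOUND if flag_reversible else 0.0
        ub = DEFAULT_BOUND
    else:
        if lb is None:
            lb = -DEFAULT_BOUND if flag_reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
    return float(lb), float(ub)


def read_sbml(path: str, boundary_suffix: str = BOUNDARY_SUFFIX,
              biomass: Optional[str] = None) -> Model:
    """Read an SBML Level 2 or Level 3 (+fbc) file into a :class:`Model`.

    Bounds come from the fbc package when present, else from kinetic-law
    parameters named ``LOWER_BOUND``/``UPPER_BOUND``, else the COBRA default
    of [-1000, 1000] for reversible and [0, 1000] for irreversible reactions.
    A species is flagged as boundary when its ``boundaryCondition`` attribute
    is set or its id carries the conventional suffix (``_b`` by default;
    pass ``boundary_suffix=""`` to disable the suffix rule).

    ``biomass`` overrides automatic biomass detection (fbc objective, else
    the first reaction whose id or name contains "biomass").
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                msg = err.getMessage().strip()
                if err.getErrorId() == libsbml.XMLFileUnreadable:
                    raise IOError(f"cannot read {path}: {msg}")
                raise ValidationError(
                    f"SBML parse error in {path} (line {err.getLine()}): {msg}"
                )
        if doc.getModel() is None:
            raise ValidationError(f"no model element found in {path}")
    sm = doc.getModel()

    model = Model(id=sm.getId() or "model", name=sm.getName() or "")
    for i in range(sm.getNumCompartments()):
        c = sm.getCompartment(i)
        model.add_compartment(Compartment(c.getId(), c.getName() or ""))
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        is_boundary = bool(s.getBoundaryCondition())
        if boundary_suffix and s.getId().endswith(boundary_suffix):
            is_boundary = True
        model.add_species(
            Species(s.getId(), s.getName() or "", s.getCompartment() or "", is_boundary)
        )

    objective_rxn = None
    fbc_model = sm.getPlugin("fbc")
    if fbc_model is not None:
        obj = fbc_model.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_rxn = obj.getFluxObjective(0).getReaction()

    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        # net storage: species cancelling exactly are dropped
        stoich = {s: c for s, c in stoich.items() if c != 0.0}

        lb = ub = None
        fbc_rxn = r.getPlugin("fbc")
        if fbc_rxn is not None:
            lb_id = fbc_rxn.getLowerFluxBound()
            ub_id = fbc_rxn.getUpperFluxBound()
            if lb_id:
                p = sm.getParameter(lb_id)
                lb = p.getValue() if p is not None else None
            if ub_id:
                p = sm.getParameter(ub_id)
                ub = p.getValue() if p is not None else None
        if lb is None and ub is None and r.isSetKineticLaw():
            kl = r.getKineticLaw()
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
        lb, ub = _reconcile(lb, ub, r.getReversible())
        model.add_reaction(Reaction(r.getId(), r.getName() or "", stoich, lb, ub))

    if biomass is not None:
        if biomass not in model.reactions:
            raise ValidationError(f"biomass override {biomass!r} not in model")
        model.biomass = biomass
    elif objective_rxn and objective_rxn in model.reactions:
        model.biomass = objective_rxn
    else:
        for rx in model.reactions.values():
            if "biomass" in rx.id.lower() or "biomass" in rx.name.lower():
                model.biomass = rx.id
                break

    model.validate()
    return model


def write_sbml(model: Model, path: str) -> None:
    """Write ``model`` as SBML Level 3 Version 1 with the fbc (v2) package.

    Round-trip contract: ``read_sbml`` on the written file reproduces the
    model field-for-field (ids, names, stoichiometry, bounds, reversibility,
    boundary flags, biomass designation).
    """
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    if model.name:
        sm.setName(model.name)
    fbc_model = sm.getPlugin("fbc")
    fbc_model.setStrict(False)

    for comp in model.compartments.values():
        c = sm.createCompartment()
        c.setId(comp.id)
        if comp.name:
            c.setName(comp.name)
        c.setConstant(True)
        c.setSize(1.0)
    for sp in model.species.values():
        s = sm.createSpecies()
        s.setId(sp.id)
        if sp.name:
            s.setName(sp.name)
        if sp.compartment:
            s.setCompartment(sp.compartment)
        s.setBoundaryCondition(bool(sp.boundary))
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)

    def _bound_param(pid: str, value: float) -> None:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)

    for rx in model.reactions.values():
        r = sm.createReaction()
        r.setId(rx.id)
        if rx.name:
            r.setName(rx.name)
        r.setReversible(rx.reversible)
        r.setFast(False)
        for sid, coef in rx.stoich.items():
            if coef < 0:
                sr = r.createReactant()
                sr.setSpecies(sid)
                sr.setStoichiometry(-coef)
            else:
                sr = r.createProduct()
                sr.setSpecies(sid)
                sr.setStoichiometry(coef)
            sr.setConstant(True)
        lb_id = f"fb_{rx.id}_lb"
        ub_id = f"fb_{rx.id}_ub"
        _bound_param(lb_id, rx.lb)
        _bound_param(ub_id, rx.ub)
        fbc_rxn = r.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(lb_id)
        fbc_rxn.setUpperFluxBound(ub_id)

    if model.biomass is not None:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.biomass)
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise IOError(f"cannot write SBML to {path}")


# ---------------------------------------------------------------------------
# Editing
# ---------------------------------------------------------------------------


@dataclass
class EditPatch:
    """An ordered batch of edits. Applying a patch is atomic."""

    edits: list  # list of {"action", "kind", "id", "fields"}

    @classmethod
    def from_json(cls, path: str) -> "EditPatch":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise PatchError("patch file must contain a JSON array of edits")
        return cls(edits=data)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.edits, fh, indent=1)


@dataclass
class PurgeReport:
    """What a purge (or cascading edit) removed or rewrote."""

    removed_species: list = field(default_factory=list)
    removed_reactions: list = field(default_factory=list)
    removed_compartments: list = field(default_factory=list)
    converted_reactions: list = field(default_factory=list)  # became import/export
    affected_reactions: list = field(default_factory=list)  # stoich rewritten

    @property
    def counts(self) -> dict:
        return {
            "removed_species": len(self.removed_species),
            "removed_reactions": len(self.removed_reactions),
            "removed_compartments": len(self.removed_compartments),
            "converted_reactions": len(self.converted_reactions),
            "affected_reactions": len(self.affected_reactions),
        }

    def is_empty(self) -> bool:
        return not any(
            (self.removed_species, self.removed_reactions, self.removed_compartments,
             self.converted_reactions, self.affected_reactions)
        )

    def to_tsv(self) -> str:
        rows = ["action\tkind\tid\tdetail"]
        for sid in self.removed_species:
            rows.append(f"removed\tspecies\t{sid}\t")
        for rid in self.removed_reactions:
            rows.append(f"removed\treaction\t{rid}\t")
        for cid in self.removed_compartments:
            rows.append(f"removed\tcompartment\t{cid}\t")
        for rid, what in self.converted_reactions:
            rows.append(f"converted\treaction\t{rid}\t{what}")
        for rid in self.affected_reactions:
            rows.append(f"rewritten\treaction\t{rid}\tstoichiometry changed")
        return "\n".join(rows) + "\n"


_SPECIES_FIELDS = {"name", "compartment", "boundary"}
_REACTION_FIELDS = {"name", "stoich", "lb", "ub", "reversible"}
_COMPARTMENT_FIELDS = {"name"}


def _apply_reaction_fields(rx: Reaction, fields: Mapping) -> None:
    unknown = set(fields) - _REACTION_FIELDS
    if unknown:
        raise PatchError(f"unknown reaction fields: {sorted(unknown)}")
    if "name" in fields:
        rx.name = str(fields["name"])
    if "stoich" in fields:
        rx.stoich = {str(s): float(c) for s, c in dict(fields["stoich"]).items() if c != 0}
    if "lb" in fields:
        rx.lb = float(fields["lb"])
    if "ub" in fields:
        rx.ub = float(fields["ub"])
    if "reversible" in fields:
        # reconcile the flag with the bounds: bounds are rewritten to agree
        if fields["reversible"]:
            if rx.lb >= 0:
                rx.lb = -DEFAULT_BOUND
        else:
            rx.lb = max(rx.lb, 0.0)
    if rx.lb > rx.ub:
        raise PatchError(f"reaction {rx.id!r}: lb {rx.lb} > ub {rx.ub}")


def apply_patch(model: Model, patch: EditPatch) -> tuple:
    """Apply an :class:`EditPatch`, returning ``(new_model, report)``.

    Atomic: any failure raises :class:`PatchError` and the input model is
    untouched (a copy is edited throughout).  Deleting a species removes it
    from every reaction's stoichiometry and reports the affected reactions;
    deleting a non-empty compartment fails unless earlier edits in the same
    patch emptied it.
    """
    work = model.copy()
    report = PurgeReport()
    for i, edit in enumerate(patch.edits):
        try:
            action = edit["action"]
            kind = edit["kind"]
            target = edit["id"]
            fields = edit.get("fields", {})
        except (KeyError, TypeError) as exc:
            raise PatchError(f"edit #{i}: malformed record ({exc})") from exc
        if action not in ("add", "modify", "delete"):
            raise PatchError(f"edit #{i}: unknown action {action!r}")
        if kind not in ("species", "reaction", "compartment"):
            raise PatchError(f"edit #{i}: unknown kind {kind!r}")

        if action == "add":
            try:
                if kind == "compartment":
                    work.add_compartment(Compartment(target, str(fields.get("name", ""))))
                elif kind == "species":
                    sp = Species(target)
                    _apply_species_fields(sp, fields)
                    work.add_species(sp)
                else:
                    rx = Reaction(target)
                    _apply_reaction_fields(rx, fields)
                    work.add_reaction(rx)
            except PatchError:
                raise
            except ValidationError as exc:
                raise PatchError(f"edit #{i}: {exc}") from exc
        elif action == "modify":
            if kind == "compartment":
                comp = work.compartments.get(target)
                if comp is None:
                    raise PatchError(f"edit #{i}: unknown compartment {target!r}")
                unknown = set(fields) - _COMPARTMENT_FIELDS
                if unknown:
                    raise PatchError(f"unknown compartment fields: {sorted(unknown)}")
                if "name" in fields:
                    comp.name = str(fields["name"])
            elif kind == "species":
                sp = work.species.get(target)
                if sp is None:
                    raise PatchError(f"edit #{i}: unknown species {target!r}")
                _apply_species_fields(sp, fields)
            else:
                rx = work.reactions.get(target)
                if rx is None:
                    raise PatchError(f"edit #{i}: unknown reaction {target!r}")
                _apply_reaction_fields(rx, fields)
        else:  # delete
            if kind == "compartment":
                if target not in work.compartments:
                    raise PatchError(f"edit #{i}: unknown compartment {target!r}")
                occupants = [s.id for s in work.species.values() if s.compartment == target]
                if occupants:
                    raise PatchError(
                        f"edit #{i}: compartment {target!r} still holds species "
                        f"{occupants}; relocate or delete them first"
                    )
                del work.compartments[target]
                report.removed_compartments.append(target)
            elif kind == "species":
                if target not in work.species:
                    raise PatchError(f"edit #{i}: unknown species {target!r}")
                del work.species[target]
                for rx in work.reactions.values():
                    if target in rx.stoich:
                        del rx.stoich[target]
                        report.affected_reactions.append(rx.id)
                report.removed_species.append(target)
            else:
                if target not in work.reactions:
                    raise PatchError(f"edit #{i}: unknown reaction {target!r}")
                del work.reactions[target]
                if work.biomass == target:
                    work.biomass = None
                report.removed_reactions.append(target)

    try:
        work.validate()
    except ValidationError as exc:
        raise PatchError(f"patch leaves model invalid: {exc}") from exc
    return work, report


def _apply_species_fields(sp: Species, fields: Mapping) -> None:
    unknown = set(fields) - _SPECIES_FIELDS
    if unknown:
        raise PatchError(f"unknown species fields: {sorted(unknown)}")
    if "name" in fields:
        sp.name = str(fields["name"])
    if "compartment" in fields:
        sp.compartment = str(fields["compartment"])
    if "boundary" in fields:
        sp.boundary = bool(fields["boundary"])


# ---------------------------------------------------------------------------
# Purge operations
# ---------------------------------------------------------------------------


def purge_boundary_species(model: Model, compartment: Optional[str] = None) -> tuple:
    """Remove boundary placeholders (or a whole compartment's species).

    With ``compartment=None`` the boundary-flagged species are purged;
    otherwise every species of that compartment is.  Reactions whose entire
    reactant side was purged become imports (no reactants); symmetrically for
    exports.  Reactions left with an empty stoichiometry are kept as pure
    import/export stubs (remove them with :func:`purge_isolated_nodes`).
    """
    if compartment is not None and compartment not in model.compartments:
        raise ValidationError(f"unknown compartment {compartment!r}")
    if compartment is None:
        doomed = {s.id for s in model.species.values() if s.boundary}
    else:
        doomed = {s.id for s in model.species.values() if s.compartment == compartment}

    out = model.copy()
    report = PurgeReport()
    for sid in doomed:
        del out.species[sid]
        report.removed_species.append(sid)
    report.removed_species.sort()
    for rx in out.reactions.values():
        touched = [s for s in rx.stoich if s in doomed]
        if not touched:
            continue
        had_reactants = bool(rx.reactants)
        had_products = bool(rx.products)
        for s in touched:
            del rx.stoich[s]
        report.affected_reactions.append(rx.id)
        if had_reactants and not rx.reactants:
            report.converted_reactions.append((rx.id, "import"))
        elif had_products and not rx.products:
            report.converted_reactions.append((rx.id, "export"))
    return out, report


def _bipartite_components(model: Model) -> list:
    """Connected components (sets of node ids) of the undirected bipartite graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(model.species)
    g.add_nodes_from(model.reactions)
    for rx in model.reactions.values():
        for sid in rx.stoich:
            g.add_edge(rx.id, sid)
    return [set(c) for c in nx.connected_components(g)]


def purge_disconnected_clusters(model: Model, anchor: Optional[str] = None) -> tuple:
    """Keep only the connected component holding ``anchor``; drop the rest.

    The anchor defaults to the biomass reaction; without one the largest
    component is kept, ties broken by the lexicographically smallest member
    id.  Idempotent: the surviving model is connected.
    """
    if anchor is None:
        anchor = model.biomass
    if anchor is not None and anchor not in model.species and anchor not in model.reactions:
        raise ValidationError(f"unknown anchor id {anchor!r}")

    components = _bipartite_components(model)
    if not components:
        return model.copy(), PurgeReport()
    if anchor is not None:
        keep = next(c for c in components if anchor in c)
    else:
        keep = min(components, key=lambda c: (-len(c), min(c)))

    out = model.copy()
    report = PurgeReport()
    for sid in list(out.species):
        if sid not in keep:
            del out.species[sid]
            report.removed_species.append(sid)
    for rid in list(out.reactions):
        if rid not in keep:
            del out.reactions[rid]
            report.removed_reactions.append(rid)
    if out.biomass is not None and out.biomass not in out.reactions:
        out.biomass = None
    report.removed_species.sort()
    report.removed_reactions.sort()
    return out, report


def purge_isolated_nodes(model: Model) -> tuple:
    """Drop species used by no reaction and reactions with empty stoichiometry."""
    used = set()
    for rx in model.reactions.values():
        used.update(rx.stoich)
    out = model.copy()
    report = PurgeReport()
    for sid in list(out.species):
        if sid not in used:
            del out.species[sid]
            report.removed_species.append(sid)
    for rid in list(out.reactions):
        if not out.reactions[rid].stoich:
            del out.reactions[rid]
            report.removed_reactions.append(rid)
    if out.biomass is not None and out.biomass not in out.reactions:
        out.biomass = None
    report.removed_species.sort()
    report.removed_reactions.sort()
    return out, report


# ---------------------------------------------------------------------------
# Search & matrix
# ---------------------------------------------------------------------------


def search(model: Model, query: str) -> list:
    """Case-insensitive substring search over ids and names.

    Returns ``(node id, kind, matched field)`` triples sorted by
    ``(kind, id)``; a node matching on both id and name appears once, with
    the matched field reported as ``"id"``.
    """
    if not query:
        raise ValueError("query must be non-empty")
    q = query.lower()
    hits = []
    for kind, table in (("reaction", model.reactions), ("species", model.species)):
        for node in table.values():
            if q in node.id.lower():
                hits.append((node.id, kind, "id"))
            elif q in node.name.lower():
                hits.append((node.id, kind, "name"))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def stoichiometric_matrix(model: Model):
    """Sparse stoichiometric matrix S plus row/column index maps.

    Rows are the non-boundary species in model order (boundary placeholders
    are exempt from mass balance), columns the reactions in model order.
    Returns ``(S, species_index, reaction_index)`` with S in CSR format.
    """
    rows = [s.id for s in model.species.values() if not s.boundary]
    row_index = {sid: i for i, sid in enumerate(rows)}
    col_index = {rid: j for j, rid in enumerate(model.reactions)}
    data, ri, ci = [], [], []
    for rid, rx in model.reactions.items():
        j = col_index[rid]
        for sid, coef in rx.stoich.items():
            i = row_index.get(sid)
            if i is not None:
                data.append(coef)
                ri.append(i)
                ci.append(j)
    S = sparse.csr_matrix(
        (np.asarray(data, dtype=float), (ri, ci)),
        shape=(len(rows), len(col_index)),
    )
    return S, row_index, col_index
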