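"""Bipartite-graph construction and the network tracking tools.

Tracking tools mirror a curator's workflow: direct neighbours of a node,
endpoint species (never produced or never consumed), blocked modules
(connected groups of blocked nodes that can be repaired independently) and
production ancestry (a small import-rooted subnetwork sufficient to make a
node active, or the strongly connected component when production is
irreducibly cyclic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx

from .core_model import Compartment, Model, ValidationError
from .consistency import ConsistencyResult, BLOCKED

__all__ = [
    "BlockedModule",
    "AncestryResult",
    "NeighbourView",
    "build_graph",
    "neighbours",
    "endpoint_species",
    "blocked_modules",
    "extract_module",
    "ancestry",
    "strongly_connected_components",
]


def build_graph(model: Model) -> nx.DiGraph:
    """Directed bipartite graph: species→reaction = consumption,
    reaction→species = production; edges of reversible reactions carry
    ``bidirectional=True``.  Node attribute ``kind`` is "species" or
    "reaction"."""
    g = nx.DiGraph()
    for sid in model.species:
        g.add_node(sid, kind="species")
    for rx in model.reactions.values():
        g.add_node(rx.id, kind="reaction")
        for sid, coef in rx.stoich.items():
            if coef < 0:
                g.add_edge(sid, rx.id, bidirectional=rx.reversible)
            else:
                g.add_edge(rx.id, sid, bidirectional=rx.reversible)
    return g


@dataclass
class NeighbourView:
    """Direct neighbourhood of one node.

    Each entry is ``(id, via_reverse)``: ``via_reverse`` flags memberships
    that exist only because the connecting reaction is reversible (e.g. a
    reversible producer also listed among the consumers).
    """

    consumed_by: List[Tuple[str, bool]] = field(default_factory=list)
    produced_by: List[Tuple[str, bool]] = field(default_factory=list)
    reactants: List[Tuple[str, bool]] = field(default_factory=list)
    products: List[Tuple[str, bool]] = field(default_factory=list)


def neighbours(model: Model, node_id: str) -> NeighbourView:
    """Consumers/producers of a species, or reactants/products of a reaction."""
    view = NeighbourView()
    if node_id in model.species:
        for rx in model.reactions.values():
            coef = rx.stoich.get(node_id)
            if coef is None:
                continue
            if coef < 0:
                view.consumed_by.append((rx.id, False))
                if rx.reversible:
                    view.produced_by.append((rx.id, True))
            else:
                view.produced_by.append((rx.id, False))
                if rx.reversible:
                    view.consumed_by.append((rx.id, True))
        for lst in (view.consumed_by, view.produced_by):
            lst.sort()
        return view
    if node_id in model.reactions:
        rx = model.reactions[node_id]
        rev = rx.reversible
        view.reactants = sorted((s, rev) for s in rx.reactants)
        view.products = sorted((s, rev) for s in rx.products)
        return view
    raise ValidationError(f"unknown node id {node_id!r}")


def endpoint_species(model: Model) -> Set[str]:
    """Species that nothing can generate or nothing can consume.

    Generation/consumption counts reversibility both ways: a species touched
    only by one reversible reaction is both producible and consumable, hence
    not an endpoint.
    """
    producible: Set[str] = set()
    consumable: Set[str] = set()
    for rx in model.reactions.values():
        for sid, coef in rx.stoich.items():
            if (coef > 0 and rx.ub > 0) or (coef < 0 and rx.lb < 0):
                producible.add(sid)
            if (coef < 0 and rx.ub > 0) or (coef > 0 and rx.lb < 0):
                consumable.add(sid)
    return {s for s in model.species if s not in producible or s not in consumable}


# ---------------------------------------------------------------------------
# Blocked modules
# ---------------------------------------------------------------------------


@dataclass
class BlockedModule:
    """One connected group of blocked species and reactions."""

    module_id: int
    species_ids: List[str]
    reaction_ids: List[str]

    @property
    def members(self) -> Set[str]:
        return set(self.species_ids) | set(self.reaction_ids)

    @property
    def size(self) -> int:
        return len(self.species_ids) + len(self.reaction_ids)


def blocked_modules(model: Model, result: ConsistencyResult) -> List[BlockedModule]:
    """Connected components of the subgraph induced by blocked nodes.

    Modules are numbered from 1 by decreasing size, ties broken by the
    smallest member id; together they partition the blocked node set.
    """
    blocked = result.blocked_nodes
    g = nx.Graph()
    g.add_nodes_from(b for b in blocked)
    for rx in model.reactions.values():
        if rx.id not in blocked:
            continue
        for sid in rx.stoich:
            if sid in blocked:
                g.add_edge(rx.id, sid)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    modules = []
    for i, comp in enumerate(comps, start=1):
        modules.append(
            BlockedModule(
                module_id=i,
                species_ids=sorted(c for c in comp if c in model.species),
                reaction_ids=sorted(c for c in comp if c in model.reactions),
            )
        )
    return modules


def modules_tsv(modules: List[BlockedModule]) -> str:
    rows = ["module_id\tkind\tid"]
    for mod in modules:
        for sid in mod.species_ids:
            rows.append(f"{mod.module_id}\tspecies\t{sid}")
        for rid in mod.reaction_ids:
            rows.append(f"{mod.module_id}\treaction\t{rid}")
    return "\n".join(rows) + "\n"


def extract_module(model: Model, module: BlockedModule, context: int = 0) -> Model:
    """A standalone sub-model of the module, ids preserved.

    ``context`` adds a halo of adjacent nodes up to that bipartite depth
    (depth 1 from a member species reaches the reactions touching it, and so
    on).  Reactions keep only the stoichiometry entries whose species are
    included.  Edits recorded against the extract can be re-applied to the
    parent because every id is shared.
    """
    stale = [i for i in module.members
             if i not in model.species and i not in model.reactions]
    if stale:
        raise ValidationError(f"stale module: ids not in model: {sorted(stale)}")

    keep = set(module.members)
    frontier = set(keep)
    for _ in range(context):
        nxt: Set[str] = set()
        for node in frontier:
            if node in model.species:
                for rx in model.reactions.values():
                    if node in rx.stoich and rx.id not in keep:
                        nxt.add(rx.id)
            else:
                for sid in model.reactions[node].stoich:
                    if sid not in keep:
                        nxt.add(sid)
        keep |= nxt
        frontier = nxt

    sub = Model(id=f"{model.id}_module{module.module_id}", name=model.name)
    comps = {model.species[s].compartment for s in keep if s in model.species}
    for cid in model.compartments:
        if cid in comps:
            sub.add_compartment(model.compartments[cid].copy())
    for sid, sp in model.species.items():
        if sid in keep:
            sub.add_species(sp.copy())
    for rid, rx in model.reactions.items():
        if rid in keep:
            r = rx.copy()
            r.stoich = {s: c for s, c in r.stoich.items() if s in keep}
            sub.add_reaction(r)
    if model.biomass in sub.reactions:
        sub.biomass = model.biomass
    sub.validate()
    return sub


# ---------------------------------------------------------------------------
# Ancestry
# ---------------------------------------------------------------------------


@dataclass
class AncestryResult:
    """Minimal production subnetwork for a node, or the SCC when cyclic."""

    target: str
    kind: str  # "acyclic" | "cyclic"
    members: Set[str]
    imports_used: Set[str] = field(default_factory=set)

    def to_tsv(self, model: Model) -> str:
        rows = ["kind\tid"]
        for nid in sorted(self.members):
            k = "species" if nid in model.species else "reaction"
            rows.append(f"{k}\t{nid}")
        return "\n".join(rows) + "\n"


def _directions(model: Model):
    """Usable (reaction, direction) pairs with their reactant/product id sets.

    Boundary species are placeholders outside mass balance and never count
    as requirements.  Direction +1 needs ub > 0, −1 needs lb < 0 (the
    product/reactant roles swap).
    """
    dirs = []
    for rx in model.reactions.values():
        nb = {s: c for s, c in rx.stoich.items() if not model.species[s].boundary}
        react = frozenset(s for s, c in nb.items() if c < 0)
        prod = frozenset(s for s, c in nb.items() if c > 0)
        if rx.ub > 0:
            dirs.append((rx.id, 1, react, prod))
        if rx.lb < 0:
            dirs.append((rx.id, -1, prod, react))
    return dirs


def ancestry(model: Model, target: str) -> AncestryResult:
    """Smallest production subnetwork for ``target`` (layered heuristic).

    Nodes are costed in dependency layers from the imports upward:
    ``set(reaction direction) = {reaction} ∪ union of its reactants' sets``
    and ``set(species) = {species} ∪ set(best producing direction)``, with
    the union de-duplicating shared ancestors; cost is the set size and ties
    go to the smaller reaction id.  If the target never resolves, its
    production is irreducibly cyclic and the strongly connected component
    at the first unresolvable dependency is reported instead.
    """
    if target not in model.species and target not in model.reactions:
        raise ValidationError(f"unknown node id {target!r}")
    dirs = _directions(model)

    best: Dict[str, frozenset] = {}  # species id -> member set
    for sid in model.species:
        if model.species[sid].boundary:
            best[sid] = frozenset()

    def dir_set(react: frozenset) -> Optional[frozenset]:
        acc: Set[str] = set()
        for s in react:
            bs = best.get(s)
            if bs is None:
                return None
            acc |= bs
        return frozenset(acc)

    changed = True
    guard = len(model.species) + len(model.reactions) + 1
    while changed and guard:
        changed = False
        guard -= 1
        for rid, _sig, react, prod in sorted(dirs, key=lambda d: d[0]):
            base = dir_set(react)
            if base is None:
                continue
            rset = base | {rid}
            for sid in prod:
                cand = frozenset(rset | {sid})
                cur = best.get(sid)
                if cur is None or len(cand) < len(cur) or (
                    len(cand) == len(cur) and sorted(cand) < sorted(cur)
                ):
                    best[sid] = cand
                    changed = True

    if target in model.reactions:
        rx_dirs = [(rid, sig, react, prod) for rid, sig, react, prod in dirs
                   if rid == target]
        options = []
        for rid, _sig, react, _prod in rx_dirs:
            base = dir_set(react)
            if base is not None:
                options.append(frozenset(base | {rid}))
        members = min(options, key=lambda s: (len(s), sorted(s))) if options else None
    else:
        members = best.get(target)

    if members is not None:
        imports_used = {
            rid for rid in members
            if rid in model.reactions and _is_import_within(model, rid, members)
        }
        return AncestryResult(target=target, kind="acyclic", members=set(members),
                              imports_used=imports_used)

    # cyclic fallback: report the SCC at the first unresolvable dependency
    g = build_graph(model)
    sccs = strongly_connected_components(g)
    in_scc = {n: comp for comp in sccs for n in comp}
    seen = {target}
    queue = [target]
    while queue:
        node = queue.pop(0)
        comp = in_scc.get(node)
        if comp is not None and _scc_unresolved(model, comp, best):
            return AncestryResult(target=target, kind="cyclic", members=set(comp))
        # walk backwards over unresolved dependencies
        if node in model.species:
            deps = [rid for rid, _s, _re, prod in dirs if node in prod]
        else:
            deps = sorted({s for rid, _s, react, _p in dirs if rid == node
                           for s in react if best.get(s) is None})
        for d in deps:
            if d not in seen:
                seen.add(d)
                queue.append(d)
    # disconnected target with no producers at all: degenerate single node
    return AncestryResult(target=target, kind="cyclic", members={target})


def _is_import_within(model: Model, rid: str, members: frozenset) -> bool:
    rx = model.reactions[rid]
    nb = {s: c for s, c in rx.stoich.items() if not model.species[s].boundary}
    fwd_react = [s for s, c in nb.items() if c < 0]
    back_react = [s for s, c in nb.items() if c > 0]
    if rx.ub > 0 and not fwd_react:
        return True
    if rx.lb < 0 and not back_react:
        return True
    return False


def _scc_unresolved(model: Model, comp: set, best: Dict[str, frozenset]) -> bool:
    return any(n in model.species and best.get(n) is None for n in comp)


def strongly_connected_components(graph: nx.DiGraph) -> List[Set[str]]:
    """Non-trivial SCCs of the graph, bidirectional edges expanded both ways."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        g.add_edge(u, v)
        if data.get("bidirectional"):
            g.add_edge(v, u)
    return [set(c) for c in nx.strongly_connected_components(g) if len(c) > 1]
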