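"""Synthetic metabolic models with planted inconsistencies and ground truth.

The generator emulates the situations a curator meets in real draft
reconstructions — dead-end metabolites, orphan substrates, misdirected
exchange reactions and stoichiometric carrier traps — on top of a backbone
that is flux-consistent by construction (a randomly branched pathway from an
import to one or more exports, with unit stoichiometry and optional
reversible steps).  Ground-truth blocked sets are recorded by running the
per-reaction LP oracle on the emitted model, so labels can never drift from
the generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_model import Compartment, Model, Reaction, Species, DEFAULT_BOUND
from .consistency import ConsistencyConfig, blocked_oracle

__all__ = ["SyntheticTruth", "toy_models", "random_model", "plant", "PLANT_KINDS"]

PLANT_KINDS = ("dead_end", "orphan_substrate", "misdirected", "trap")


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside a generated model."""

    blocked_reactions: set = field(default_factory=set)
    blocked_species: set = field(default_factory=set)
    modules: List[set] = field(default_factory=list)
    planted: List[Tuple[str, List[str]]] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        data = {
            "blocked_reactions": sorted(self.blocked_reactions),
            "blocked_species": sorted(self.blocked_species),
            "modules": [sorted(m) for m in self.modules],
            "planted": [[kind, sorted(ids)] for kind, ids in self.planted],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            blocked_reactions=set(data["blocked_reactions"]),
            blocked_species=set(data["blocked_species"]),
            modules=[set(m) for m in data["modules"]],
            planted=[(k, list(ids)) for k, ids in data["planted"]],
        )


# ---------------------------------------------------------------------------
# Named toy models
# ---------------------------------------------------------------------------


def _model(mid, species, reactions, biomass=None) -> Model:
    m = Model(id=mid, compartments=[Compartment("c", "cytosol")])
    for sid in species:
        m.add_species(Species(sid, compartment="c"))
    for rid, stoich, lb, ub in reactions:
        m.add_reaction(Reaction(rid, stoich=dict(stoich), lb=lb, ub=ub))
    m.biomass = biomass
    m.validate()
    return m


def toy_models() -> Dict[str, Model]:
    """The named toy models used throughout the tests and documentation.

    chain3
        a consistent import → conversion → export chain.
    deadend
        an imported species converted into a product nothing consumes.
    misdirected
        a conversion written against the flow: everything is FBA-blocked but
        fully active once directionality is relaxed.
    loop
        a two-reaction A↔B cycle with no exchange at all.
    two_modules
        the chain3 core plus two disjoint blocked dead-ends.
    biomass_toy
        growth on an imported precursor plus a side branch with no consumer:
        FBA-blocked, dynamic-active.
    """
    B = DEFAULT_BOUND
    return {
        "chain3": _model(
            "chain3",
            ["A", "B"],
            [("EX_A", {"A": 1}, 0, B), ("R_AB", {"A": -1, "B": 1}, 0, B),
             ("EX_B", {"B": -1}, 0, B)],
        ),
        "deadend": _model(
            "deadend",
            ["A", "B"],
            [("EX_A", {"A": 1}, 0, B), ("R_AB", {"A": -1, "B": 1}, 0, B)],
        ),
        "misdirected": _model(
            "misdirected",
            ["A", "B"],
            [("EX_A", {"A": 1}, 0, B), ("R1", {"B": -1, "A": 1}, 0, B),
             ("EX_B", {"B": -1}, 0, B)],
        ),
        "loop": _model(
            "loop",
            ["A", "B"],
            [("R1", {"A": -1, "B": 1}, 0, B), ("R2", {"B": -1, "A": 1}, 0, B)],
        ),
        "two_modules": _model(
            "two_modules",
            ["A", "B", "P", "X"],
            [("EX_A", {"A": 1}, 0, B), ("R_AB", {"A": -1, "B": 1}, 0, B),
             ("EX_B", {"B": -1}, 0, B),
             ("R_P", {"A": -1, "P": 1}, 0, B),
             ("R_X", {"A": -1, "X": 1}, 0, B)],
        ),
        "biomass_toy": _model(
            "biomass_toy",
            ["A", "B"],
            [("EX_A", {"A": 1}, 0, B), ("BIO", {"A": -1}, 0, B),
             ("R_AB", {"A": -1, "B": 1}, 0, B)],
            biomass="BIO",
        ),
    }


# ---------------------------------------------------------------------------
# Random consistent backbones
# ---------------------------------------------------------------------------


def random_model(
    n_species: int,
    n_reactions: int,
    rev_fraction: float = 0.0,
    seed: int = 0,
) -> Model:
    """A random flux-consistent model of exactly the requested size.

    The backbone is a randomly branched unit-stoichiometry pathway: one
    import feeds a random tree over all species, and every leaf gets an
    export, so each backbone reaction can route flux from the import to an
    export.  Any remaining reaction budget becomes single-substrate,
    single-product cross-links between backbone species, which are likewise
    consistent (substrate producible, product consumable).  A ``rev_fraction``
    share of the conversion and cross-link reactions is made reversible.
    Deterministic per seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_reactions < 1:
        raise ValueError("need at least 1 reaction")
    max_leaves = n_reactions - n_species  # import + (n-1) conversions + leaves
    if max_leaves < 1:
        raise ValueError(
            f"n_reactions={n_reactions} too small for a consistent backbone over "
            f"{n_species} species (need at least {n_species + 1})"
        )
    rng = np.random.default_rng(seed)
    B = DEFAULT_BOUND

    m = Model(id=f"random_s{n_species}_r{n_reactions}_seed{seed}",
              compartments=[Compartment("c", "cytosol")])
    sids = [f"M{i:03d}" for i in range(n_species)]
    for sid in sids:
        m.add_species(Species(sid, compartment="c"))

    children: Dict[int, int] = {0: 0}
    leaves = {0}
    convertibles = []
    for i in range(1, n_species):
        if len(leaves) >= max_leaves:
            parent = int(rng.choice(sorted(leaves)))
        else:
            parent = int(rng.integers(i))
        rid = f"R{i:03d}"
        m.add_reaction(Reaction(rid, stoich={sids[parent]: -1.0, sids[i]: 1.0},
                                lb=0.0, ub=B))
        convertibles.append(rid)
        leaves.discard(parent)
        leaves.add(i)
        children[i] = 0

    m.add_reaction(Reaction(f"IM_{sids[0]}", stoich={sids[0]: 1.0}, lb=0.0, ub=B))
    for leaf in sorted(leaves):
        m.add_reaction(Reaction(f"EX_{sids[leaf]}", stoich={sids[leaf]: -1.0},
                                lb=0.0, ub=B))

    extra = n_reactions - len(m.reactions)
    for k in range(extra):
        a, b = rng.choice(n_species, size=2, replace=False)
        rid = f"X{k:03d}"
        m.add_reaction(Reaction(rid, stoich={sids[int(a)]: -1.0, sids[int(b)]: 1.0},
                                lb=0.0, ub=B))
        convertibles.append(rid)

    if rev_fraction > 0:
        for rid in convertibles:
            if rng.random() < rev_fraction:
                m.reactions[rid].lb = -B

    m.validate()
    assert len(m.reactions) == n_reactions
    return m


# ---------------------------------------------------------------------------
# Planted inconsistencies
# ---------------------------------------------------------------------------


def plant(model: Model, kind: str, seed: int = 0,
          cfg: Optional[ConsistencyConfig] = None) -> Tuple[Model, SyntheticTruth]:
    """Plant one inconsistency of the given kind into a copy of ``model``.

    dead_end
        a new species with a producer but no consumer.
    orphan_substrate
        a new reaction consuming a species nothing ever produces.
    misdirected
        an exchange written in the wrong direction strands its chain: a new
        species that is consumed into the network and also exported, but
        never imported — blocked as written, fully active once
        directionality is relaxed.
    trap
        a carrier species consumed stoichiometrically by a transport pair
        with no regeneration, locking the whole appendage.

    Ground truth is recorded by running :func:`blocked_oracle` on the
    planted model.  Deterministic per seed.
    """
    if kind not in PLANT_KINDS:
        raise ValueError(f"unsupported plant kind {kind!r}; choose from {PLANT_KINDS}")
    rng = np.random.default_rng(seed)
    out = model.copy()
    out.id = f"{model.id}_{kind}"
    B = DEFAULT_BOUND
    hosts = sorted(out.species)
    anchor = hosts[int(rng.integers(len(hosts)))]
    comp = out.species[anchor].compartment

    def add_sp(sid: str) -> str:
        out.add_species(Species(sid, compartment=comp))
        return sid

    planted_ids: List[str] = []
    if kind == "dead_end":
        d = add_sp("P_dead")
        out.add_reaction(Reaction("R_dead", stoich={anchor: -1.0, d: 1.0}, lb=0.0, ub=B))
        planted_ids = [d, "R_dead"]
    elif kind == "orphan_substrate":
        o = add_sp("S_orphan")
        out.add_reaction(Reaction("R_orphan", stoich={o: -1.0, anchor: 1.0}, lb=0.0, ub=B))
        planted_ids = [o, "R_orphan"]
    elif kind == "misdirected":
        u = add_sp("U_mis")
        out.add_reaction(Reaction("R_mis", stoich={u: -1.0, anchor: 1.0}, lb=0.0, ub=B))
        out.add_reaction(Reaction("EX_U_mis", stoich={u: -1.0}, lb=0.0, ub=B))
        planted_ids = [u, "R_mis", "EX_U_mis"]
    else:  # trap
        t = add_sp("T_carrier")
        w = add_sp("W_cargo")
        out.add_reaction(Reaction("R_trap_load", stoich={anchor: -1.0, t: -1.0, w: 1.0},
                                  lb=0.0, ub=B))
        out.add_reaction(Reaction("EX_W_cargo", stoich={w: -1.0}, lb=0.0, ub=B))
        planted_ids = [t, w, "R_trap_load", "EX_W_cargo"]

    out.validate()
    res = blocked_oracle(out, cfg or ConsistencyConfig())
    truth = SyntheticTruth(
        blocked_reactions=res.blocked_reactions,
        blocked_species=res.blocked_species,
        planted=[(kind, planted_ids)],
    )
    from .topology import blocked_modules  # local import: avoids a cycle

    truth.modules = [
        set(mod.species_ids) | set(mod.reaction_ids)
        for mod in blocked_modules(out, res)
    ]
    return out, truth
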