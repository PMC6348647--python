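"""Compartment-aware force-directed layout and static SVG/DOT rendering.

Layout is two-phase: a spring embedding of each compartment's species and
internal reactions, then deterministic packing of the compartments on the
canvas along a spiral so their contours never overlap.  Contours are padded
convex hulls, so every species lies strictly inside its compartment's
polygon.  Transport reactions (touching two or more compartments) sit at the
centroid of their participants, nudged outside all contours.

Visual encoding: reactions are bright and species dark shades of the same
hue — green when active, red when blocked, neutral grey without a
consistency result; endpoint species get a light-blue outline, the biomass
reaction a thick yellow one, compartment contours are orange, edges are grey
semi-transparent arrows with one or two heads depending on reversibility,
and highlighted nodes are circled in purple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx
import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon

from .core_model import Model
from .consistency import ConsistencyResult, BLOCKED, ACTIVE
from .topology import BlockedModule, endpoint_species, extract_module

__all__ = ["Layout", "compute_layout", "render_svg", "export_dot", "render_module", "STYLE"]

#: one style table so snapshots stay stable
STYLE = {
    "species_active": "#1b5e20",   # dark green
    "species_blocked": "#8e0000",  # dark red
    "species_none": "#616161",     # dark grey
    "reaction_active": "#4caf50",  # bright green
    "reaction_blocked": "#ff5252", # bright red
    "reaction_none": "#bdbdbd",    # bright grey
    "endpoint_outline": "#81d4fa", # light blue
    "biomass_outline": "#ffd600",  # yellow
    "contour": "#ff9800",          # orange
    "edge": "#808080",
    "highlight": "#9c27b0",        # purple
}

NODE_RADIUS = 8.0
PAD = 2.0 * NODE_RADIUS  # contour padding: one node diameter
GAP = 3.0 * NODE_RADIUS  # spacing between packed compartments


@dataclass
class Layout:
    """Node positions plus convex compartment contours, reproducible per seed."""

    positions: Dict[str, Tuple[float, float]]
    contours: Dict[str, List[Tuple[float, float]]]
    seed: int
    iterations: int

    def polygon(self, compartment_id: str) -> Polygon:
        return Polygon(self.contours[compartment_id])


def _compartment_groups(model: Model):
    """Species and internal reactions per compartment, plus the rest.

    A reaction is internal to a compartment when all its species live there;
    reactions spanning compartments are transport, reactions with empty
    stoichiometry are free-floating.
    """
    groups: Dict[str, List[str]] = {cid: [] for cid in model.compartments}
    for sp in model.species.values():
        groups.setdefault(sp.compartment or "", []).append(sp.id)
    transport, floating = [], []
    for rx in model.reactions.values():
        comps = {model.species[s].compartment or "" for s in rx.stoich}
        if len(comps) == 1:
            groups.setdefault(next(iter(comps)), []).append(rx.id)
        elif len(comps) == 0:
            floating.append(rx.id)
        else:
            transport.append(rx.id)
    return groups, transport, floating


def compute_layout(model: Model, seed: int = 0, iterations: int = 500) -> Layout:
    """Two-phase deterministic layout (see module docstring)."""
    if not model.species and not model.reactions:
        raise ValueError("cannot lay out an empty model")
    groups, transport, floating = _compartment_groups(model)

    local: Dict[str, Dict[str, np.ndarray]] = {}
    boxes: Dict[str, Tuple[float, float]] = {}
    for cid in sorted(groups):
        members = groups[cid]
        if not members:
            continue
        g = nx.Graph()
        g.add_nodes_from(members)
        member_set = set(members)
        for rid in members:
            rx = model.reactions.get(rid)
            if rx is None:
                continue
            for sid in rx.stoich:
                if sid in member_set:
                    g.add_edge(rid, sid)
        scale = NODE_RADIUS * 3.0 * max(1.0, math.sqrt(len(members)))
        pos = nx.spring_layout(g, seed=seed, iterations=iterations, scale=scale) \
            if len(members) > 1 else {members[0]: np.zeros(2)}
        xs = [p[0] for p in pos.values()]
        ys = [p[1] for p in pos.values()]
        shift = np.array([min(xs), min(ys)])
        local[cid] = {n: np.asarray(p) - shift for n, p in pos.items()}
        boxes[cid] = (max(xs) - min(xs) + 2 * (PAD + GAP),
                      max(ys) - min(ys) + 2 * (PAD + GAP))

    # pack compartment boxes on an Archimedean spiral, big first, first fit
    order = sorted(boxes, key=lambda c: (-boxes[c][0] * boxes[c][1], c))
    placed: Dict[str, Tuple[float, float]] = {}
    rects: List[Tuple[float, float, float, float]] = []

    def overlaps(x, y, w, h) -> bool:
        return any(x < rx + rw and rx < x + w and y < ry + rh and ry < y + h
                   for rx, ry, rw, rh in rects)

    for cid in order:
        w, h = boxes[cid]
        t = 0.0
        while True:
            r = 4.0 * NODE_RADIUS * t
            x = r * math.cos(t) - w / 2.0
            y = r * math.sin(t) - h / 2.0
            if not overlaps(x, y, w, h):
                placed[cid] = (x, y)
                rects.append((x, y, w, h))
                break
            t += 0.15

    positions: Dict[str, Tuple[float, float]] = {}
    contours: Dict[str, List[Tuple[float, float]]] = {}
    polygons: List[Polygon] = []
    for cid, members in local.items():
        ox, oy = placed[cid]
        pts = []
        for nid, p in members.items():
            xy = (round(float(p[0] + ox + PAD + GAP), 3),
                  round(float(p[1] + oy + PAD + GAP), 3))
            positions[nid] = xy
            pts.append(xy)
        if cid in model.compartments:
            hull = MultiPoint(pts).convex_hull.buffer(PAD, quad_segs=4)
            coords = [(round(x, 3), round(y, 3)) for x, y in hull.exterior.coords]
            contours[cid] = coords
            polygons.append(Polygon(coords))

    # transport reactions: participant centroid, nudged outside every contour
    for rid in transport:
        rx = model.reactions[rid]
        pts = np.array([positions[s] for s in rx.stoich])
        p = Point(pts.mean(axis=0))
        for poly in polygons:
            if poly.covers(p):
                c = poly.centroid
                d = np.array([p.x - c.x, p.y - c.y])
                norm = np.hypot(*d)
                d = d / norm if norm > 1e-9 else np.array([1.0, 0.0])
                radius = poly.exterior.distance(c)
                q = np.array([c.x, c.y]) + d * (radius + PAD)
                step = 0
                while poly.covers(Point(q)) and step < 64:
                    q += d * PAD
                    step += 1
                p = Point(q)
        positions[rid] = (round(p.x, 3), round(p.y, 3))

    # free-floating reactions parked on a row below everything
    if floating:
        min_y = min((y for _, y in positions.values()), default=0.0)
        for i, rid in enumerate(sorted(floating)):
            positions[rid] = (i * 3.0 * NODE_RADIUS, min_y - 4.0 * NODE_RADIUS)

    return Layout(positions=positions, contours=contours, seed=seed,
                  iterations=iterations)


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _svg_document(model: Model, layout: Layout,
                  result: Optional[ConsistencyResult],
                  highlight: Optional[Set[str]]) -> str:
    highlight = highlight or set()
    xs = [p[0] for p in layout.positions.values()]
    ys = [p[1] for p in layout.positions.values()]
    for poly in layout.contours.values():
        xs += [p[0] for p in poly]
        ys += [p[1] for p in poly]
    margin = 4 * NODE_RADIUS
    x0, y0 = min(xs) - margin, min(ys) - margin
    w, h = max(xs) - x0 + margin, max(ys) - y0 + margin

    def status(nid: str) -> Optional[str]:
        if result is None:
            return None
        try:
            return result.status_of(nid)
        except KeyError:
            return None

    endpoints = endpoint_species(model)
    out: List[str] = []
    out.append(
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'viewBox="{_fmt(x0)} {_fmt(y0)} {_fmt(w)} {_fmt(h)}">'
    )
    out.append(
        "<defs>"
        f'<marker id="arrow" markerWidth="8" markerHeight="8" refX="7" refY="3" '
        'orient="auto"><path d="M0,0 L7,3 L0,6 z" fill="'
        + STYLE["edge"] + '"/></marker>'
        f'<marker id="arrowback" markerWidth="8" markerHeight="8" refX="1" refY="3" '
        'orient="auto"><path d="M8,0 L1,3 L8,6 z" fill="'
        + STYLE["edge"] + '"/></marker>'
        "</defs>"
    )

    for cid in sorted(layout.contours):
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in layout.contours[cid])
        out.append(
            f'<polygon class="contour" points="{pts}" fill="none" '
            f'stroke="{STYLE["contour"]}" stroke-width="2"/>'
        )

    for rid in model.reactions:
        rx = model.reactions[rid]
        x1, y1 = layout.positions[rid]
        for sid, coef in sorted(rx.stoich.items()):
            x2, y2 = layout.positions[sid]
            if coef < 0:  # species -> reaction
                a, b = (x2, y2), (x1, y1)
            else:
                a, b = (x1, y1), (x2, y2)
            extra = ' marker-start="url(#arrowback)"' if rx.reversible else ""
            out.append(
                f'<line x1="{_fmt(a[0])}" y1="{_fmt(a[1])}" '
                f'x2="{_fmt(b[0])}" y2="{_fmt(b[1])}" '
                f'stroke="{STYLE["edge"]}" stroke-opacity="0.5" '
                f'stroke-width="1.5" marker-end="url(#arrow)"{extra}/>'
            )

    for sid in model.species:
        x, y = layout.positions[sid]
        st = status(sid)
        fill = (STYLE["species_none"] if st is None else
                STYLE["species_blocked"] if st == BLOCKED else STYLE["species_active"])
        stroke = (f' stroke="{STYLE["endpoint_outline"]}" stroke-width="2.5"'
                  if sid in endpoints else "")
        out.append(
            f'<circle class="species" cx="{_fmt(x)}" cy="{_fmt(y)}" '
            f'r="{_fmt(NODE_RADIUS)}" fill="{fill}"{stroke}>'
            f"<title>{sid}</title></circle>"
        )

    for rid in model.reactions:
        x, y = layout.positions[rid]
        st = status(rid)
        fill = (STYLE["reaction_none"] if st is None else
                STYLE["reaction_blocked"] if st == BLOCKED else STYLE["reaction_active"])
        stroke = (f' stroke="{STYLE["biomass_outline"]}" stroke-width="4"'
                  if rid == model.biomass else "")
        s = NODE_RADIUS
        out.append(
            f'<rect class="reaction" x="{_fmt(x - s)}" y="{_fmt(y - s)}" '
            f'width="{_fmt(2 * s)}" height="{_fmt(2 * s)}" fill="{fill}"{stroke}>'
            f"<title>{rid}</title></rect>"
        )

    for nid in sorted(highlight):
        if nid not in layout.positions:
            continue
        x, y = layout.positions[nid]
        out.append(
            f'<circle class="highlight" cx="{_fmt(x)}" cy="{_fmt(y)}" '
            f'r="{_fmt(2.2 * NODE_RADIUS)}" fill="none" '
            f'stroke="{STYLE["highlight"]}" stroke-width="2.5"/>'
        )

    out.append("</svg>")
    return "\n".join(out) + "\n"


def render_svg(
    model: Model,
    layout: Layout,
    result: Optional[ConsistencyResult] = None,
    path: Optional[str] = None,
    highlight: Optional[Set[str]] = None,
) -> str:
    """Render the model to SVG 1.1; pure — identical inputs give identical bytes.

    Returns the SVG text; writes it to ``path`` when given.
    """
    missing = [n for n in list(model.species) + list(model.reactions)
               if n not in layout.positions]
    if missing:
        raise ValueError(f"layout does not cover nodes: {missing[:5]}")
    doc = _svg_document(model, layout, result, highlight)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc


# ---------------------------------------------------------------------------
# DOT / module rendering
# ---------------------------------------------------------------------------


def export_dot(model: Model, result: Optional[ConsistencyResult] = None,
               path: Optional[str] = None) -> str:
    """Graphviz DOT export: ellipse species, box reactions, compartments as
    clusters, ``dir=both`` on reversible edges, status as fillcolor."""

    def color(nid: str, kind: str) -> str:
        if result is None:
            return STYLE[f"{kind}_none"]
        try:
            st = result.status_of(nid)
        except KeyError:
            return STYLE[f"{kind}_none"]
        return STYLE[f"{kind}_blocked"] if st == BLOCKED else STYLE[f"{kind}_active"]

    lines = [f'digraph "{model.id}" {{', "  rankdir=LR;"]
    groups, transport, floating = _compartment_groups(model)
    for cid in sorted(groups):
        members = groups[cid]
        if not members:
            continue
        indent = "  "
        cluster = cid in model.compartments
        if cluster:
            lines.append(f'  subgraph "cluster_{cid}" {{')
            lines.append(f'    label="{model.compartments[cid].name or cid}"; color="{STYLE["contour"]}";')
            indent = "    "
        for nid in sorted(members):
            kind = "species" if nid in model.species else "reaction"
            shape = "ellipse" if kind == "species" else "box"
            lines.append(
                f'{indent}"{nid}" [shape={shape}, style=filled, '
                f'fillcolor="{color(nid, kind)}"];'
            )
        if cluster:
            lines.append("  }")
    for rid in sorted(transport + floating):
        lines.append(
            f'  "{rid}" [shape=box, style=filled, fillcolor="{color(rid, "reaction")}"];'
        )
    for rid in sorted(model.reactions):
        rx = model.reactions[rid]
        attr = " [dir=both]" if rx.reversible else ""
        for sid, coef in sorted(rx.stoich.items()):
            if coef < 0:
                lines.append(f'  "{sid}" -> "{rid}"{attr};')
            else:
                lines.append(f'  "{rid}" -> "{sid}"{attr};')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def render_module(
    model: Model,
    module: BlockedModule,
    result: Optional[ConsistencyResult] = None,
    path: Optional[str] = None,
    seed: int = 0,
    iterations: int = 500,
    context: int = 0,
) -> str:
    """Extract a blocked module, lay it out on its own and render it to SVG."""
    sub = extract_module(model, module, context=context)
    layout = compute_layout(sub, seed=seed, iterations=iterations)
    sub_result = None
    if result is not None:
        sub_result = ConsistencyResult(
            mode=result.mode,
            reaction_status={r: result.reaction_status[r] for r in sub.reactions
                             if r in result.reaction_status},
            species_status={s: result.species_status[s] for s in sub.species
                            if s in result.species_status},
            lp_count=result.lp_count,
            config=result.config,
        )
    return render_svg(sub, layout, sub_result, path)
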