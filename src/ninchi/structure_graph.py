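"""Component-relation graphs: hierarchy, interface and defect operators.

A multi-component nanomaterial is more than a bag of parts: a silica-coated
gold sphere is the gold core, the silica shell, and the *relation* "shell
coats core".  The overall-structure layer ``y1&2`` orders components from
the inside out; this module turns that ordering — plus interface annotations
(bond labels, mixing fractions) and defect operators — into a directed
graph whose edges can be queried, mass-balanced and round-tripped back to
the notation.

Mixtures use the ``{items}:{fractions}`` operator.  Fractions may be left
incomplete; :func:`missing_fraction` reports the unaccounted share (e.g.
``{0.5, 0.3}`` leaves 20% of the input undescribed).  Defect extents
combine by set operators under a zero-overlap default, bounded by
inclusion–exclusion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import networkx as nx

from ._text import fmt_number, normalize_text, split_top

if TYPE_CHECKING:  # pragma: no cover
    from .grammar_core import NanoRepresentation

__all__ = [
    "MixtureSpec",
    "RelationEdge",
    "DefectSpec",
    "StructureGraph",
    "StructureError",
    "parse_mixture",
    "missing_fraction",
    "build_graph",
    "apply_defect",
    "combine_extents",
    "query",
    "containment_paths",
]

_FRACTION_TOL = 1e-9


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class MixtureSpec:
    """``{items}:{fractions}`` — items with (possibly partial) fractions.

    ``items`` are free tokens or 1-based component indices; ``fractions``
    entries are floats in [0, 1], or distribution-expression strings (e.g. a
    purity claim ``cdf(1,0.995)``).  With a concentration unit (``mg/L``)
    the numbers are concentrations, not fractions.  ``items_elided`` marks
    the ``...`` placeholder.
    """

    items: tuple = ()
    fractions: tuple = ()
    unit: str | None = None
    fraction_kind: str = "unknown"
    items_elided: bool = False
    notes: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.unit is None:
            s = sum(f for f in self.fractions if isinstance(f, float))
            if s > 1 + _FRACTION_TOL:
                raise StructureError(f"mixture fractions sum to {s} > 1")

    def canonical(self) -> str:
        items = "..." if self.items_elided else (
            "{" + ",".join(str(i) for i in self.items) + "}"
        )
        fracs = ",".join(
            fmt_number(f) if isinstance(f, float) else str(f) for f in self.fractions
        )
        return f"{items}:{{{fracs}}}{self.unit or ''}"


@dataclass(frozen=True)
class RelationEdge:
    source: int
    target: int
    relation: str
    bond_label: str | None = None
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.fraction is not None and not 0 < self.fraction <= 1:
            raise StructureError(f"edge fraction {self.fraction} outside (0, 1]")


@dataclass(frozen=True)
class DefectSpec:
    """A point-defect class with an extent (scalar fraction or DistExpr text)."""

    defect_kind: str
    extent: float | str = 0.0
    set_op: str = "union"

    def __post_init__(self) -> None:
        if isinstance(self.extent, float) and not 0 <= self.extent <= 1:
            raise StructureError(f"scalar defect extent {self.extent} outside [0, 1]")
        if self.set_op not in ("union", "intersection", "difference"):
            raise StructureError(f"unknown set operator {self.set_op!r}")


# ---------------------------------------------------------------------------
# mixtures
# ---------------------------------------------------------------------------

_MIX_RE = re.compile(r"^\s*(\{(?P<items>.*?)\}|\.\.\.)\s*:\s*\{(?P<fr>.*?)\}\s*(?P<unit>[A-Za-z/%]*)\s*$")
_NUM_RE = re.compile(r"^[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?$")
_EXPR_RE = re.compile(r"^[a-z]+\(.*\)$")


def parse_mixture(text: str) -> MixtureSpec:
    """Parse ``"{NaCl, glucose}:{0.0045,0.001}"``-style mixture operators."""
    m = _MIX_RE.match(normalize_text(text))
    if not m:
        raise StructureError(f"malformed mixture {text!r}")
    elided = m.group(1) == "..."
    items: tuple = ()
    if not elided and m.group("items").strip():
        toks = [t.strip() for t, _ in split_top(m.group("items"), ",")]
        items = tuple(int(t) if t.isdigit() else t for t in toks)
    unit = m.group("unit") or None
    fractions: list = []
    if m.group("fr").strip():
        for tok, _ in split_top(m.group("fr"), ","):
            tok = tok.strip()
            if _NUM_RE.match(tok):
                v = float(tok)
                if unit is None and v > 1:
                    raise StructureError(
                        f"dimensionless fraction {v} > 1 (supply a unit for concentrations)"
                    )
                fractions.append(v)
            elif _EXPR_RE.match(tok):
                fractions.append(tok)
            else:
                raise StructureError(f"malformed fraction {tok!r}")
    notes = []
    if items and fractions and len(items) != len(fractions):
        notes.append(f"{len(items)} items vs {len(fractions)} fractions")
    kind = "mass" if unit and ("g" in unit or "%" in unit) else "unknown"
    return MixtureSpec(items, tuple(fractions), unit, kind, elided, tuple(notes))


def missing_fraction(mix: MixtureSpec) -> float:
    """Unaccounted share of a mixture: 1 minus the stated fractions.

    Items without a paired fraction contribute nothing — their share is part
    of the missing mass.  Concentration-valued mixtures (with a unit) need
    an external total and are rejected.
    """
    if mix.unit is not None:
        raise StructureError(
            "concentrations need a stated total to convert to fractions"
        )
    s = sum(f for f in mix.fractions if isinstance(f, float))
    if s > 1 + _FRACTION_TOL:
        raise StructureError(f"mixture fractions sum to {s} > 1")
    return max(0.0, 1.0 - s)


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


@dataclass
class StructureGraph:
    """Directed component-relation graph plus the originating ordering."""

    graph: nx.MultiDiGraph
    ordering: tuple[int, ...] = ()
    mixture: Optional[MixtureSpec] = None

    def edges(self) -> list[RelationEdge]:
        out = [
            RelationEdge(u, v, d.get("relation", ""), d.get("bond_label"), d.get("fraction"))
            for u, v, d in self.graph.edges(data=True)
        ]
        return sorted(out, key=lambda e: (e.source, e.target, e.relation))

    def node_defects(self, node: int) -> list[DefectSpec]:
        return list(self.graph.nodes[node].get("defects", ()))

    def to_edgelist_text(self) -> str:
        lines = [
            "\t".join(
                [str(e.source), e.relation, str(e.target), e.bond_label or "-",
                 fmt_number(e.fraction) if e.fraction is not None else "-"]
            )
            for e in self.edges()
        ]
        return "\n".join(lines)

    def to_structural_layer(self):
        """Back-map to a structural layer; build_graph of it is a fixed point."""
        from .grammar_core import InterfaceSpec, StructuralLayer

        chain_pairs = set(zip(self.ordering[1:], self.ordering[:-1]))
        interfaces = tuple(
            InterfaceSpec(e.source, e.target, e.relation, e.bond_label, e.fraction)
            for e in self.edges()
            if (e.source, e.target) not in chain_pairs or e.relation != "coats"
        )
        return StructuralLayer(self.ordering, self.mixture, interfaces)


def build_graph(rep: "NanoRepresentation") -> StructureGraph:
    """Build the relation graph from a representation's structural layer.

    The inside-out ordering ``i&j&...`` becomes a chain of ``coats`` edges
    directed outer -> inner; interface annotations attach additional labelled
    edges; the mixture spec rides along on the graph.
    """
    if rep.structural is None:
        raise StructureError("representation has no structural layer")
    n = len(rep.components)
    g: nx.MultiDiGraph = nx.MultiDiGraph()
    for idx, comp in enumerate(rep.components, start=1):
        g.add_node(idx, label=comp.composition)
    layer = rep.structural
    for idx in layer.ordering:
        if not 1 <= idx <= n:
            raise StructureError(f"component index {idx} out of range 1..{n}")
    for inner, outer in zip(layer.ordering[:-1], layer.ordering[1:]):
        g.add_edge(outer, inner, relation="coats")
    for spec in layer.interfaces:
        for idx in (spec.source, spec.target):
            if not 1 <= idx <= n:
                raise StructureError(f"component index {idx} out of range 1..{n}")
        g.add_edge(
            spec.source,
            spec.target,
            relation=spec.relation,
            bond_label=spec.bond_label,
            fraction=spec.fraction,
        )
    containment = nx.MultiDiGraph(
        (u, v) for u, v, d in g.edges(data=True) if d["relation"] in ("coats", "contains")
    )
    if containment.number_of_edges() and not nx.is_directed_acyclic_graph(containment):
        raise StructureError("containment hierarchy contains a cycle")
    if layer.mixture is not None:
        for item in layer.mixture.items:
            if isinstance(item, int) and not 1 <= item <= n:
                raise StructureError(f"mixture component index {item} out of range 1..{n}")
    return StructureGraph(g, tuple(layer.ordering), layer.mixture)


def combine_extents(e1: float, e2: float, set_op: str = "union", overlap: float = 0.0) -> float:
    """Combine two defect extents under a set operator.

    Overlap defaults to zero (disjoint defect sets), the inclusion–exclusion
    lower bound: ``max(e1,e2) <= union <= min(1, e1+e2)`` always holds.
    """
    if set_op == "union":
        return min(1.0, e1 + e2 - overlap)
    if set_op == "intersection":
        return overlap
    if set_op == "difference":
        return max(0.0, e1 - overlap)
    raise StructureError(f"unknown set operator {set_op!r}")


def apply_defect(graph: StructureGraph, node: int, defect: DefectSpec) -> StructureGraph:
    """Return a new graph with the defect annotation attached to ``node``."""
    if node not in graph.graph:
        raise StructureError(f"node {node} not in graph")
    if isinstance(defect.extent, float) and not 0 <= defect.extent <= 1:
        raise StructureError(f"scalar defect extent {defect.extent} outside [0, 1]")
    g = graph.graph.copy()
    defects = tuple(g.nodes[node].get("defects", ())) + (defect,)
    g.nodes[node]["defects"] = defects
    return StructureGraph(g, graph.ordering, graph.mixture)


_PATTERN_RE = re.compile(r"^\s*([A-Za-z_][\w-]*|\*)\s*\(\s*(\*|\d+)\s*,\s*(\*|\d+)\s*\)\s*$")


def query(graph: StructureGraph, pattern: str) -> list[RelationEdge]:
    """Match edges against ``relation(source, target)`` with ``*`` wildcards.

    ``query(g, "coats(*, 1)")`` finds everything that coats component 1.
    Results are deterministically ordered.
    """
    m = _PATTERN_RE.match(pattern)
    if not m:
        raise StructureError(f"malformed query pattern {pattern!r}")
    rel, src, tgt = m.groups()
    out = []
    for e in graph.edges():
        if rel != "*" and e.relation != rel:
            continue
        if src != "*" and e.source != int(src):
            continue
        if tgt != "*" and e.target != int(tgt):
            continue
        out.append(e)
    return out


def containment_paths(graph: StructureGraph, inner: int, outer: int) -> list[list[int]]:
    """All containment paths from an inner component out to ``outer``.

    Containment edges point outer -> inner, so paths are enumerated on the
    reversed relation.
    """
    sub = nx.DiGraph(
        (u, v)
        for u, v, d in graph.graph.edges(data=True)
        if d["relation"] in ("coats", "contains")
    ).reverse()
    if inner not in sub or outer not in sub:
        return []
    return sorted(nx.all_simple_paths(sub, inner, outer))
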