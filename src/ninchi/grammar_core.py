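"""The nanomaterial line-notation grammar: parse, serialize, validate.

A representation string opens with a version token (``1A`` for the alpha
notation), followed by one component per ``!``-separated segment and then
the cross-component layers.  Within a component, ``/``-delimited sublayers
carry one property class each, identified by prefix:

========  =============================================================
(first)   composition — InChI-style elemental formula, opaque here
``m``     morphology — legacy category (``msp`` sphere, ``msh`` shell)
          or a bracketed harmonic expression ``m[Y(0,0)*scale(4,1,1)]``
``s``     size — scalar ``s20d-9`` (20, diameter qualifier, SI exponent
          -9 => 20 nm) or a bracketed distribution ``s[pdf(30,sd=2)]d-9``
``k``     crystal structure — space-group token, opaque: ``k[P4_2/mnm]``
``w``     chirality — chiral vector for nanotubes, opaque: ``w(6,5)``
========  =============================================================

Cross-component layers: ``y`` (overall structure: inside-out ordering
``y1&2`` and/or a mixture ``y{1,2}:{0.3,0.7}``), ``i`` (interfaces,
``i2-1[bond:b;0.7]``), ``c{...}`` (structured comments) and ``d{...}``
(macro definitions/uses).  Unknown layer prefixes are preserved as opaque
layers with a warning and survive round-trips; the grammar never guarantees
uniqueness — two strings may describe the same material, and equality of
materials is a job for the similarity metrics, not the parser.

Every parse error carries a 0-based character offset into the (normalized)
input.  The normative syntax reference is the shipped ``grammar.ebnf``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from ._text import fmt_number, normalize_text, split_top
from .annotations import CommentInstance, split_comment
from .distributions import DistExpr, DistributionError, parse_dist_expr
from .macros import MacroDefinition, MacroError, MacroInvocation, parse_definition, parse_invocation
from .morphology import BoundingBoxShape, HarmonicShape, ShapeError, from_category, parse_shape_expr
from .structure_graph import MixtureSpec, StructureError, parse_mixture

__all__ = [
    "NanoRepresentation",
    "Component",
    "MorphologyLayer",
    "SizeLayer",
    "StructuralLayer",
    "InterfaceSpec",
    "Issue",
    "NotationParseError",
    "parse",
    "serialize",
    "validate",
    "fixture_generate",
]

VERSION_ALPHA = "1A"
PREFIX = "NInChI="

#: category <-> legacy morphology token table (alpha notation)
_LEGACY_TO_CATEGORY = {"sp": "sphere", "sh": "shell"}
_CATEGORY_TO_LEGACY = {v: k for k, v in _LEGACY_TO_CATEGORY.items()}

_KNOWN_CATEGORIES = {"sphere", "shell", "wire", "rod", "cylinder", "irregular"}

#: does bracket content look like a not-yet-expanded macro fragment?
_MACROISH_RE = re.compile(r"%[A-Za-z]|[A-Z][A-Za-z0-9_]*\s*\(")


class NotationParseError(ValueError):
    """Parse failure with a 0-based character offset into the input."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (offset {offset})")


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    location: str
    message: str


@dataclass(frozen=True)
class MorphologyLayer:
    """Morphology: a category token or a shape expression (one of the two).

    ``expr`` holds the canonical shape-expression string; it may also hold
    unexpanded macro text (containing %-tokens or macro calls), which
    :meth:`to_shape` refuses until expansion.
    """

    category: str | None = None
    expr: str | None = None

    def __post_init__(self) -> None:
        if (self.category is None) == (self.expr is None):
            raise ValueError("exactly one of category/expr must be set")

    def to_shape(self) -> HarmonicShape | BoundingBoxShape:
        if self.category is not None:
            return from_category(self.category)
        return parse_shape_expr(self.expr)  # type: ignore[arg-type]


@dataclass(frozen=True)
class SizeLayer:
    """Size: a strictly positive scalar or a distribution expression.

    ``qualifier``: ``d`` diameter, ``t`` thickness, ``None`` generic length.
    ``exponent``: SI power of the meter (e.g. -9 for nm); ``None`` when the
    layer leaves the power implicit.  ``quantity`` may also be a raw string
    of unexpanded macro text.
    """

    quantity: float | DistExpr | str
    qualifier: str | None = None
    exponent: int | None = None


@dataclass(frozen=True)
class InterfaceSpec:
    source: int
    target: int
    relation: str = "bonded"
    bond_label: str | None = None
    fraction: float | None = None

    def canonical(self) -> str:
        # the notation writes a plain bonded relation as "bond:label"
        body = "bond" if self.relation == "bonded" and self.bond_label else self.relation
        if self.bond_label is not None:
            body += f":{self.bond_label}"
        if self.fraction is not None:
            body += f";{fmt_number(self.fraction)}"
        return f"i{self.source}-{self.target}[{body}]"


@dataclass(frozen=True)
class StructuralLayer:
    """Overall structure: inside-out ordering, mixture, interfaces."""

    ordering: tuple[int, ...] = ()
    mixture: MixtureSpec | None = None
    interfaces: tuple[InterfaceSpec, ...] = ()


@dataclass(frozen=True)
class Component:
    """One constituent of the material: composition plus optional sublayers."""

    composition: str
    morphology: MorphologyLayer | None = None
    size: SizeLayer | None = None
    crystal: str | None = None
    chirality: str | None = None
    extras: tuple[tuple[str, str], ...] = ()  # (prefix, text) opaque layers


@dataclass(frozen=True)
class NanoRepresentation:
    """A parsed representation: ordered components plus cross layers."""

    version: str = VERSION_ALPHA
    components: tuple[Component, ...] = ()
    structural: StructuralLayer | None = None
    comments: tuple[CommentInstance, ...] = ()
    macro_defs: tuple[MacroDefinition, ...] = ()
    macro_uses: tuple[MacroInvocation, ...] = ()
    extras: tuple[tuple[str, str], ...] = ()
    prefixed: bool = field(default=False, compare=False)
    warnings: tuple[str, ...] = field(default=(), compare=False)


def replace_macros(rep: NanoRepresentation, defs=(), uses=()) -> NanoRepresentation:
    return _dc_replace(rep, macro_defs=tuple(defs), macro_uses=tuple(uses))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_VERSION_RE = re.compile(r"^(\d+[A-Za-z])(/|$)")
_SIZE_RE = re.compile(r"^(\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)([a-z]?)(-?\d+)?$")
_Y_RE = re.compile(r"^y(?P<ord>\d+(?:&\d+)*)?(?P<mix>(\{|\.\.\.).*)?$", re.S)
_I_RE = re.compile(r"^i(\d+)-(\d+)\[(.*)\]$", re.S)


def _is_cross(tok: str) -> bool:
    return bool(
        re.match(r"^y(\d|\{|\.\.\.|$)", tok)
        or re.match(r"^i\d+-\d+\[", tok)
        or tok.startswith("c{")
        or tok.startswith("d{")
    )


def _parse_bracketed(tok: str, off: int, prefix: str) -> str:
    """Content of ``p[...]`` for layer prefix ``p``."""
    if not tok.endswith("]"):
        raise NotationParseError(f"unterminated {prefix}[...] layer", off)
    return tok[2:-1]


def _parse_size(tok: str, off: int) -> SizeLayer:
    body = tok[1:]
    if body.startswith("["):
        end = body.rfind("]")
        if end < 0:
            raise NotationParseError("unterminated s[...] layer", off)
        inner, rest = body[1:end], body[end + 1:]
        m = re.match(r"^([a-z]?)(-?\d+)?$", rest)
        if not m:
            raise NotationParseError(f"malformed size suffix {rest!r}", off)
        qualifier = m.group(1) or None
        exponent = int(m.group(2)) if m.group(2) else None
        inner = inner.strip()
        quantity: float | DistExpr | str
        if re.fullmatch(r"\d+(?:\.\d+)?(?:[eE][-+]?\d+)?", inner):
            quantity = float(inner)
        elif _MACROISH_RE.search(inner):
            quantity = inner
        else:
            try:
                quantity = parse_dist_expr(inner)
            except DistributionError as exc:
                raise NotationParseError(f"malformed size distribution: {exc}", off) from None
        return SizeLayer(quantity, qualifier, exponent)
    m = _SIZE_RE.match(body)
    if not m:
        raise NotationParseError(f"malformed size layer {tok!r}", off)
    qualifier = m.group(2) or None
    exponent = int(m.group(3)) if m.group(3) else None
    return SizeLayer(float(m.group(1)), qualifier, exponent)


def _parse_morphology(tok: str, off: int, warnings_out: list[str]) -> MorphologyLayer:
    body = tok[1:]
    if body.startswith("["):
        inner = _parse_bracketed(tok, off, "m")
        if _MACROISH_RE.search(inner) and not inner.startswith(("Y(", "bbox")):
            return MorphologyLayer(expr=inner.strip())
        try:
            shape = parse_shape_expr(inner)
        except (ShapeError, DistributionError) as exc:
            raise NotationParseError(f"malformed shape expression: {exc}", off) from None
        return MorphologyLayer(expr=shape.canonical())
    category = _LEGACY_TO_CATEGORY.get(body, body)
    if category not in _KNOWN_CATEGORIES:
        warnings_out.append(f"unknown morphology category {body!r} kept verbatim")
    return MorphologyLayer(category=category)


def parse(text: str) -> NanoRepresentation:
    """Parse a line-notation string into a :class:`NanoRepresentation`."""
    raw = normalize_text(text).strip()
    prefixed = raw.startswith(PREFIX)
    s = raw[len(PREFIX):] if prefixed else raw
    base = len(PREFIX) if prefixed else 0

    vm = _VERSION_RE.match(s)
    if not vm:
        raise NotationParseError("expected version token (e.g. '1A') then '/'", base)
    version = vm.group(1)
    rest = s[len(version):]
    if not rest.startswith("/"):
        raise NotationParseError("expected '/' after version token", base + len(version))
    warnings_out: list[str] = []

    # split into !-separated segments, bracket aware
    segments = split_top(rest, "!")
    components: list[Component] = []
    structural_ordering: tuple[int, ...] | None = None
    structural_mixture: MixtureSpec | None = None
    interfaces: list[InterfaceSpec] = []
    comments: list[CommentInstance] = []
    macro_defs: list[MacroDefinition] = []
    macro_uses: list[MacroInvocation] = []
    rep_extras: list[tuple[str, str]] = []
    seen_y = False

    for seg_idx, (seg, seg_off) in enumerate(segments):
        abs_seg = base + len(version) + seg_off
        if not seg.startswith("/"):
            raise NotationParseError("component must start with '/'", abs_seg)
        layers = split_top(seg, "/")[1:]  # drop empty leading token
        if not layers or not layers[0][0]:
            raise NotationParseError("empty component", abs_seg)
        comp_kwargs: dict = {}
        extras: list[tuple[str, str]] = []
        composition: str | None = None
        in_cross = False
        seen_prefixes: set[str] = set()

        for tok, tok_off in layers:
            off = abs_seg + tok_off
            if not tok:
                raise NotationParseError("empty layer", off)
            if composition is None and not in_cross:
                composition = tok
                continue
            if _is_cross(tok):
                in_cross = True
            if in_cross:
                if seg_idx != len(segments) - 1:
                    raise NotationParseError(
                        "cross-component layers must follow the last component", off
                    )
                if tok[0] == "y":
                    if seen_y:
                        raise NotationParseError("duplicate y-layer", off)
                    seen_y = True
                    ym = _Y_RE.match(tok)
                    if not ym:
                        raise NotationParseError(f"malformed y-layer {tok!r}", off)
                    if ym.group("ord"):
                        structural_ordering = tuple(int(x) for x in ym.group("ord").split("&"))
                    if ym.group("mix"):
                        try:
                            structural_mixture = parse_mixture(ym.group("mix"))
                        except StructureError as exc:
                            raise NotationParseError(str(exc), off) from None
                elif tok[0] == "i":
                    im = _I_RE.match(tok)
                    if not im:
                        raise NotationParseError(f"malformed interface layer {tok!r}", off)
                    body = im.group(3)
                    frac = None
                    if ";" in body:
                        body, _, fs = body.partition(";")
                        try:
                            frac = float(fs)
                        except ValueError:
                            raise NotationParseError(f"malformed interface fraction {fs!r}", off) from None
                    rel, _, bond = body.partition(":")
                    relation = "bonded" if rel == "bond" else (rel or "bonded")
                    interfaces.append(
                        InterfaceSpec(int(im.group(1)), int(im.group(2)), relation, bond or None, frac)
                    )
                elif tok.startswith("c{"):
                    if not tok.endswith("}"):
                        raise NotationParseError("unterminated c{...} layer", off)
                    try:
                        comments.append(split_comment(tok[2:-1]))
                    except ValueError as exc:
                        raise NotationParseError(str(exc), off) from None
                elif tok.startswith("d{"):
                    if not tok.endswith("}"):
                        raise NotationParseError("unterminated d{...} layer", off)
                    inner = tok[2:-1]
                    try:
                        if re.search(r":\s*=", inner):
                            macro_defs.append(parse_definition(inner))
                        else:
                            macro_uses.append(parse_invocation(inner))
                    except MacroError as exc:
                        raise NotationParseError(str(exc), off) from None
                else:
                    rep_extras.append((tok[0], tok[1:]))
                    warnings_out.append(f"unknown layer prefix {tok[0]!r} kept verbatim")
                continue

            prefix = tok[0]
            if prefix in seen_prefixes and prefix in "mskw":
                raise NotationParseError(f"duplicate {prefix!r} layer in component", off)
            seen_prefixes.add(prefix)
            if prefix == "m":
                comp_kwargs["morphology"] = _parse_morphology(tok, off, warnings_out)
            elif prefix == "s":
                comp_kwargs["size"] = _parse_size(tok, off)
            elif prefix == "k":
                if tok[1:].startswith("["):
                    comp_kwargs["crystal"] = _parse_bracketed(tok, off, "k")
                else:
                    comp_kwargs["crystal"] = tok[1:]
            elif prefix == "w":
                comp_kwargs["chirality"] = tok[1:]
            else:
                extras.append((prefix, tok[1:]))
                warnings_out.append(f"unknown layer prefix {prefix!r} kept verbatim")

        if composition is None:
            raise NotationParseError("component without composition", abs_seg)
        components.append(Component(composition, extras=tuple(extras), **comp_kwargs))

    n = len(components)
    if structural_ordering is not None:
        for idx in structural_ordering:
            if not 1 <= idx <= n:
                raise NotationParseError(
                    f"y-layer references component {idx} of {n}", base
                )
    for spec in interfaces:
        for idx in (spec.source, spec.target):
            if not 1 <= idx <= n:
                raise NotationParseError(
                    f"interface references component {idx} of {n}", base
                )

    structural = None
    if structural_ordering is not None or structural_mixture is not None or interfaces:
        structural = StructuralLayer(
            structural_ordering or (), structural_mixture, tuple(interfaces)
        )
    return NanoRepresentation(
        version=version,
        components=tuple(components),
        structural=structural,
        comments=tuple(comments),
        macro_defs=tuple(macro_defs),
        macro_uses=tuple(macro_uses),
        extras=tuple(rep_extras),
        prefixed=prefixed,
        warnings=tuple(warnings_out),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _emit_size(layer: SizeLayer) -> str:
    if isinstance(layer.quantity, float):
        body = fmt_number(layer.quantity)
    elif isinstance(layer.quantity, DistExpr):
        body = f"[{layer.quantity.canonical()}]"
    else:
        body = f"[{layer.quantity}]"
    if layer.qualifier:
        body += layer.qualifier
    if layer.exponent is not None:
        body += str(layer.exponent)
    return "s" + body


def _emit_morphology(layer: MorphologyLayer, harmonic: bool) -> str:
    if layer.category is not None:
        if harmonic:
            return f"m[{from_category(layer.category).canonical()}]"
        return "m" + _CATEGORY_TO_LEGACY.get(layer.category, layer.category)
    return f"m[{layer.expr}]"


def serialize(rep: NanoRepresentation, harmonic: bool = False, prefix: bool | None = None) -> str:
    """Serialize a representation back to line notation.

    Layer order is fixed (composition, m, s, k, w within a component; y, i,
    c, d across components).  Legacy category tokens are preserved by
    default; ``harmonic=True`` rewrites them as harmonic expressions.
    The output re-parses to a structurally equal representation.
    """
    issues = [i for i in validate(rep) if i.severity == "error"]
    if issues:
        raise ValueError(
            "cannot serialize invalid representation: "
            + "; ".join(f"{i.location}: {i.message}" for i in issues)
        )
    parts: list[str] = []
    for comp in rep.components:
        layers = [comp.composition]
        if comp.morphology is not None:
            layers.append(_emit_morphology(comp.morphology, harmonic))
        if comp.size is not None:
            layers.append(_emit_size(comp.size))
        if comp.crystal is not None:
            layers.append(f"k[{comp.crystal}]")
        if comp.chirality is not None:
            layers.append(f"w{comp.chirality}")
        layers.extend(p + t for p, t in comp.extras)
        parts.append("/" + "/".join(layers))
    out = rep.version + "!".join(parts)
    if rep.structural is not None:
        y = "y" + "&".join(str(i) for i in rep.structural.ordering)
        if rep.structural.mixture is not None:
            y += rep.structural.mixture.canonical()
        if rep.structural.ordering or rep.structural.mixture is not None:
            out += "/" + y
        for spec in rep.structural.interfaces:
            out += "/" + spec.canonical()
    for c in rep.comments:
        out += "/c{" + c.canonical() + "}"
    for d in rep.macro_defs:
        out += "/d{" + d.canonical() + "}"
    for u in rep.macro_uses:
        out += "/d{" + u.canonical() + "}"
    out += "".join("/" + p + t for p, t in rep.extras)
    if prefix or (prefix is None and rep.prefixed):
        out = PREFIX + out
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate(rep: NanoRepresentation) -> list[Issue]:
    """Check all invariants; returns issues instead of raising.

    The empty list means every type invariant and cross-layer reference
    holds (warnings — preserved unknown layers, advisory notes — do not
    appear here as errors).
    """
    issues: list[Issue] = []
    err = lambda loc, msg: issues.append(Issue("error", loc, msg))
    warn = lambda loc, msg: issues.append(Issue("warning", loc, msg))

    if not rep.components:
        err("components", "at least one component required")
    n = len(rep.components)
    for i, comp in enumerate(rep.components, start=1):
        loc = f"component {i}"
        if not comp.composition:
            err(loc, "composition must be non-empty")
        if comp.size is not None:
            q = comp.size.quantity
            if isinstance(q, float) and not q > 0:
                err(loc, f"scalar size must be strictly positive, got {q}")
            e = comp.size.exponent
            if e is not None and not -12 <= e <= 0:
                err(loc, f"size exponent {e} outside [-12, 0]")
            if comp.size.qualifier is not None and comp.size.qualifier not in ("d", "t", "l"):
                warn(loc, f"unrecognized size qualifier {comp.size.qualifier!r}")
        if comp.morphology is not None and comp.morphology.category is not None:
            if comp.morphology.category not in _KNOWN_CATEGORIES:
                warn(loc, f"unknown morphology category {comp.morphology.category!r}")
        for p, _ in comp.extras:
            warn(loc, f"opaque layer prefix {p!r} preserved")

    if rep.structural is not None:
        lay = rep.structural
        seen: set[int] = set()
        for idx in lay.ordering:
            if not 1 <= idx <= n:
                err("y-layer", f"component index {idx} out of range 1..{n}")
            if idx in seen:
                err("y-layer", f"duplicate component index {idx} in ordering")
            seen.add(idx)
        if lay.mixture is not None:
            numeric = [f for f in lay.mixture.fractions if isinstance(f, float)]
            if any(not 0 <= f <= 1 for f in numeric):
                err("mixture", "fractions must lie in [0, 1]")
            s = sum(numeric)
            if s > 1 + 1e-9:
                err("mixture", f"fractions sum to {s} > 1")
            for item in lay.mixture.items:
                if isinstance(item, int) and not 1 <= item <= n:
                    err("mixture", f"component index {item} out of range 1..{n}")
        for spec in lay.interfaces:
            for idx in (spec.source, spec.target):
                if not 1 <= idx <= n:
                    err("interface", f"component index {idx} out of range 1..{n}")
            if spec.fraction is not None and not 0 < spec.fraction <= 1:
                err("interface", f"fraction {spec.fraction} outside (0, 1]")
    for p, _ in rep.extras:
        warn("cross layers", f"opaque layer prefix {p!r} preserved")
    return issues


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

_COMPOSITIONS = ("Au", "O2Si", "Ti2O", "Ag", "C", "Fe2O3", "C8H8", "ZnO", "CuO")
_CRYSTALS = ("P4_2/mnm", "Fm-3m", "I4_1/amd", "P6_3mc")
_CHIRALITIES = ("(6,5)", "(9,1)", "(10,10)")


def _random_dist_expr(rng: np.random.Generator) -> DistExpr:
    kind = rng.integers(0, 4)
    loc = float(rng.integers(5, 200))
    if kind == 0:
        return parse_dist_expr(f"pdf({fmt_number(loc)},sd={fmt_number(round(loc * 0.1, 2))})")
    if kind == 1:
        return parse_dist_expr(f"cdf({fmt_number(loc)})")
    if kind == 2:
        hi = loc + float(rng.integers(5, 50))
        return parse_dist_expr(f"rcdf({fmt_number(loc)})*cdf({fmt_number(hi)})")
    mode = round(loc * 0.8, 2)
    return parse_dist_expr(f"pdf({fmt_number(loc)},m={fmt_number(mode)})")


def _random_component(rng: np.random.Generator) -> Component:
    kwargs: dict = {}
    u = rng.random()
    if u < 0.3:
        kwargs["morphology"] = MorphologyLayer(
            category=str(rng.choice(["sphere", "shell", "wire", "rod"]))
        )
    elif u < 0.55:
        exprs = ["Y(0,0)", "Y(0,0)*scale(4,1,1)", "Y(0,0)+Y(2,0)*0.2",
                 "Y(0,0)*scale(100,1,1)", "Y(0,0)+Y(1,0)*0.1+Y(2,2)*0.05"]
        kwargs["morphology"] = MorphologyLayer(expr=str(rng.choice(exprs)))
    elif u < 0.62:
        kwargs["morphology"] = MorphologyLayer(expr="bbox(pdf(20,sd=2);pdf(30,sd=3))")
    u = rng.random()
    if u < 0.4:
        kwargs["size"] = SizeLayer(
            float(rng.integers(1, 500)),
            str(rng.choice(["d", "t"])) if rng.random() < 0.7 else None,
            int(rng.choice([-9, -6])) if rng.random() < 0.8 else None,
        )
    elif u < 0.75:
        kwargs["size"] = SizeLayer(
            _random_dist_expr(rng),
            "d" if rng.random() < 0.5 else None,
            -9,
        )
    if rng.random() < 0.25:
        kwargs["crystal"] = str(rng.choice(_CRYSTALS))
    if rng.random() < 0.15:
        kwargs["chirality"] = str(rng.choice(_CHIRALITIES))
    extras = ()
    if rng.random() < 0.1:
        extras = (("q", f"opaque{int(rng.integers(0, 100))}"),)
    return Component(str(rng.choice(_COMPOSITIONS)), extras=extras, **kwargs)


def _random_comment(rng: np.random.Generator) -> CommentInstance:
    u = rng.random()
    if u < 0.4:
        val = -float(rng.integers(1, 80))
        return CommentInstance("Zpotential", (fmt_number(val), "mV", "urlx"))
    if u < 0.7:
        return CommentInstance("Taxonomy", (str(rng.choice(["crustacean", "fish", "algae"])),))
    day = f"2019-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
    return CommentInstance("Publication", (day, '"Author A., Coauthor B."', '"J.Nan"'))


def fixture_generate(seed: int, n: int) -> list[NanoRepresentation]:
    """Deterministic random representations covering every layer kind.

    All outputs validate with no error-severity issues and round-trip
    through :func:`serialize` / :func:`parse`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[NanoRepresentation] = []
    for _ in range(n):
        ncomp = int(rng.integers(1, 4))
        comps = tuple(_random_component(rng) for _ in range(ncomp))
        structural = None
        if ncomp > 1 or rng.random() < 0.5:
            ordering = tuple(int(x) for x in rng.permutation(ncomp) + 1)
            mixture = None
            if rng.random() < 0.3:
                fr = rng.dirichlet(np.ones(ncomp)) * 0.9
                fractions = tuple(round(float(f), 4) for f in fr)
                mixture = MixtureSpec(tuple(range(1, ncomp + 1)), fractions)
            interfaces: tuple[InterfaceSpec, ...] = ()
            if ncomp >= 2 and rng.random() < 0.25:
                interfaces = (
                    InterfaceSpec(
                        1, 2, str(rng.choice(["bonded", "mixed_with"])),
                        str(rng.choice(["a", "b"])),
                        round(float(rng.uniform(0.1, 1.0)), 3),
                    ),
                )
            structural = StructuralLayer(ordering, mixture, interfaces)
        comments = tuple(_random_comment(rng) for _ in range(int(rng.random() < 0.35)))
        macro_defs: tuple[MacroDefinition, ...] = ()
        if rng.random() < 0.15:
            macro_defs = (
                MacroDefinition(f"Alias{int(rng.integers(0, 50))}", (), "2O.Ti/k[I4_1/amd]"),
            )
        out.append(
            NanoRepresentation(
                components=comps,
                structural=structural,
                comments=comments,
                macro_defs=macro_defs,
            )
        )
    return out
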