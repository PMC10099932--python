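"""Macros and aliases: reusable, parametrizable notation templates.

A macro definition names a notation fragment, optionally with %-parameters:

    Anatase := 2O.Ti/k[Ir_1/amd]
    Sphere(%x) := Y(0,0)*%x
    Mystructure(%a,%b,%c) := core(%a) coating(%b) sphere(%c)

Expansion is purely textual — arguments replace their %-tokens, innermost
invocations first — after which the result must re-parse under the line
grammar.  %-tokens are reserved to macro bodies, so hygienic capture cannot
arise.  Registries are plain-text files, one definition per line; a cycle
among definitions, an undeclared %-token, or exceeding the depth limit is an
error.  A toolchain that does not process macros may silently discard the
layer (``strip_or_keep`` with policy ``discard``), losing nothing relative
to the expanded form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._text import normalize_text, split_top

__all__ = [
    "MacroDefinition",
    "MacroInvocation",
    "MacroRegistry",
    "MacroError",
    "MacroCycleError",
    "parse_definition",
    "parse_invocation",
    "expand",
    "strip_or_keep",
    "standard_registry",
    "fixture_registries",
]

DEFAULT_MAX_DEPTH = 16

_NAME = r"[A-Za-z_][A-Za-z0-9_]*"
_DEF_RE = re.compile(rf"^\s*({_NAME})\s*(?:\(([^()]*)\))?\s*:\s*=\s*(.*?)\s*$", re.S)
_PARAM_RE = re.compile(r"%[A-Za-z][A-Za-z0-9_]*")


class MacroError(ValueError):
    pass


class MacroCycleError(MacroError):
    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("macro definition cycle: " + " -> ".join(cycle + cycle[:1]))


@dataclass(frozen=True)
class MacroDefinition:
    name: str
    params: tuple[str, ...]  # %-tokens, e.g. ("%x",)
    body: str

    def __post_init__(self) -> None:
        if len(set(self.params)) != len(self.params):
            raise MacroError(f"duplicate parameter in {self.name}: {self.params}")
        declared = set(self.params)
        for tok in _PARAM_RE.findall(self.body):
            if tok not in declared:
                raise MacroError(
                    f"body of {self.name} references undeclared token {tok}"
                )

    def canonical(self) -> str:
        head = self.name
        if self.params:
            head += f"({','.join(self.params)})"
        return f"{head} := {self.body}"


@dataclass(frozen=True)
class MacroInvocation:
    name: str
    args: tuple[str, ...] = ()

    def canonical(self) -> str:
        if self.args:
            return f"{self.name}({','.join(self.args)})"
        return self.name


def parse_definition(text: str) -> MacroDefinition:
    """Parse ``"Name(params) := body"`` (zero-parameter aliases allowed)."""
    m = _DEF_RE.match(normalize_text(text))
    if not m:
        raise MacroError(f"malformed macro definition {text!r}")
    name, params_raw, body = m.group(1), m.group(2), m.group(3)
    params: tuple[str, ...] = ()
    if params_raw is not None and params_raw.strip():
        toks = [p.strip() for p in params_raw.split(",")]
        for t in toks:
            if not _PARAM_RE.fullmatch(t):
                raise MacroError(f"parameter {t!r} must be a %-token")
        params = tuple(toks)
    if not body:
        raise MacroError(f"macro {name} has an empty body")
    return MacroDefinition(name, params, body)


def parse_invocation(text: str) -> MacroInvocation:
    m = re.match(rf"^\s*({_NAME})\s*(?:\((.*)\))?\s*$", normalize_text(text), re.S)
    if not m:
        raise MacroError(f"malformed macro invocation {text!r}")
    args: tuple[str, ...] = ()
    if m.group(2) is not None and m.group(2).strip():
        args = tuple(a.strip() for a, _ in split_top(m.group(2), ","))
    return MacroInvocation(m.group(1), args)


class MacroRegistry:
    """Name -> definition mapping with redefinition and cycle checks."""

    def __init__(self) -> None:
        self._defs: dict[str, MacroDefinition] = {}

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __len__(self) -> int:
        return len(self._defs)

    def get(self, name: str) -> MacroDefinition:
        if name not in self._defs:
            raise MacroError(f"unknown macro {name!r}")
        return self._defs[name]

    def names(self) -> list[str]:
        return sorted(self._defs)

    def define(self, definition: MacroDefinition | str) -> MacroDefinition:
        if isinstance(definition, str):
            definition = parse_definition(definition)
        if definition.name in self._defs:
            raise MacroError(f"macro {definition.name!r} already defined")
        self._defs[definition.name] = definition
        return definition

    # -- cycle analysis ------------------------------------------------------

    def references(self, name: str) -> set[str]:
        """Registered macro names invoked by ``name``'s body."""
        body = self._defs[name].body
        out = set()
        for m in re.finditer(rf"\b({_NAME})\b", body):
            if m.group(1) in self._defs and m.group(1) != "":
                out.add(m.group(1))
        return out

    def find_cycle(self) -> list[str] | None:
        """Depth-first search for a directed cycle among definitions."""
        WHITE, GREY, BLACK = 0, 1, 2
        color = {n: WHITE for n in self._defs}
        stack: list[str] = []

        def visit(n: str) -> list[str] | None:
            color[n] = GREY
            stack.append(n)
            for ref in sorted(self.references(n)):
                if color[ref] == GREY:
                    return stack[stack.index(ref):]
                if color[ref] == WHITE:
                    found = visit(ref)
                    if found:
                        return found
            stack.pop()
            color[n] = BLACK
            return None

        for n in sorted(self._defs):
            if color[n] == WHITE:
                found = visit(n)
                if found:
                    return found
        return None

    # -- files ---------------------------------------------------------------

    @classmethod
    def from_file(cls, path) -> "MacroRegistry":
        reg = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    reg.define(line)
        return reg

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name in self.names():
                fh.write(self._defs[name].canonical() + "\n")


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


def _find_invocations(text: str, registry: MacroRegistry):
    """Occurrences of registered names, with optional argument lists."""
    for m in re.finditer(rf"\b({_NAME})\b", text):
        name = m.group(1)
        if name not in registry:
            continue
        end = m.end()
        rest = text[end:]
        ws = len(rest) - len(rest.lstrip())
        args: tuple[str, ...] | None = None
        arg_end = end
        if rest[ws: ws + 1] == "(":
            depth = 0
            for j in range(end + ws, len(text)):
                if text[j] == "(":
                    depth += 1
                elif text[j] == ")":
                    depth -= 1
                    if depth == 0:
                        inner = text[end + ws + 1: j]
                        args = tuple(
                            a.strip() for a, _ in split_top(inner, ",")
                        ) if inner.strip() else ()
                        arg_end = j + 1
                        break
            else:
                raise MacroError(f"unbalanced parentheses after {name!r}")
        yield m.start(), arg_end, name, args


def _substitute(definition: MacroDefinition, args: tuple[str, ...] | None) -> str:
    args = args or ()
    if len(args) != len(definition.params):
        raise MacroError(
            f"{definition.name} expects {len(definition.params)} argument(s), "
            f"got {len(args)}"
        )
    body = definition.body
    for param, arg in sorted(zip(definition.params, args), key=lambda t: -len(t[0])):
        body = body.replace(param, arg)
    return body


def expand(
    text: str,
    registry: MacroRegistry,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> str:
    """Fully expand all registered macro invocations in ``text``.

    Substitution proceeds innermost-first until a fixed point; expansion is
    therefore idempotent.  A definition cycle reachable from ``text`` raises
    :class:`MacroCycleError` before any rewriting; exceeding ``max_depth``
    rewriting passes raises :class:`MacroError`.
    """
    text = normalize_text(text)
    cycle = registry.find_cycle()
    if cycle is not None:
        reachable = {name for _, _, name, _ in _find_invocations(text, registry)}
        frontier = set(reachable)
        while frontier:
            nxt = set()
            for n in frontier:
                nxt |= registry.references(n) - reachable
            reachable |= nxt
            frontier = nxt
        if reachable & set(cycle):
            raise MacroCycleError(cycle)
    for _ in range(max_depth):
        hits = list(_find_invocations(text, registry))
        if not hits:
            return text
        # Rewrite non-overlapping hits per pass (a nested invocation travels
        # textually inside its argument and is rewritten on a later pass);
        # replace right-to-left so earlier offsets stay valid.
        kept: list[tuple[int, int, str, tuple[str, ...] | None]] = []
        last_end = -1
        for hit in hits:
            if hit[0] >= last_end:
                kept.append(hit)
                last_end = hit[1]
        out = text
        for start, end, name, args in reversed(kept):
            out = out[:start] + _substitute(registry.get(name), args) + out[end:]
        text = out
    raise MacroError(f"macro expansion exceeded max depth {max_depth}")


def strip_or_keep(rep, policy: str, registry: MacroRegistry | None = None):
    """Apply a macro policy to a parsed representation.

    ``keep`` preserves macro layers verbatim; ``expand`` rewrites the
    notation with every invocation expanded (definitions retained);
    ``discard`` additionally drops the macro layers — lossless with respect
    to the expanded form.
    """
    from . import grammar_core  # local import: grammar depends on this module

    if policy == "keep":
        return rep
    if policy not in ("expand", "discard"):
        raise MacroError(f"unknown macro policy {policy!r}")
    reg = MacroRegistry()
    if registry is not None:
        for name in registry.names():
            reg.define(registry.get(name))
    for d in rep.macro_defs:
        if d.name not in reg:
            reg.define(d)
    # expand the notation text with the definition layers stripped (they are
    # templates, not expansion sites); standalone invocation layers are
    # spliced in place as the notation fragment they expand to.
    bare = grammar_core.replace_macros(rep, defs=(), uses=rep.macro_uses)
    text = grammar_core.serialize(bare)
    for use in rep.macro_uses:
        if use.name not in reg:
            raise MacroError(f"unknown macro {use.name!r}")
        frag = expand(use.canonical(), reg)
        spliced = frag if frag.startswith(("/", "!")) else "/" + frag
        text = text.replace("/d{" + use.canonical() + "}", spliced)
    text = expand(text, reg)
    new = grammar_core.parse(text)
    if policy == "expand":
        new = grammar_core.replace_macros(new, defs=rep.macro_defs, uses=())
    return new


# ---------------------------------------------------------------------------
# shipped registry and fixtures
# ---------------------------------------------------------------------------


def standard_registry() -> MacroRegistry:
    """The shipped starter registry.

    ``core``/``coating``/``sphere`` are the scaffold templates used by
    core-coating structures: ``core(X)`` opens a representation with
    component X, ``coating(Y)`` appends component Y, ``sphere(d)`` attaches
    a spherical morphology with diameter ``d`` (meters).  They expand to
    component + overall-structure fragments of the line notation.
    """
    reg = MacroRegistry()
    reg.define("core(%a) := 1A/%a")
    reg.define("coating(%b) := !/%b")
    reg.define("sphere(%x) := /m[Y(0,0)]/s[%x]")
    reg.define("Anatase := 2O.Ti/k[Ir_1/amd]")
    reg.define("Sphere(%x) := Y(0,0)*%x")
    return reg


def fixture_registries(seed: int, n: int, cyclic: bool = False) -> list[MacroRegistry]:
    """Deterministic random registries for property tests.

    Acyclic by construction unless ``cyclic`` is set, in which case every
    registry contains at least one directed definition cycle.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        reg = MacroRegistry()
        k = int(rng.integers(2, 7))
        names = [f"M{i}" for i in range(k)]
        arity = [int(rng.integers(0, 3)) for _ in range(k)]
        for i, name in enumerate(names):
            params = tuple(f"%{chr(ord('a') + j)}" for j in range(arity[i]))
            bits = [f"frag{int(rng.integers(0, 100))}"] + list(params)
            # reference only later names: guarantees a DAG
            for j in range(i + 1, k):
                if rng.random() < 0.4:
                    call = names[j]
                    if arity[j]:
                        call += "(" + ",".join(f"v{t}" for t in range(arity[j])) + ")"
                    bits.append(call)
            order = rng.permutation(len(bits))
            body = "/".join(bits[t] for t in order)
            reg.define(MacroDefinition(name, params, body))
        if cyclic:
            # close a loop: chain every name to its successor, then wrap
            # the last back around to the first
            for i, name in enumerate(names):
                succ = names[(i + 1) % k]
                call = succ
                if arity[(i + 1) % k]:
                    call += "(" + ",".join("w" for _ in range(arity[(i + 1) % k])) + ")"
                d = reg.get(name)
                reg._defs[name] = MacroDefinition(d.name, d.params, d.body + "/" + call)
        out.append(reg)
    return out
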