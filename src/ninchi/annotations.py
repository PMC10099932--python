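"""Structured comments: typed auxiliary information on representations.

Auxiliary data — zeta potential, test organism, publication metadata — is
routinely lost in free-form comments.  Here a comment is an instance of a
*header*: a registered, shareable schema naming the record and typing each
slot.  ``Zpotential[-35;mV;urlx]`` is an instance of the header
``Zpotential`` with signature ``Float;Units;URI``.

Type tokens: ``Date`` (ISO 8601, also dd/mm/yyyy on input), ``Float`` (real
numbers or distribution expressions), ``Text`` (UTF-8, quoted when it
contains separators), ``Units`` (SI unit with prefix; unknown units warn
rather than fail), ``URI`` and ``Enumeration(v1|v2|...)``.  Values may be a
proper prefix of the signature — incomplete knowledge is representable —
but never exceed it.

Headers live in registries: plain-text files, one ``Title:Description:
Type1;Type2;...`` line per header, shareable independently of any
representation.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

from ._text import fmt_number, normalize_text, split_top
from .distributions import DistExpr, DistributionError, parse_dist_expr

__all__ = [
    "CommentHeader",
    "CommentInstance",
    "TypedComment",
    "HeaderRegistry",
    "AnnotationError",
    "define_header",
    "parse_comment",
    "serialize_comment",
    "query_comments",
    "standard_registry",
]


class AnnotationError(ValueError):
    pass


_SIMPLE_TYPES = ("Date", "Float", "Text", "Units", "URI")
_ENUM_RE = re.compile(r"^Enumeration\((.*)\)$", re.I)

#: Base SI and common derived unit symbols accepted (with optional prefix).
_UNIT_BASES = ("m", "g", "s", "A", "K", "mol", "cd", "L", "V", "Pa", "J", "W", "Hz", "C")
_PREFIXES = ("y", "z", "a", "f", "p", "n", "u", "m", "c", "d", "da", "h", "k", "M", "G", "T", "P", "E", "Z", "Y", "")
_UNIT_OK = {p + b for b in _UNIT_BASES for p in _PREFIXES} | {"%", "mg/L", "g/L"}


def _norm_type(tok: str) -> str:
    t = tok.strip()
    m = _ENUM_RE.match(t)
    if m:
        values = tuple(v.strip() for v in m.group(1).split("|") if v.strip())
        if not values:
            raise AnnotationError("Enumeration needs at least one value")
        return f"Enumeration({'|'.join(values)})"
    for s in _SIMPLE_TYPES:
        if t.lower() == s.lower():
            return s
    if t.lower() == "enumeration":
        # a bare Enumeration admits any token; membership is then advisory
        return "Enumeration()"
    raise AnnotationError(f"unknown type token {tok!r}")


@dataclass(frozen=True)
class CommentHeader:
    """A named, typed schema for one kind of auxiliary record."""

    title: str
    description: str
    type_signature: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.title or not re.fullmatch(r"[A-Za-z_]\w*", self.title):
            raise AnnotationError(f"invalid header title {self.title!r}")
        if not self.type_signature:
            raise AnnotationError("type signature must be non-empty")
        object.__setattr__(
            self, "type_signature", tuple(_norm_type(t) for t in self.type_signature)
        )

    def registry_line(self) -> str:
        return f"{self.title}:{self.description}:{';'.join(self.type_signature)}"


@dataclass(frozen=True)
class CommentInstance:
    """A raw comment as it appears in the notation: title + value tokens."""

    header_title: str
    values: tuple[str, ...]

    def canonical(self) -> str:
        return f"{self.header_title}[{';'.join(self.values)}]"


@dataclass(frozen=True)
class TypedComment:
    """A validated comment: header plus coerced Python values."""

    header: CommentHeader
    values: tuple

    def canonical(self) -> str:
        return serialize_comment(self)


class HeaderRegistry:
    """Title -> header mapping; titles are unique within a registry."""

    def __init__(self) -> None:
        self._headers: dict[str, CommentHeader] = {}

    def __contains__(self, title: str) -> bool:
        return title in self._headers

    def get(self, title: str) -> CommentHeader:
        if title not in self._headers:
            raise AnnotationError(f"unknown comment header {title!r}")
        return self._headers[title]

    def titles(self) -> list[str]:
        return sorted(self._headers)

    def define(self, title: str, description: str, signature) -> CommentHeader:
        if title in self._headers:
            raise AnnotationError(f"header {title!r} already registered")
        header = CommentHeader(title, description, tuple(signature))
        self._headers[title] = header
        return header

    @classmethod
    def from_file(cls, path) -> "HeaderRegistry":
        reg = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                title, _, rest = line.partition(":")
                desc, _, types = rest.rpartition(":")
                reg.define(title.strip(), desc.strip(), [t for t in types.split(";") if t.strip()])
        return reg

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for title in self.titles():
                fh.write(self._headers[title].registry_line() + "\n")


def define_header(registry: HeaderRegistry, title: str, description: str, signature) -> CommentHeader:
    """Register a new comment header (module-level convenience)."""
    return registry.define(title, description, signature)


def standard_registry() -> HeaderRegistry:
    """The shipped starter headers for common auxiliary records."""
    reg = HeaderRegistry()
    reg.define(
        "Zpotential",
        "Zeta potential value; units; URL to medium description",
        ["Float", "Units", "URI"],
    )
    reg.define(
        "Publication",
        "Publication date; Authors; Journal name",
        ["Date", "Text", "Text"],
    )
    reg.define(
        "Taxonomy",
        "Subphylum name; Link to taxonomy database",
        ["Enumeration(crustacean|fish|algae|rodent|human|bacteria)", "URI"],
    )
    return reg


# ---------------------------------------------------------------------------
# parsing / coercion
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*\[(.*)\]\s*$", re.S)
_DATE_DMY = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")
_FLOAT_RE = re.compile(r"^[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?$")


def split_comment(text: str) -> CommentInstance:
    """Split a comment into title and raw value tokens (quote-aware)."""
    m = _COMMENT_RE.match(normalize_text(text))
    if not m:
        raise AnnotationError(f"malformed comment {text!r}")
    body = m.group(2)
    values: tuple[str, ...] = ()
    if body.strip():
        values = tuple(v.strip() for v, _ in split_top(body, ";"))
    return CommentInstance(m.group(1), values)


def _unquote(tok: str) -> str:
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        return tok[1:-1]
    return tok


def _coerce(tok: str, type_tok: str, position: int):
    raw = tok
    tok = _unquote(tok.strip())
    try:
        if type_tok == "Date":
            m = _DATE_DMY.match(tok)
            if m:
                d, mo, y = (int(g) for g in m.groups())
                return _dt.date(y, mo, d)
            return _dt.date.fromisoformat(tok)
        if type_tok == "Float":
            if _FLOAT_RE.match(tok):
                return float(tok)
            return parse_dist_expr(tok)  # "real numbers or distributions"
        if type_tok == "Text":
            return tok
        if type_tok == "Units":
            return tok  # validity advisory, see validate_units
        if type_tok == "URI":
            if not tok:
                raise AnnotationError("empty URI")
            return tok
        m = _ENUM_RE.match(type_tok)
        if m:
            allowed = tuple(v for v in m.group(1).split("|") if v)
            if allowed and tok not in allowed:
                raise AnnotationError(
                    f"{tok!r} not in enumeration {{{m.group(1)}}}"
                )
            return tok
    except (ValueError, DistributionError) as exc:
        raise AnnotationError(
            f"value {position}: {raw!r} is not a valid {type_tok}: {exc}"
        ) from None
    raise AnnotationError(f"unknown type token {type_tok!r}")


def unit_warnings(comment: TypedComment) -> list[str]:
    """Advisory check of Units slots against the SI table."""
    out = []
    for type_tok, val in zip(comment.header.type_signature, comment.values):
        if type_tok == "Units" and isinstance(val, str) and val not in _UNIT_OK:
            out.append(f"unit {val!r} not in the SI table (passed through)")
    return out


def parse_comment(text: str | CommentInstance, registry: HeaderRegistry) -> TypedComment:
    """Validate and coerce a comment against its registered header.

    Validation is total: a malformed instance raises a typed error naming
    the offending position; a partial object is never returned.
    """
    inst = split_comment(text) if isinstance(text, str) else text
    header = registry.get(inst.header_title)
    if len(inst.values) > len(header.type_signature):
        raise AnnotationError(
            f"{header.title}: {len(inst.values)} values exceed signature "
            f"arity {len(header.type_signature)}"
        )
    coerced = tuple(
        _coerce(tok, type_tok, i + 1)
        for i, (tok, type_tok) in enumerate(zip(inst.values, header.type_signature))
    )
    return TypedComment(header, coerced)


def _serialize_value(val, type_tok: str) -> str:
    if type_tok == "Date":
        return val.isoformat()
    if type_tok == "Float":
        if isinstance(val, DistExpr):
            return val.canonical()
        return fmt_number(val)
    s = str(val)
    if any(ch in s for ch in ";[]{}") or ("," in s or " " in s) and type_tok == "Text":
        return f'"{s}"'
    return s


def serialize_comment(comment: TypedComment) -> str:
    """Emit the canonical notation form; dates come out as ISO 8601."""
    vals = [
        _serialize_value(v, t)
        for v, t in zip(comment.values, comment.header.type_signature)
    ]
    return f"{comment.header.title}[{';'.join(vals)}]"


def query_comments(collection, header_title: str, predicate) -> list[TypedComment]:
    """All typed comments with the given header whose values satisfy
    ``predicate(values_tuple)``; deterministic (input) order.

    ``collection`` is an iterable of :class:`TypedComment`.
    """
    out = []
    for c in collection:
        if c.header.title == header_title and predicate(c.values):
            out.append(c)
    return out
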