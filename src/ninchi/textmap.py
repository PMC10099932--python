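"""Deterministic normalizer from database free-text to the formal notation.

Nanomaterial databases record sizes, shapes and mixtures as loosely worded
phrases — "Less than 100 nm", "Mixture of spherical, prismatic and
rod-shaped", "0.45% NaCl w/ 0.1% glucose".  This module is the executable
rule set mapping that phrase inventory onto the formal operators:
distribution expressions for sizes, harmonic expressions for shapes and
``{items}:{fractions}`` operators for mixtures.

Matching is rule-based (anchored regular expressions) and nothing else: the
mapping must be auditable and reproduce the documented phrase table
byte-exactly (after ASCII normalization), so no statistical text processing
is involved.  Keywords match case-insensitively; chemical names keep their
case.  A phrase outside the inventory raises :class:`NoMatchError` listing
the nearest known patterns rather than guessing.
"""

from __future__ import annotations

import difflib
import re

from ._text import fmt_number, normalize_text

__all__ = [
    "NoMatchError",
    "normalize_size_text",
    "normalize_shape_text",
    "normalize_mixture_text",
    "normalize_any",
]


class NoMatchError(ValueError):
    def __init__(self, text: str, kind: str, examples: list[str]):
        near = difflib.get_close_matches(text.lower(), [e.lower() for e in examples], n=3, cutoff=0.1)
        hint = f"; nearest known patterns: {near}" if near else ""
        super().__init__(f"no {kind} rule matches {text!r}{hint}")


def _num(s: str) -> str:
    return fmt_number(float(s))


def _pct(s: str) -> str:
    # decimal division keeps "0.45" / 100 at exactly "0.0045"
    from decimal import Decimal

    d = Decimal(s) / Decimal(100)
    return format(d.normalize(), "f")


# ---------------------------------------------------------------------------
# sizes  (phrase -> distribution expression)
# ---------------------------------------------------------------------------

_UNIT = r"(nm|um|mm|m)"

_SIZE_RULES: list[tuple[re.Pattern, object]] = [
    (
        re.compile(rf"^less than ([\d.]+)\s*{_UNIT}$", re.I),
        lambda m: f"cdf({_num(m.group(1))}) {m.group(2)}",
    ),
    (
        re.compile(rf"^(?:more|greater|larger) than ([\d.]+)\s*{_UNIT}$", re.I),
        lambda m: f"rcdf({_num(m.group(1))}) {m.group(2)}",
    ),
    (
        re.compile(rf"^([\d.]+)% is below ([\d.]+)\s*{_UNIT}$", re.I),
        lambda m: f"cdf({_num(m.group(2))},{_pct(m.group(1))}) {m.group(3)}",
    ),
    (
        re.compile(rf"^size between ([\d.]+)\s*-\s*([\d.]+)\s*{_UNIT}$", re.I),
        lambda m: f"rcdf({_num(m.group(1))})*cdf({_num(m.group(2))}) {m.group(3)}",
    ),
    (
        re.compile(
            rf"^mean ([\d.]+)\s*{_UNIT}, (?:stdev|std|sd|standard deviation) ([\d.]+)\s*{_UNIT}$",
            re.I,
        ),
        lambda m: f"pdf({_num(m.group(1))},sd={_num(m.group(3))}) {m.group(2)}",
    ),
    (
        re.compile(rf"^mean ([\d.]+)\s*{_UNIT}, mode ([\d.]+)\s*{_UNIT}$", re.I),
        lambda m: f"pdf({_num(m.group(1))},m={_num(m.group(3))}) {m.group(2)}",
    ),
    (
        re.compile(rf"^([\d.]+)\s*{_UNIT} \(size distribution ([\d.]+)%\)$", re.I),
        lambda m: f"pdf({_num(m.group(1))},ci=(u,{_pct(m.group(3))})) {m.group(2)}",
    ),
    (
        re.compile(r"^at least ([\d.]+)% purity$", re.I),
        lambda m: f"cdf(1,{_pct(m.group(1))})",
    ),
]

_SIZE_EXAMPLES = [
    "Less than 100 nm",
    "90% is below 20 nm",
    "Size between 60-100 nm",
    "Mean 27 nm, stdev 8 nm",
    "Mean 115 nm, mode 95 nm",
    "15 nm (size distribution 99%)",
    "At least 99.5% purity",
    "50% < 5 nm, 30% 5-10",
]

_CLAUSE_LT = re.compile(rf"^([\d.]+)%\s*<\s*([\d.]+)\s*{_UNIT}$", re.I)
_CLAUSE_RANGE = re.compile(rf"^([\d.]+)%\s*([\d.]+)\s*-\s*([\d.]+)(?:\s*{_UNIT})?$", re.I)


def _try_quantile_clauses(text: str) -> str | None:
    """Handle "50% < 5 nm, 30% 5-10": per-clause expressions, comma-joined."""
    clauses = [c.strip() for c in text.split(",")]
    if len(clauses) < 2:
        return None
    parts = []
    unit = "nm"
    for c in clauses:
        m = _CLAUSE_LT.match(c)
        if m:
            unit = m.group(3)
            parts.append(f"cdf({_num(m.group(2))}) {unit}")
            continue
        m = _CLAUSE_RANGE.match(c)
        if m:
            unit = m.group(4) or unit
            parts.append(f"rcdf({_num(m.group(2))})*cdf({_num(m.group(3))}) {unit}")
            continue
        return None
    return ",".join(parts)


def normalize_size_text(text: str) -> str:
    """Normalize a size/range phrase to a distribution expression string."""
    t = " ".join(normalize_text(text).split())
    for pat, build in _SIZE_RULES:
        m = pat.match(t)
        if m:
            return build(m)
    multi = _try_quantile_clauses(t)
    if multi is not None:
        return multi
    raise NoMatchError(text, "size", _SIZE_EXAMPLES)


# ---------------------------------------------------------------------------
# shapes  (phrase -> harmonic expression or mixture wrapper)
# ---------------------------------------------------------------------------

_SHAPE_WORDS = {
    "spherical": "Y(0,0)",
    "sphere": "Y(0,0)",
    "wire": "Y(0,0)*scale(100,1,1)",
    "rods": "Y(0,0)*scale(4,1,1)",
    "rod": "Y(0,0)*scale(4,1,1)",
    "cylindrical": "Y(0,0)+Y(2,0)*0.2*scale(3,1,1)",
    "irregular": "bbox()",
}

#: Documented shape words with no agreed formula; refused, not guessed.
_SHAPE_UNMAPPED = {
    "nanohorn": "printed harmonic Y(3,5) violates |m| <= l",
    "tubes": "no harmonic mapping agreed",
    "triangular or rhombic": "no harmonic mapping agreed",
    "hexagonal, clubbed": "no harmonic mapping agreed",
}

_SHAPE_EXAMPLES = list(_SHAPE_WORDS) + [
    "Spherical mixed with irregular",
    "Mixture of spherical, prismatic and rod-shaped",
]

_SHAPE_NAME = r"[a-z-]+"
_MIXED_WITH = re.compile(rf"^({_SHAPE_NAME}) mixed with ({_SHAPE_NAME})$", re.I)
_MIXTURE_OF = re.compile(r"^mixture of (.+)$", re.I)


def _base_shape_word(word: str) -> str:
    w = word.lower().rstrip(".")
    w = re.sub(r"-shaped$", "", w)
    return {"spherical": "sphere", "prismatic": "prism", "rods": "rod"}.get(w, w)


def normalize_shape_text(text: str) -> str:
    """Normalize a shape phrase to a harmonic expression or mixture wrapper."""
    t = " ".join(normalize_text(text).split())
    low = t.lower()
    if low in _SHAPE_UNMAPPED:
        raise ValueError(
            f"shape word {text!r} is documented but not yet mapped: {_SHAPE_UNMAPPED[low]}"
        )
    if low in _SHAPE_WORDS:
        return _SHAPE_WORDS[low]
    m = _MIXED_WITH.match(t)
    if m:
        items = [_base_shape_word(m.group(1)), _base_shape_word(m.group(2))]
        return "{" + ",".join(items) + "}:{}"
    m = _MIXTURE_OF.match(t)
    if m:
        body = m.group(1).replace(" and ", ", ")
        items = [_base_shape_word(w.strip()) for w in body.split(",") if w.strip()]
        return "{" + ",".join(items) + "}:{}"
    raise NoMatchError(text, "shape", _SHAPE_EXAMPLES)


# ---------------------------------------------------------------------------
# mixtures  (phrase -> {items}:{fractions})
# ---------------------------------------------------------------------------

_PCT_PAIR = re.compile(r"([\d.]+)%\s+([A-Za-z][\w()-]*)")
_CONC_LIST = re.compile(
    r"^mass-concentration proportions:?\s*\((.+)\)$", re.I
)
_CONC_ITEM = re.compile(r"^([\d.]+)\s*(mg/L|g/L)\s+(\S+)$")

_MIX_EXAMPLES = [
    "0.45% NaCl w/ 0.1% glucose",
    "Mass-concentration proportions: (96 mg/L A, 60 mg/L B, 60 mg/L C, 4 mg/L D)",
    "At least 99.5% purity",
    "Mixture of spherical, prismatic and rod-shaped",
]


def _try_quantile_mixture(t: str) -> str | None:
    """"50% < 5 nm, 30% 5-10" as a mixture: size classes with fractions."""
    clauses = [c.strip() for c in t.split(",")]
    if len(clauses) < 2:
        return None
    items, fracs = [], []
    unit = "nm"
    for c in clauses:
        m = _CLAUSE_LT.match(c)
        if m:
            unit = m.group(3)
            items.append(f"{_num(m.group(2))} {unit}")
            fracs.append(_pct(m.group(1)))
            continue
        m = _CLAUSE_RANGE.match(c)
        if m:
            unit = m.group(4) or unit
            items.append(f"{_num(m.group(2))}-{_num(m.group(3))} {unit}")
            fracs.append(_pct(m.group(1)))
            continue
        return None
    if sum(float(f) for f in fracs) > 1:
        raise ValueError("mixture fractions sum above 1")
    return "{" + ",".join(items) + "}:{" + ",".join(fracs) + "}"


def normalize_mixture_text(text: str) -> str:
    """Normalize a mixture/media/purity phrase to the mixture operator."""
    t = " ".join(normalize_text(text).split())
    quant = _try_quantile_mixture(t)
    if quant is not None:
        return quant
    m = re.match(r"^at least ([\d.]+)% purity$", t, re.I)
    if m:
        return "...:{cdf(1," + _pct(m.group(1)) + ")}"
    m = _CONC_LIST.match(t)
    if m:
        items, vals, unit = [], [], None
        for chunk in m.group(1).split(","):
            cm = _CONC_ITEM.match(chunk.strip())
            if not cm:
                raise NoMatchError(text, "mixture", _MIX_EXAMPLES)
            vals.append(_num(cm.group(1)))
            unit = cm.group(2)
            items.append(cm.group(3))
        return "{" + ",".join(items) + "}:{" + ",".join(vals) + "}" + (unit or "")
    pairs = _PCT_PAIR.findall(t)
    if pairs and re.fullmatch(
        r"\s*" + r"\s*(?:w/|with|and|,|\+)\s*".join([re.escape(f"{p}% {n}") for p, n in pairs]) + r"\s*",
        t,
        re.I,
    ):
        total = sum(float(p) for p, _ in pairs)
        if total > 100:
            raise ValueError(f"mixture percentages sum to {total}% > 100%")
        items = ",".join(n for _, n in pairs)
        fracs = ",".join(_pct(p) for p, _ in pairs)
        return "{" + items + "}:{" + fracs + "}"
    if t.lower().startswith(("mixture of", "spherical mixed")) or " mixed with " in t.lower():
        return normalize_shape_text(t)
    raise NoMatchError(text, "mixture", _MIX_EXAMPLES)


def normalize_any(text: str) -> tuple[str, str]:
    """Try size, shape and mixture rules in turn; returns (kind, output)."""
    for kind, fn in (
        ("size", normalize_size_text),
        ("mixture", normalize_mixture_text),
        ("shape", normalize_shape_text),
    ):
        try:
            return kind, fn(text)
        except (NoMatchError, ValueError):
            continue
    raise NoMatchError(text, "any", _SIZE_EXAMPLES + _SHAPE_EXAMPLES + _MIX_EXAMPLES)
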