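"""Input text normalization shared by all parsers.

Database excerpts and published tables mix typography: Greek sigma for the
standard deviation, en/em dashes and true minus signs for ranges and negative
numbers, and spaced minus signs ("- 35").  Every parser in this package first
maps its input onto a canonical ASCII form; serializers only ever emit that
form.
"""

from __future__ import annotations

import re

_DASHES = {
    "‐": "-",  # hyphen
    "‑": "-",  # non-breaking hyphen
    "‒": "-",  # figure dash
    "–": "-",  # en dash
    "—": "-",  # em dash
    "−": "-",  # minus sign
}


def normalize_text(s: str) -> str:
    """Map a notation fragment onto its canonical ASCII form.

    sigma -> "sd", all dash variants -> "-", micro sign -> "u",
    ellipsis -> "...", and a minus separated from its digits by spaces is
    glued back ("- 35" -> "-35").
    """
    s = s.replace("σ", "sd").replace("μ", "u").replace("µ", "u")
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    s = s.replace("…", "...")
    s = re.sub(r"-\s+(?=\d)", "-", s)
    return s


def canonicalize(s: str) -> str:
    """Whitespace-canonical form used for byte-exact comparisons.

    In addition to :func:`normalize_text`, whitespace directly after an
    opening delimiter / separator and directly before a closing one is
    removed.  Spaces *inside* tokens (e.g. the item "5 nm") and anything
    inside double quotes are preserved.
    """
    s = normalize_text(s)
    parts = s.split('"')
    for i in range(0, len(parts), 2):  # odd indices are quoted content
        parts[i] = re.sub(r"([({\[,;:*=])\s+", r"\1", parts[i])
        parts[i] = re.sub(r"\s+([)}\],;:*=])", r"\1", parts[i])
    return '"'.join(parts)


def fmt_number(x: float) -> str:
    """Shortest exact decimal form: integers without a trailing ``.0``."""
    if isinstance(x, int):
        return str(x)
    xf = float(x)
    if xf.is_integer() and abs(xf) < 1e16:
        return str(int(xf))
    return repr(xf)


def split_top(s: str, seps: str) -> list[tuple[str, int]]:
    """Split ``s`` on any character of ``seps`` at bracket depth 0.

    Returns ``(token, offset)`` pairs where offset is the 0-based position of
    the token's first character in ``s``.  Respects (), [], {} nesting and
    double-quoted strings.  The separator characters themselves are dropped;
    a separator is reported by starting a new token.
    """
    out: list[tuple[str, int]] = []
    depth = 0
    quoted = False
    start = 0
    for i, ch in enumerate(s):
        if ch == '"':
            quoted = not quoted
        elif not quoted:
            if ch in "([{":
                depth += 1
            elif ch in ")]}":
                depth -= 1
            elif depth == 0 and ch in seps:
                out.append((s[start:i], start))
                start = i + 1
    out.append((s[start:], start))
    return out
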