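"""Particle morphology as spherical-harmonic expansions.

Categorical shape words ("sphere", "rod", "wire") are discontinuous and
incomparable; this module replaces them with a continuous description: the
radial function of a star-shaped surface expanded in real (tesseral)
spherical harmonics,

    r(theta, phi) = sum_lm  c_lm * Y(l, m)(theta, phi) / Y(0, 0),

rescaled so that a lone ``Y(0,0)`` with coefficient 1 is literally the unit
sphere.  An affine ``scale(a, b, c)`` stretches the surface along the three
axes (dimensionless; physical size enters separately through the size layer,
whose diameter d sets r = d/2 for the unit shape).

Geometry queries — volume, surface area, surface/volume ratio — are computed
by Gauss–Legendre quadrature in cos(theta) crossed with a uniform periodic
rule in phi; the affine factors are pulled out analytically where exact
(volume scales by a*b*c).

Elongation presets follow the categorical-to-harmonic mapping table:
wire = ``Y(0,0)*scale(100,1,1)``, rod = ``Y(0,0)*scale(4,1,1)``.  Shapes that
cannot be drawn as r(theta, phi) from one interior point (non-star-shaped
expansions) are rejected rather than silently clamped, and truly irregular
particles fall back to per-axis bounding-box distributions.
"""

from __future__ import annotations

import difflib
import math
import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

from ._text import fmt_number, normalize_text, split_top
from .distributions import DistExpr, parse_dist_expr

__all__ = [
    "AffineScale",
    "HarmonicTerm",
    "HarmonicShape",
    "BoundingBoxShape",
    "ShapeError",
    "parse_shape_expr",
    "from_category",
    "category_table",
    "volume",
    "surface_area",
    "sv_ratio",
    "shape_similarity",
]

DEFAULT_NTHETA = 64
DEFAULT_NPHI = 128

_Y00 = 0.5 / math.sqrt(math.pi)


class ShapeError(ValueError):
    """Raised for invalid harmonic orders, scales or non-star-shaped input."""


@dataclass(frozen=True)
class AffineScale:
    """Axis stretch factors (dimensionless, strictly positive)."""

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ShapeError(f"scale factors must be positive: {(self.a, self.b, self.c)}")

    def compose(self, other: "AffineScale") -> "AffineScale":
        return AffineScale(self.a * other.a, self.b * other.b, self.c * other.c)

    def canonical(self) -> str:
        return f"scale({fmt_number(self.a)},{fmt_number(self.b)},{fmt_number(self.c)})"


@dataclass(frozen=True)
class HarmonicTerm:
    """One expansion term ``coefficient * Y(l, m)`` with an optional scale."""

    l: int
    m: int
    coefficient: float = 1.0
    term_scale: AffineScale | None = None

    def __post_init__(self) -> None:
        if self.l < 0 or abs(self.m) > self.l:
            raise ShapeError(
                f"harmonic order rule violated: Y({self.l},{self.m}) needs |m| <= l"
            )

    def canonical(self) -> str:
        s = f"Y({self.l},{self.m})"
        if self.coefficient != 1.0:
            s += f"*{fmt_number(self.coefficient)}"
        if self.term_scale is not None:
            s += f"*{self.term_scale.canonical()}"
        return s


def _real_sph(l: int, m: int, theta, phi):
    """Real (tesseral) spherical harmonic, Condon–Shortley convention."""
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    if m > 0:
        return math.sqrt(2) * (-1) ** m * np.real(sph_harm_y(l, m, theta, phi))
    return math.sqrt(2) * (-1) ** m * np.imag(sph_harm_y(l, -m, theta, phi))


@dataclass(frozen=True, eq=False)
class HarmonicShape:
    """A star-shaped surface given by a harmonic expansion plus affine scale."""

    terms: tuple[HarmonicTerm, ...]
    global_scale: AffineScale = AffineScale()
    normalization: str = "unit-sphere"  # basis divided by Y(0,0)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ShapeError("shape needs at least one harmonic term")

    # -- canonical structure -------------------------------------------------

    def effective_scale(self) -> AffineScale:
        """Global scale composed multiplicatively with all per-term scales."""
        s = self.global_scale
        for t in self.terms:
            if t.term_scale is not None:
                s = s.compose(t.term_scale)
        return s

    def coefficients(self) -> dict[tuple[int, int], float]:
        """Merged, zero-pruned coefficient map keyed by (l, m)."""
        out: dict[tuple[int, int], float] = {}
        for t in self.terms:
            key = (t.l, t.m)
            out[key] = out.get(key, 0.0) + t.coefficient
        return {k: v for k, v in out.items() if v != 0.0}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HarmonicShape):
            return NotImplemented
        return (
            self.coefficients() == other.coefficients()
            and self.effective_scale() == other.effective_scale()
        )

    def __hash__(self) -> int:
        return hash(
            (tuple(sorted(self.coefficients().items())), self.effective_scale())
        )

    # -- evaluation ----------------------------------------------------------

    def radial(self, theta, phi):
        """Unit radial function (pre-affine): sum of c * Y(l,m) / Y(0,0)."""
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        r = np.zeros(np.broadcast(theta, phi).shape)
        for (l, m), c in self.coefficients().items():
            r = r + c * _real_sph(l, m, theta, phi) / _Y00
        return r

    def is_star_shaped(self, ntheta: int = 90, nphi: int = 180) -> bool:
        th = np.linspace(1e-3, math.pi - 1e-3, ntheta)
        ph = np.linspace(0, 2 * math.pi, nphi, endpoint=False)
        return bool(np.all(self.radial(th[:, None], ph[None, :]) > 0))

    def canonical(self) -> str:
        s = "+".join(t.canonical() for t in self.terms)
        if self.global_scale != AffineScale():
            s += f"*{self.global_scale.canonical()}"
        return s


@dataclass(frozen=True)
class BoundingBoxShape:
    """Irregular morphology: per-axis extent distributions (may be absent)."""

    x: DistExpr | None = None
    y: DistExpr | None = None
    z: DistExpr | None = None

    def canonical(self) -> str:
        parts = [d.canonical() if d is not None else "" for d in (self.x, self.y, self.z)]
        while parts and not parts[-1]:
            parts.pop()
        return f"bbox({';'.join(parts)})"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_Y_RE = re.compile(r"^Y\(\s*(-?\d+)\s*,\s*(-?\d+)\s*\)$")
_SCALE_RE = re.compile(r"^scale\((.*)\)$")
_NUM_RE = re.compile(r"^[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?$")


def parse_shape_expr(text: str) -> HarmonicShape | BoundingBoxShape:
    """Parse ``"Y(0,0)*scale(4,1,1)"``-style expressions or ``bbox(...)``."""
    text = normalize_text(text).strip()
    if not text:
        raise ShapeError("empty shape expression")
    if text.startswith("bbox"):
        m = re.match(r"^bbox\((.*)\)$", text, re.S)
        if not m:
            raise ShapeError(f"malformed bbox expression {text!r}")
        body = m.group(1).strip()
        parts = [p.strip() for p, _ in split_top(body, ";")] if body else []
        if len(parts) > 3:
            raise ShapeError("bbox takes at most three axis distributions")
        dists = [parse_dist_expr(p) if p else None for p in parts]
        dists += [None] * (3 - len(dists))
        return BoundingBoxShape(*dists)

    terms = []
    for chunk, _ in split_top(text, "+"):
        chunk = chunk.strip()
        if not chunk:
            raise ShapeError("empty harmonic term")
        factors = [f.strip() for f, _ in split_top(chunk, "*")]
        ym = _Y_RE.match(factors[0])
        if not ym:
            raise ShapeError(f"term must start with Y(l,m): {factors[0]!r}")
        l, m = int(ym.group(1)), int(ym.group(2))
        coeff = 1.0
        scale: AffineScale | None = None
        for f in factors[1:]:
            sm = _SCALE_RE.match(f)
            if sm:
                vals = [v.strip() for v in sm.group(1).split(",")]
                if len(vals) != 3 or not all(_NUM_RE.match(v) for v in vals):
                    raise ShapeError(f"malformed scale factor {f!r}")
                new = AffineScale(*(float(v) for v in vals))
                scale = new if scale is None else scale.compose(new)
            elif _NUM_RE.match(f):
                coeff *= float(f)
            else:
                raise ShapeError(f"unknown factor {f!r}")
        terms.append(HarmonicTerm(l, m, coeff, scale))
    pruned = tuple(t for t in terms if t.coefficient != 0.0)
    if not pruned:
        raise ShapeError("all terms have zero coefficient")
    return HarmonicShape(pruned)


# ---------------------------------------------------------------------------
# category mapping
# ---------------------------------------------------------------------------

#: Categorical shape words and their harmonic expressions.  ``cylinder`` is a
#: provisional three-term preset (the published mapping elides its scales);
#: ``shell`` shares the sphere geometry — the hollow topology is carried by
#: the component structure, not the radial function.
_CATEGORIES: dict[str, str] = {
    "sphere": "Y(0,0)",
    "shell": "Y(0,0)",
    "wire": "Y(0,0)*scale(100,1,1)",
    "rod": "Y(0,0)*scale(4,1,1)",
    "cylinder": "Y(0,0)+Y(2,0)*0.2*scale(3,1,1)",
}

_ALIASES = {
    "msp": "sphere",
    "spherical": "sphere",
    "msh": "shell",
    "rods": "rod",
    "cylindrical": "cylinder",
}

_UNMAPPABLE = {
    "nanohorn": "the published harmonic Y(3,5) violates |m| <= l; no corrected"
    " mapping has been agreed",
    "irregular": "irregular shapes use bounding-box distributions: bbox(...)",
}


def category_table() -> dict[str, str]:
    """Supported category names mapped to their harmonic expressions."""
    return dict(_CATEGORIES)


def from_category(name: str) -> HarmonicShape:
    """Harmonic shape for a categorical token (``sphere``, ``wire``, ...)."""
    key = _ALIASES.get(name.strip().lower(), name.strip().lower())
    if key in _UNMAPPABLE:
        raise ShapeError(f"category {name!r} has no harmonic mapping: {_UNMAPPABLE[key]}")
    if key not in _CATEGORIES:
        near = difflib.get_close_matches(key, list(_CATEGORIES) + list(_ALIASES), n=3)
        hint = f"; did you mean {', '.join(near)}?" if near else ""
        raise ShapeError(f"unknown shape category {name!r}{hint}")
    shape = parse_shape_expr(_CATEGORIES[key])
    assert isinstance(shape, HarmonicShape)
    return shape


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _grid(ntheta: int, nphi: int):
    u, wu = np.polynomial.legendre.leggauss(ntheta)
    theta = np.arccos(u)
    phi = np.linspace(0.0, 2 * math.pi, nphi, endpoint=False)
    return theta, u, wu, phi, 2 * math.pi / nphi


def _check_star(shape: HarmonicShape, R: np.ndarray) -> None:
    if np.any(R <= 0):
        raise ShapeError(
            "non-star-shaped expansion: radial function is not strictly positive"
        )


def volume(
    shape: HarmonicShape,
    r: float = 1.0,
    ntheta: int = DEFAULT_NTHETA,
    nphi: int = DEFAULT_NPHI,
) -> float:
    """Enclosed volume, V = (abc/3) * r^3 * integral of R^3 dOmega.

    The affine factors multiply the volume exactly (factored analytically);
    only the harmonic part is integrated numerically.
    """
    theta, _, wu, phi, wphi = _grid(ntheta, nphi)
    R = shape.radial(theta[:, None], phi[None, :])
    _check_star(shape, R)
    v_unit = float((wu[:, None] * R**3).sum() * wphi / 3.0)
    s = shape.effective_scale()
    return s.a * s.b * s.c * v_unit * r**3


def surface_area(
    shape: HarmonicShape,
    r: float = 1.0,
    ntheta: int = DEFAULT_NTHETA,
    nphi: int = DEFAULT_NPHI,
) -> float:
    """Surface area via the first fundamental form of the affine-mapped surface."""
    theta, _, wu, phi, wphi = _grid(ntheta, nphi)
    th = theta[:, None]
    ph = phi[None, :]
    R = shape.radial(th, ph)
    _check_star(shape, R)
    h = 1e-5
    Rth = (shape.radial(th + h, ph) - shape.radial(th - h, ph)) / (2 * h)
    Rph = (shape.radial(th, ph + h) - shape.radial(th, ph - h)) / (2 * h)

    st, ct = np.sin(th), np.cos(th)
    sp, cp = np.sin(ph), np.cos(ph)
    n = np.stack([st * cp, st * sp, ct * np.ones_like(sp)])
    nth = np.stack([ct * cp, ct * sp, -st * np.ones_like(sp)])
    nph = np.stack([-st * sp, st * cp, np.zeros(np.broadcast(th, ph).shape)])

    Xth = Rth * n + R * nth
    Xph = Rph * n + R * nph
    s = shape.effective_scale()
    A = np.array([s.a, s.b, s.c]).reshape(3, 1, 1) * r
    Xth = A * Xth
    Xph = A * Xph
    cross = np.cross(Xth, Xph, axisa=0, axisb=0, axisc=0)
    dA = np.sqrt((cross**2).sum(axis=0))
    # Gauss nodes are in u = cos(theta): d(theta) = du / sin(theta)
    return float((wu[:, None] * dA / st).sum() * wphi)


def sv_ratio(
    shape: HarmonicShape,
    r: float = 1.0,
    ntheta: int = DEFAULT_NTHETA,
    nphi: int = DEFAULT_NPHI,
) -> float:
    """Surface-to-volume ratio; equals 3/r for a sphere of radius r."""
    return surface_area(shape, r, ntheta, nphi) / volume(shape, r, ntheta, nphi)


def sv_ratio_equal_volume(
    shape: HarmonicShape,
    ntheta: int = DEFAULT_NTHETA,
    nphi: int = DEFAULT_NPHI,
) -> float:
    """Surface-to-volume ratio after rescaling the shape to unit volume.

    The dimensionless quantity (S/V) * V^(1/3).  This is the scale at which
    the isoperimetric inequality orders shapes: the sphere attains the
    minimum (36*pi)^(1/3) ~= 4.8360, and the ratio grows monotonically with
    elongation (rod < wire among the categorical presets).
    """
    v = volume(shape, 1.0, ntheta, nphi)
    return surface_area(shape, 1.0, ntheta, nphi) / v * v ** (1.0 / 3.0)


def shape_similarity(
    s1: HarmonicShape,
    s2: HarmonicShape,
    metric: str = "svr",
) -> float:
    """Distance between two shapes (0 iff equal under the chosen metric).

    ``svr``: |difference of surface/volume ratios| at unit size;
    ``coeff``: L2 distance between aligned coefficient vectors;
    ``volume_ratio``: |log(V1/V2)| at unit size.
    """
    if metric == "svr":
        return abs(sv_ratio(s1) - sv_ratio(s2))
    if metric == "coeff":
        c1, c2 = s1.coefficients(), s2.coefficients()
        keys = set(c1) | set(c2)
        return math.sqrt(sum((c1.get(k, 0.0) - c2.get(k, 0.0)) ** 2 for k in keys))
    if metric == "volume_ratio":
        return abs(math.log(volume(s1) / volume(s2)))
    raise ShapeError(f"unknown similarity metric {metric!r}")
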