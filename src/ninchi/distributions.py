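"""Distribution-valued quantities for nanomaterial descriptors.

Most quantities attached to a nanomaterial (particle diameter, purity,
surface coverage) are distributions or ranges rather than single numbers.
This module implements the symbolic expression language used to encode them
— ``pdf``/``cdf``/``rcdf`` terms combined by the mixing operator ``*`` — and
the numerics behind it:

* :func:`parse_dist_expr` reads expressions like ``"rcdf(60)*cdf(100) nm"``
  ("size between 60 and 100 nm") into a :class:`DistExpr`;
* :func:`fit_family` solves gamma or normal parameters from stated
  constraints (mean, standard deviation, mode, central interval, quantiles);
* :func:`realize` turns a symbolic expression into a concrete
  :class:`FittedDistribution`;
* :func:`jensen_shannon` and :func:`ks_distance` compare two realized
  distributions.

The default family is the gamma distribution (positive support suits sizes
and purities); the normal family is selectable.  Where the notation leaves a
parameter implicit — a bare ``cdf(x)`` with no probability — the package
defines the default (coverage 0.95) and records it in :class:`~ninchi.config.RunConfig`.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit

from ._text import fmt_number, normalize_text, split_top

__all__ = [
    "DistExpr",
    "FunctionTerm",
    "FittedDistribution",
    "SigmoidFactor",
    "DistributionError",
    "parse_dist_expr",
    "fit_family",
    "realize",
    "sigmoid_factor",
    "product_density",
    "jensen_shannon",
    "jensen_shannon_mc",
    "ks_distance",
]

#: Default probability mass implied by a single-argument cdf(x)/rcdf(x).
DEFAULT_COVERAGE = 0.95
#: Relative standard deviation implied by a bare pdf(x) with no spread given.
DEFAULT_REL_SD = 0.1
#: Gamma shape used when a lone tail constraint leaves the shape free.
DEFAULT_SHAPE = 2.0

KNOWN_UNITS = ("nm", "um", "mm", "m", "mg/L", "g/L")


class DistributionError(ValueError):
    """Raised for malformed expressions or infeasible constraint sets."""


# ---------------------------------------------------------------------------
# symbolic expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FunctionTerm:
    """One factor of a distribution expression.

    ``kind`` is ``pdf`` (a density located at ``location``), ``cdf`` ("mass
    ``p`` below ``location``") or ``rcdf`` (the reversed cdf, "mass ``p``
    above ``location``").  Optional parameters: ``sd`` (standard deviation),
    ``mode``, ``ci`` (an interval-type token and a coverage probability) and
    ``p`` (the probability argument of cdf/rcdf).
    """

    kind: str
    location: float
    p: float | None = None
    sd: float | None = None
    mode: float | None = None
    ci: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("pdf", "cdf", "rcdf"):
            raise DistributionError(f"unknown function name {self.kind!r}")
        if not math.isfinite(self.location):
            raise DistributionError("location must be finite")
        if self.p is not None and not 0 < self.p <= 1:
            raise DistributionError(f"probability {self.p} outside (0, 1]")
        if self.sd is not None and not self.sd > 0:
            raise DistributionError(f"sd must be positive, got {self.sd}")
        if self.ci is not None and not 0 < self.ci[1] <= 1:
            raise DistributionError(f"ci coverage {self.ci[1]} outside (0, 1]")

    def canonical(self) -> str:
        args = [fmt_number(self.location)]
        if self.p is not None:
            args.append(fmt_number(self.p))
        if self.sd is not None:
            args.append(f"sd={fmt_number(self.sd)}")
        if self.mode is not None:
            args.append(f"m={fmt_number(self.mode)}")
        if self.ci is not None:
            args.append(f"ci=({self.ci[0]},{fmt_number(self.ci[1])})")
        return f"{self.kind}({','.join(args)})"


@dataclass(frozen=True)
class DistExpr:
    """A symbolic distribution expression: terms joined by ``*`` (or ``+``).

    ``*`` is the mixing operator of the notation: simultaneous conditions,
    realized as a pointwise product of factors followed by renormalization.
    ``+`` (multi-modal mixtures) is supported as a flagged extension beyond
    the alpha notation.
    """

    terms: tuple[FunctionTerm, ...]
    unit: str | None = None
    combine: str = "product"

    def __post_init__(self) -> None:
        if not self.terms:
            raise DistributionError("expression needs at least one term")
        if self.combine not in ("product", "sum"):
            raise DistributionError(f"unknown combinator {self.combine!r}")

    def canonical(self) -> str:
        op = "*" if self.combine == "product" else "+"
        s = op.join(t.canonical() for t in self.terms)
        return f"{s} {self.unit}" if self.unit else s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


_UNIT_RE = re.compile(
    r"\s*(" + "|".join(re.escape(u) for u in KNOWN_UNITS) + r")\s*$"
)
_TERM_RE = re.compile(r"^\s*([a-z]+)\s*\((.*)\)\s*$", re.S)
_NUM_RE = re.compile(r"^[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?$")


def _parse_number(tok: str, what: str) -> float:
    tok = tok.strip()
    if not _NUM_RE.match(tok):
        raise DistributionError(f"malformed {what}: {tok!r}")
    return float(tok)


def _parse_term(text: str) -> FunctionTerm:
    m = _TERM_RE.match(text)
    if not m:
        raise DistributionError(f"malformed term {text!r}")
    name, body = m.group(1), m.group(2)
    if name not in ("pdf", "cdf", "rcdf"):
        raise DistributionError(f"unknown function name {name!r}")
    args = [a.strip() for a, _ in split_top(body, ",")]
    if not args or not args[0]:
        raise DistributionError(f"{name} needs a location argument")
    kw: dict = {"kind": name, "location": _parse_number(args[0], "location")}
    for a in args[1:]:
        if "=" in a:
            key, _, val = a.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "sd":
                kw["sd"] = _parse_number(val, "sd")
            elif key == "m":
                kw["mode"] = _parse_number(val, "mode")
            elif key == "ci":
                mm = re.match(r"^\((\w+)\s*,\s*([\d.eE+-]+)\)$", val)
                if not mm:
                    raise DistributionError(f"malformed ci parameter {val!r}")
                kw["ci"] = (mm.group(1), _parse_number(mm.group(2), "coverage"))
            elif key == "p":
                kw["p"] = _parse_number(val, "probability")
            else:
                raise DistributionError(f"unknown parameter {key!r}")
        else:
            if "p" in kw:
                raise DistributionError(f"duplicate probability argument {a!r}")
            kw["p"] = _parse_number(a, "probability")
    return FunctionTerm(**kw)


def parse_dist_expr(text: str) -> DistExpr:
    """Parse an expression such as ``"rcdf(60)*cdf(100) nm"``."""
    text = normalize_text(text).strip()
    if not text:
        raise DistributionError("empty distribution expression")
    unit = None
    m = _UNIT_RE.search(text)
    if m:
        unit = m.group(1)
        text = text[: m.start()]
    prods = split_top(text, "*")
    sums = split_top(text, "+")
    if len(prods) > 1 and len(sums) > 1:
        raise DistributionError("cannot mix '*' and '+' in one expression")
    if len(sums) > 1:
        terms = tuple(_parse_term(t) for t, _ in sums)
        return DistExpr(terms, unit, combine="sum")
    terms = tuple(_parse_term(t) for t, _ in prods)
    return DistExpr(terms, unit)


# ---------------------------------------------------------------------------
# concrete distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FittedDistribution:
    """A fitted probability distribution (gamma or normal).

    ``params`` is ``(shape k, scale theta)`` for the gamma family and
    ``(mean, sd)`` for the normal family.
    """

    family: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        a, b = self.params
        if self.family == "gamma":
            if not (a > 0 and b > 0):
                raise DistributionError(f"invalid gamma parameters {self.params}")
        elif self.family == "normal":
            if not b > 0:
                raise DistributionError(f"invalid normal sd {b}")
        else:
            raise DistributionError(f"unknown family {self.family!r}")

    @classmethod
    def gamma(cls, k: float, theta: float) -> "FittedDistribution":
        return cls("gamma", (float(k), float(theta)))

    @classmethod
    def normal(cls, mu: float, sd: float) -> "FittedDistribution":
        return cls("normal", (float(mu), float(sd)))

    def _frozen(self):
        if self.family == "gamma":
            return stats.gamma(self.params[0], scale=self.params[1])
        return stats.norm(*self.params)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, math.inf) if self.family == "gamma" else (-math.inf, math.inf)

    def pdf(self, x):
        return self._frozen().pdf(x)

    def cdf(self, x):
        return self._frozen().cdf(x)

    def ppf(self, q):
        return self._frozen().ppf(q)

    def mean(self) -> float:
        return float(self._frozen().mean())

    def sd(self) -> float:
        return float(self._frozen().std())

    def mode(self) -> float:
        if self.family == "normal":
            return self.params[0]
        k, theta = self.params
        return max(0.0, (k - 1.0) * theta)

    def rvs(self, n: int, rng: np.random.Generator):
        return self._frozen().rvs(size=n, random_state=rng)


# ---------------------------------------------------------------------------
# constraint fitting
# ---------------------------------------------------------------------------


def _gamma_from_mean_sd(mean: float, sd: float) -> FittedDistribution:
    if sd <= 0:
        raise DistributionError("sd must be positive (zero-variance is degenerate)")
    if mean <= 0:
        raise DistributionError("gamma mean must be positive")
    k = (mean / sd) ** 2
    return FittedDistribution.gamma(k, sd * sd / mean)


def _gamma_from_mean_mode(mean: float, mode: float) -> FittedDistribution:
    # k*theta = mean, (k-1)*theta = mode  =>  theta = mean - mode, k = mean/theta
    if not 0 <= mode < mean:
        raise DistributionError(
            f"infeasible: gamma requires 0 <= mode < mean, got mode={mode}, mean={mean}"
        )
    theta = mean - mode
    return FittedDistribution.gamma(mean / theta, theta)


def _gamma_from_mean_ci(mean: float, coverage: float) -> FittedDistribution:
    # Central interval convention for a positive quantity: coverage mass in
    # (0, 2*mean], i.e. within one mean of the stated value.  Solve the shape.
    if mean <= 0:
        raise DistributionError("gamma mean must be positive")

    def f(log_k: float) -> float:
        k = math.exp(log_k)
        return stats.gamma.cdf(2 * mean, k, scale=mean / k) - coverage

    # F(2*mean) is not monotone in k (it tends to 1 both as k -> 0 and
    # k -> inf, with an interior minimum near the exponential case), so
    # bracket the root on the increasing branch: sharper shape, higher
    # confidence.
    lo, hi = math.log(1e-4), math.log(1e6)
    grid = np.linspace(lo, hi, 400)
    vals = np.array([f(g) for g in grid])
    i_min = int(np.argmin(vals))
    if vals[i_min] > 0:
        raise DistributionError(
            f"infeasible central-interval coverage {coverage} (minimum attainable "
            f"is {vals[i_min] + coverage:.6f})"
        )
    log_k = optimize.brentq(f, grid[i_min], hi, xtol=1e-13)
    k = math.exp(log_k)
    return FittedDistribution.gamma(k, mean / k)


def _lsq_fit(family: str, residual_fns, x0: tuple[float, float]) -> FittedDistribution:
    def resid(z):
        d = (
            FittedDistribution.gamma(math.exp(z[0]), math.exp(z[1]))
            if family == "gamma"
            else FittedDistribution.normal(z[0], math.exp(z[1]))
        )
        return [f(d) for f in residual_fns]

    if family == "gamma":
        z0 = [math.log(x0[0]), math.log(x0[1])]
        bounds = ([-40.0, -40.0], [40.0, 40.0])
    else:
        z0 = [x0[0], math.log(x0[1])]
        bounds = ([-1e12, -40.0], [1e12, 40.0])
    sol = optimize.least_squares(
        resid, z0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if family == "gamma":
        return FittedDistribution.gamma(math.exp(sol.x[0]), math.exp(sol.x[1]))
    return FittedDistribution.normal(sol.x[0], math.exp(sol.x[1]))


def fit_family(constraints: dict, family: str = "gamma") -> FittedDistribution:
    """Fit a gamma or normal distribution to stated constraints.

    ``constraints`` may hold ``mean``, ``sd``, ``mode``, ``ci`` (a coverage
    probability, or an ``(interval_type, coverage)`` pair) and ``quantiles``
    (a list of ``(x, p)`` pairs meaning ``F(x) = p``).  Exactly solvable
    cases use closed forms; over-determined sets minimize squared constraint
    residuals.
    """
    if not constraints:
        raise DistributionError("at least one constraint required")
    c = dict(constraints)
    ci = c.get("ci")
    if isinstance(ci, tuple) and len(ci) == 2 and isinstance(ci[0], str):
        ci = ci[1]
    mean, sd, mode = c.get("mean"), c.get("sd"), c.get("mode")
    quantiles = list(c.get("quantiles", ()))
    if sd is not None and sd <= 0:
        raise DistributionError("sd must be positive (zero-variance is degenerate)")

    n_named = sum(x is not None for x in (mean, sd, mode, ci))
    if family == "gamma":
        if not quantiles and n_named <= 2:
            if mean is not None and sd is not None:
                return _gamma_from_mean_sd(mean, sd)
            if mean is not None and mode is not None:
                return _gamma_from_mean_mode(mean, mode)
            if mean is not None and ci is not None:
                return _gamma_from_mean_ci(mean, ci)
            if sd is not None and mode is not None:
                # theta^2 + mode*theta - sd^2 = 0
                theta = (-mode + math.sqrt(mode * mode + 4 * sd * sd)) / 2
                return FittedDistribution.gamma((mode + theta) / theta, theta)
            if mean is not None:
                return _gamma_from_mean_sd(mean, DEFAULT_REL_SD * mean)
            if mode is not None:
                return _gamma_from_mean_mode(mode / (1 - DEFAULT_REL_SD**2), mode)
        if quantiles and n_named == 0:
            for x, p in quantiles:
                if not 0 < p < 1:
                    raise DistributionError(f"quantile probability {p} outside (0,1)")
            if len(quantiles) == 1:
                x, p = quantiles[0]
                theta = x / stats.gamma.ppf(p, DEFAULT_SHAPE)
                return FittedDistribution.gamma(DEFAULT_SHAPE, theta)
    elif family == "normal":
        if not quantiles:
            if mean is None:
                mean = mode
            if mean is None:
                raise DistributionError("normal fit needs a mean or mode")
            if mode is not None and mean is not None and mode != mean and sd is None:
                raise DistributionError("infeasible: normal mode must equal mean")
            if sd is None and ci is not None:
                z = stats.norm.ppf(0.5 + ci / 2)
                sd = abs(mean) / z
            if sd is None:
                sd = DEFAULT_REL_SD * abs(mean) or 1.0
            return FittedDistribution.normal(mean, sd)
    else:
        raise DistributionError(f"unknown family {family!r}")

    # general / over-determined case: least squares
    fns = []
    if mean is not None:
        fns.append(lambda d, v=mean: (d.mean() - v) / max(abs(v), 1e-12))
    if sd is not None:
        fns.append(lambda d, v=sd: (d.sd() - v) / max(abs(v), 1e-12))
    if mode is not None:
        fns.append(lambda d, v=mode: (d.mode() - v) / max(abs(v), 1e-12))
    if ci is not None and mean is not None:
        fns.append(
            lambda d, v=ci, m=mean: d.cdf(2 * m) - d.cdf(0.0) - v
        )
    for x, p in quantiles:
        fns.append(lambda d, x=x, p=p: d.cdf(x) - p)
    if not fns:
        raise DistributionError("constraint set is empty or unsupported")
    m0 = mean if mean is not None else (quantiles[0][0] if quantiles else 1.0)
    s0 = sd if sd is not None else max(abs(m0) * 0.3, 1e-6)
    x0 = ((m0 / s0) ** 2, s0 * s0 / m0) if family == "gamma" else (m0, s0)
    fitted = _lsq_fit(family, fns, x0)
    # quantile claims are hard constraints: a strongly violated one means the
    # set was contradictory (e.g. "95% above 0.7" and "95% below 0.3")
    for x, p in quantiles:
        if abs(fitted.cdf(x) - p) > 0.1:
            raise DistributionError(
                f"infeasible constraints: best fit gives F({x}) = "
                f"{fitted.cdf(x):.4f}, required {p}"
            )
    return fitted


# ---------------------------------------------------------------------------
# realization of symbolic expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidFactor:
    """Logistic weight factor realized from a cdf/rcdf term.

    ``cdf(x, p)`` weights mass below ``x``; its reversed twin ``rcdf(x, p)``
    is the exact pointwise complement: ``rcdf(x)(t) == 1 - cdf(x)(t)``.
    """

    kind: str
    location: float
    tau: float

    def __call__(self, t):
        z = (np.asarray(t, dtype=float) - self.location) / self.tau
        return expit(-z) if self.kind == "cdf" else expit(z)

    def complement(self) -> "SigmoidFactor":
        other = "rcdf" if self.kind == "cdf" else "cdf"
        return SigmoidFactor(other, self.location, self.tau)


def sigmoid_factor(term: FunctionTerm, coverage: float = DEFAULT_COVERAGE) -> SigmoidFactor:
    """Realize a cdf/rcdf term as a logistic weight factor.

    The logistic scale is ``tau = |x|(1-p)/2`` so that tighter probability
    claims sharpen the cut-off.
    """
    if term.kind not in ("cdf", "rcdf"):
        raise DistributionError("sigmoid factors realize only cdf/rcdf terms")
    p = term.p if term.p is not None else coverage
    tau = max(abs(term.location) * (1 - p) / 2, 1e-9 * max(abs(term.location), 1.0))
    return SigmoidFactor(term.kind, term.location, tau)


def _pdf_constraints(term: FunctionTerm) -> dict:
    c: dict = {"mean": term.location}
    if term.sd is not None:
        c["sd"] = term.sd
    if term.mode is not None:
        c["mode"] = term.mode
    if term.ci is not None:
        c["ci"] = term.ci
    return c


def product_density(
    expr: DistExpr,
    family: str = "gamma",
    coverage: float = DEFAULT_COVERAGE,
    npoints: int = 20001,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Numeric renormalized product density of a ``*``-combined expression.

    Returns ``(grid, density, mass)`` where ``mass`` is the integral of the
    raw factor product before renormalization (relative to a uniform base
    when no pdf term is present).  Serves as the quadrature oracle for
    :func:`realize` and flags degenerate (near-empty) intersections.
    """
    if expr.combine != "product":
        raise DistributionError("product_density applies to '*' expressions")
    locs = [t.location for t in expr.terms]
    spread = max(
        [t.sd or 0 for t in expr.terms] + [DEFAULT_REL_SD * max(abs(x) for x in locs)]
    )
    hi = max(abs(x) for x in locs) * 2 + 8 * spread
    lo = 0.0 if family == "gamma" else min(min(locs) - 8 * spread, 0.0)
    t = np.linspace(lo, hi, npoints)
    if family == "gamma":
        t = t[1:]
    dens = np.ones_like(t)
    has_pdf = False
    for term in expr.terms:
        if term.kind == "pdf":
            has_pdf = True
            dens = dens * fit_family(_pdf_constraints(term), family).pdf(t)
        else:
            dens = dens * sigmoid_factor(term, coverage)(t)
    if not has_pdf:
        dens = dens / (hi - lo)  # uniform base measure
    mass = float(np.trapezoid(dens, t))
    if mass < 1e-12:
        raise DistributionError(
            "degenerate expression: renormalized mass below 1e-12 (empty intersection)"
        )
    return t, dens / mass, mass


def realize(
    expr: DistExpr,
    family: str = "gamma",
    coverage: float = DEFAULT_COVERAGE,
) -> FittedDistribution:
    """Realize a symbolic expression as a fitted distribution.

    ``pdf`` terms contribute moment/mode/interval constraints; ``cdf``/
    ``rcdf`` terms contribute quantile constraints (``cdf(x, p)`` means
    ``F(x) = p``; a bare ``cdf(x)`` uses the default coverage).  The family
    parameters are solved from the combined constraint set; degenerate
    products (no overlapping mass) raise.
    """
    if expr.combine == "sum":
        parts = [realize(DistExpr((t,), expr.unit), family, coverage) for t in expr.terms]
        mean = float(np.mean([p.mean() for p in parts]))
        var = float(
            np.mean([p.sd() ** 2 + p.mean() ** 2 for p in parts]) - mean**2
        )
        return fit_family({"mean": mean, "sd": math.sqrt(var)}, family)

    constraints: dict = {}
    quantiles: list[tuple[float, float]] = []
    for term in expr.terms:
        if term.kind == "pdf":
            for key, val in _pdf_constraints(term).items():
                if key in constraints:
                    raise DistributionError(f"conflicting {key} constraints")
                constraints[key] = val
        elif term.kind == "cdf":
            quantiles.append((term.location, term.p if term.p is not None else coverage))
        else:
            quantiles.append(
                (term.location, 1 - (term.p if term.p is not None else coverage))
            )
    if len(expr.terms) > 1:
        product_density(expr, family, coverage, npoints=4001)  # feasibility gate
    if quantiles:
        constraints["quantiles"] = quantiles
    return fit_family(constraints, family)


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------


def _overlap(d1: FittedDistribution, d2: FittedDistribution) -> bool:
    lo1, hi1 = d1.support
    lo2, hi2 = d2.support
    return max(lo1, lo2) < min(hi1, hi2)


def jensen_shannon(
    d1: FittedDistribution,
    d2: FittedDistribution,
    log_base: float = 2.0,
) -> float:
    """Jensen–Shannon divergence between two realized distributions.

    Computed by adaptive quadrature; symmetric, zero iff the densities agree
    almost everywhere, and bounded by 1 in base 2 (``log 2 / log base`` in
    general).
    """
    bound = math.log(2) / math.log(log_base)
    if not _overlap(d1, d2):
        warnings.warn("non-overlapping supports: Jensen-Shannon at its maximum")
        return bound
    if d1 == d2:
        return 0.0
    qlo, qhi = 1e-13, 1 - 1e-13
    lo = min(d1.ppf(qlo), d2.ppf(qlo))
    hi = max(d1.ppf(qhi), d2.ppf(qhi))
    # effectively disjoint densities sit exactly at the bound
    grid = np.linspace(lo, hi, 4001)
    overlap_mass = np.trapezoid(np.minimum(d1.pdf(grid), d2.pdf(grid)), grid)
    if overlap_mass < 1e-9:
        warnings.warn("effectively non-overlapping densities: Jensen-Shannon at its maximum")
        return bound

    # entropy-deficit form, JSD = log 2 - 0.5 * int (p+q) h(p/(p+q)):
    # numerically stable both near 0 (identical inputs) and near the bound
    # (barely overlapping inputs), where the direct form loses precision
    def integrand(t: float) -> float:
        p = d1.pdf(t)
        q = d2.pdf(t)
        tot = p + q
        if tot <= 0 or p <= 0 or q <= 0:
            return 0.0
        w = p / tot
        if w <= 0.0 or w >= 1.0:  # the other density underflowed
            return 0.0
        h = -(w * math.log(w) + (1 - w) * math.log1p(-w))
        return 0.5 * tot * h

    anchors: set[float] = set()
    for d in (d1, d2):
        m, s = d.mean(), d.sd()
        anchors.update((m, d.mode(), m - 3 * s, m + 3 * s, m - s, m + s))
    pts = sorted(x for x in anchors if lo < x < hi)
    deficit, _ = integrate.quad(
        integrand, lo, hi, points=pts or None, limit=500, epsabs=1e-10, epsrel=1e-10
    )
    val = (math.log(2) - deficit) / math.log(log_base)
    return float(min(max(val, 0.0), bound))


def jensen_shannon_mc(
    d1: FittedDistribution,
    d2: FittedDistribution,
    n: int = 10**6,
    seed: int = 0,
    log_base: float = 2.0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the Jensen–Shannon divergence.

    Independent oracle for :func:`jensen_shannon`: samples from each
    distribution and averages the pointwise log-ratio terms.  Returns
    ``(estimate, standard_error)``.
    """
    rng = np.random.default_rng(seed)
    logb = math.log(log_base)
    halves = []
    for da, db in ((d1, d2), (d2, d1)):
        x = da.rvs(n, rng)
        p = da.pdf(x)
        q = db.pdf(x)
        vals = np.log(2 * p / (p + q)) / logb
        halves.append((float(vals.mean()), float(vals.var(ddof=1) / n)))
    est = 0.5 * (halves[0][0] + halves[1][0])
    se = 0.5 * math.sqrt(halves[0][1] + halves[1][1])
    return est, se


def ks_distance(
    d1: FittedDistribution,
    d2: FittedDistribution,
    npoints: int = 200001,
) -> float:
    """Kolmogorov–Smirnov distance: sup over a refined grid of |F1 - F2|."""
    qlo, qhi = 1e-9, 1 - 1e-9
    lo = min(d1.ppf(qlo), d2.ppf(qlo))
    hi = max(d1.ppf(qhi), d2.ppf(qhi))
    t = np.linspace(lo, hi, npoints)
    d = float(np.max(np.abs(d1.cdf(t) - d2.cdf(t))))
    return min(max(d, 0.0), 1.0)
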