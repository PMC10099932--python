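# ninchi

A Python toolkit for an **extended nanomaterial line notation** (NInChI): a
layered, InChI-style string representation of nanomaterials, plus the
computations the notation exists to enable — distribution-valued sizes with
divergence metrics, spherical-harmonic morphology with geometry queries,
component-relation graphs, typed auxiliary comments, and parametrizable
macros.

It is written for nanoinformatics practitioners — database curators, QSAR
modellers, safe-by-design engineers — who need nanomaterial records that are
*accurate* (no information loss), *flexible* (partial knowledge is
representable), *complete* (continuous descriptors, not category words) and
*computable* (similarity and mass-balance queries are one function call).

## The notation in one example

```
1A/Au/msp/s20d-9!/O2Si/msh/s3t-9/y1&2
```

is a silica-coated gold sphere: version `1A`; component 1 `Au`, spherical
(`msp`), diameter 20 nm (`s20d-9`: 20, diameter qualifier, SI exponent −9);
`!` separates components; component 2 `O2Si`, shell, thickness 3 nm; and the
overall-structure layer `y1&2` orders the components inside-out.

On top of the alpha notation the package implements:

* **Distributions** — anywhere a scalar is allowed, a bracketed expression
  encodes a range or distribution: `s[pdf(30,sd=2)]d-9`, `s[rcdf(60)*cdf(100) nm]`.
  `pdf(μ, …)` is a density located at μ; `cdf(x, p)` claims mass *p* below
  *x*; `rcdf = 1 − cdf`; the mixing operator `*` multiplies factors pointwise
  and renormalizes. Expressions realize to fitted gamma (default) or normal
  distributions: constraints such as (μ=27, σ=8) solve *k*=(μ/σ)²,
  θ=σ²/μ; (μ=115, mode=95) solves *k*θ=115, (*k*−1)θ=95. Realized
  distributions compare by Jensen–Shannon divergence (base 2, bounded [0,1])
  or Kolmogorov–Smirnov distance.
* **Morphology** — shapes are star-shaped surfaces r(θ,φ) = Σ c·Y(l,m)/Y(0,0)
  with an affine `scale(a,b,c)`: `m[Y(0,0)*scale(4,1,1)]` is a rod,
  `scale(100,1,1)` a wire. Surface area, volume and S/V ratio come from
  Gauss–Legendre × trapezoid quadrature (sphere: S=4πr², V=4πr³/3, S/V=3/r).
* **Structure graphs** — `y`-orderings, mixtures `{items}:{fractions}` and
  interfaces `i2-1[bond:b;0.7]` build a directed relation graph
  (outer `coats` inner) supporting pattern queries and mass-balance checks.
* **Comments** — `c{Zpotential[-35;mV;urlx]}`: typed, registry-validated
  auxiliary records (dates, floats/distributions, units, URIs, enumerations).
* **Macros** — `d{Sphere(%x) := Y(0,0)*%x}`: reusable, parametrizable
  templates with cycle-safe textual expansion.
* **textmap** — a deterministic rule set that maps database free text
  ("Less than 100 nm", "0.45% NaCl w/ 0.1% glucose") onto the formal
  operators.

## Worked example

```python
from ninchi import parse, serialize
from ninchi import distributions as D, morphology as M, structure_graph as S

rep = parse("1A/Au/msp/s20d-9!/O2Si/msh/s3t-9/y1&2")
print(len(rep.components))                  # 2
print(serialize(rep))                       # the same string back

g = S.build_graph(rep)
print(S.query(g, "coats(*, 1)")[0].source)  # 2  (the silica shell coats the core)

mix = S.parse_mixture("{5 nm, 5-10 nm}:{0.5, 0.3}")
print(100 * S.missing_fraction(mix))        # 20.0  (% of the input undescribed)

d1 = D.realize(D.parse_dist_expr("pdf(27,sd=8)"))
print(d1.params)                            # (11.390625, 2.3703703703703702)
d2 = D.FittedDistribution.gamma(0.5, 18.4)
print(round(D.jensen_shannon(d1, d2), 3))   # 0.583

sphere = M.from_category("sphere")
print(round(M.sv_ratio(sphere, r=15), 3))   # 0.2  (= 3/r)
```

The last numbers mean: half of the mixture's mass is in the 5 nm class and
30% in the 5–10 nm class, so 20% of the sample is unaccounted for; the
narrow 27±8 distribution and the broad heavy-tailed one are strongly
dissimilar (JSD ≈ 0.58 of a possible 1); and a 15-unit sphere carries 0.2
units of surface per unit volume.

A console script exposes the same operations:

```
ninchi parse "1A/Au/msp/s30d-9/k[P4_2/mnm]/y1"
ninchi compare --metric jsd "pdf(27,sd=8) nm" "pdf(30,sd=2) nm"
ninchi normalize "Less than 100 nm"
ninchi expand "Sphere(30e-9)"
```

The normative grammar is shipped as `src/ninchi/grammar.ebnf`; starter
registries for comment headers and macros are under `src/ninchi/data/`.

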