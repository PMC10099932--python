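# Methods

This note documents the models, conventions and numerical choices behind
`ninchi`, in the order a reader meets them: the grammar, the distribution
layer, the morphology layer, graphs, comments, macros, the free-text
normalizer, and the synthetic fixture generator the tests rely on.

## The grammar and its normal form

The notation is a `/`-delimited layer stack per component, components
separated by `!`, cross-component layers (`y`, `i`, `c{}`, `d{}`) after the
last component. The parser is a hand-written, bracket- and quote-aware
tokenizer plus recursive descent; `src/ninchi/grammar.ebnf` is the normative
syntax reference. Design points:

* **ASCII canonical form.** Published tables and database exports mix
  typography (Greek sigma, en-dashes, minus signs with spaces). All parsers
  first normalize to ASCII (`σ→sd`, all dashes→`-`, `µ→u`, `…→...`,
  `− 35→-35`); serializers only emit the ASCII form. A second, stricter
  canonicalization (whitespace stripped around delimiters, quoted text
  untouched) defines the byte-equality used by the golden-table tests.
* **Round trips.** `parse ∘ serialize` is the identity on the package's
  canonical forms, and `serialize ∘ parse` is the identity on canonical
  input strings (including the published example strings). Legacy category
  tokens (`msp` sphere, `msh` shell) are *preserved* on re-emission by
  default; `serialize(harmonic=True)` rewrites them as harmonic
  expressions. Uniqueness is deliberately **not** guaranteed — two strings
  may denote the same material; equality of materials is assessed through
  the similarity metrics, not string identity.
* **Flexibility.** Every layer except the composition is optional; unknown
  layer prefixes are preserved as opaque layers with a warning and survive
  round trips; crystal (`k[...]`) and chirality (`w...`) tokens are opaque
  byte strings (no space-group or chiral-vector semantics).
* **Extended value slots.** Wherever the alpha notation has a scalar, a
  bracketed expression is accepted: `s[pdf(30,sd=2)]d-9` (distribution
  sizes), `m[Y(0,0)*scale(4,1,1)]` (harmonic morphology). The bracket
  syntax, the comment prefix `c{}`, the macro prefix `d{}`, the mixture form
  `y{items}:{fractions}` and the interface form `i1-2[bond:b;0.7]` are this
  package's concrete token choices, collected in one grammar table and
  flagged provisional pending standardization.
* Parse errors carry 0-based character offsets into the normalized input.

## Distribution-valued quantities

Terms: `pdf(x, …)` (a density located at `x`, with optional `sd=σ`, mode
`m=…`, or central interval `ci=(u,p)`), `cdf(x[,p])` ("fraction `p` of mass
below `x`"), `rcdf(x[,p])` (its exact complement). `*` expresses
simultaneous conditions; `+` (multi-modal sums) is supported as an
extension beyond the alpha proposal.

Conventions this implementation defines (the notation leaves them to the
toolchain; all live in `RunConfig` / the CLI config file):

* default family **gamma** on (0, ∞) — sizes and purities are positive and
  right-skewed; normal is selectable;
* a bare `cdf(x)`/`rcdf(x)` implies coverage **p = 0.95**;
* a bare `pdf(x)` implies a relative standard deviation of **0.1·x**;
* `ci=(u,p)` is read as a central interval of coverage `p` on (0, 2μ] — the
  mass within one mean of the stated value; the `u` token is stored opaquely
  (its semantics are not standardized);
* a lone tail constraint leaves the gamma shape free; it defaults to k = 2.

Fitting uses closed forms where they exist — k=(μ/σ)², θ=σ²/μ;
θ=μ−mode, k=μ/θ; the sd+mode quadratic — and bounded least squares in
log-parameter space otherwise. F(2μ) is not monotone in the gamma shape
(it tends to 1 at both extremes), so the interval constraint is solved on
the increasing branch (the sharper, higher-confidence solution).
Contradictory quantile sets (e.g. 95% above 0.7 *and* 95% below 0.3) are
detected two ways: the renormalized sigmoid-product density must carry mass
(≥ 1e-12), and any fitted quantile residual above 0.1 raises. Realized
cdf/rcdf terms also exist as explicit logistic factors with scale
τ = |x|(1−p)/2, for which `rcdf(x)(t) = 1 − cdf(x)(t)` holds to machine
precision.

**Similarity.** The Jensen–Shannon divergence uses log base 2 (bounded
[0, 1]) by default, computed by adaptive quadrature in the entropy-deficit
form JSD = log2 − ½∫(p+q)·h(p/(p+q)), which is numerically stable at both
ends of the range (the direct ∑p·log(p/m) form loses ~1e-8 absolute near
the bound). Densities whose overlap mass is below 1e-9 sit exactly at the
bound (with a warning). An independent Monte-Carlo estimator
(`jensen_shannon_mc`) serves as the oracle in tests; note that for
near-disjoint pairs its standard error is a rare-event underestimate, so
bound-saturated pairs are compared at the bound instead. The
Kolmogorov–Smirnov distance is the sup of |F₁−F₂| over a 2×10⁵-point grid
spanning both distributions' 1e-9…1−1e-9 quantile range.

One printed reference value is knowingly not reproduced: for
Γ(0.44, 23.8) vs Γ(0.5, 18.4) every standard convention (shape/scale or
shape/rate, base 2 or e, divergence or distance) gives a Jensen–Shannon
value near 0.004–0.06, orders of magnitude below the quoted 0.8; the
package therefore exposes the conventions as parameters and validates the
quadrature against the Monte-Carlo oracle rather than against that number.

## Morphology

The radial function r(θ,φ) = Σ c·Y(l,m)/Y(0,0) uses real (tesseral)
harmonics rescaled so a lone `Y(0,0)` with coefficient 1 is the unit sphere.
`scale(a,b,c)` is an affine map of the *surface* (not a radial modulation);
per-term scales compose multiplicatively with the global scale. Physical
size enters through the size layer (diameter d ⇒ r = d/2).

* Volume: V = (abc/3)·r³·∮R³dΩ; the affine factor is exact (factored
  analytically), only the harmonic integral is numeric.
* Area: first fundamental form of the affine-mapped surface; ∂R/∂θ, ∂R/∂φ
  by central differences (h = 1e-5).
* Quadrature: Gauss–Legendre in cosθ (64 nodes) × uniform trapezoid in φ
  (128 nodes), configurable. For the smooth shapes here convergence is
  spectral; sphere and spheroid closed forms are met to ~1e-14 relative,
  far inside the 0.1% contract.
* Non-star-shaped expansions (r ≤ 0 anywhere) are rejected, not clamped.
* Category map: sphere/shell `Y(0,0)`; wire `Y(0,0)*scale(100,1,1)`; rod
  `Y(0,0)*scale(4,1,1)`; cylinder is a **provisional** 3-term preset
  (`Y(0,0)+Y(2,0)*0.2` with `scale(3,1,1)`) because the published mapping
  elides its scales; "nanohorn" is refused because its printed harmonic
  Y(3,5) violates |m| ≤ l; "irregular" maps to per-axis bounding-box
  distributions (`bbox(…)`). A shell shares the sphere's radial function —
  hollowness is a property of the component stack, not of r(θ,φ).
* Similarity metrics: |ΔS/V| at unit size, L2 on aligned coefficient
  vectors, |log V₁/V₂|. Note that at equal *radius* elongation lowers S/V
  (volume grows faster than area under stretching); the isoperimetric
  ordering (sphere minimal, monotone in elongation) holds for the
  volume-normalized ratio (S/V)·V^⅓, exposed as `sv_ratio_equal_volume`.

## Structure graphs

`y i&j&…` (inside-out) becomes a chain of `coats` edges directed
outer→inner; interfaces attach labelled edges (bond label, fraction);
mixtures ride on the graph. Containment subgraphs must be acyclic.
`missing_fraction` = 1 − Σ stated fractions (items without a fraction
contribute nothing — their share *is* the missing mass); concentrations
(`mg/L`) are never silently converted to fractions. Defect extents combine
under set operators with **zero overlap assumed** unless stated — the
inclusion–exclusion lower bound, so `max(e₁,e₂) ≤ union ≤ min(1, e₁+e₂)`
always holds. Graph → structural-layer → graph is a fixed point.

## Comments and macros

Comment headers (`Title:Description:Type1;Type2;…`) live in shareable
plain-text registries; instances are validated totally (a malformed
instance raises, never yields a partial object). Values may be a *proper
prefix* of the signature — incomplete knowledge is representable — but
never exceed it. Dates parse as ISO 8601 or dd/mm/yyyy and serialize as
ISO 8601; Float slots accept distribution expressions; unknown units pass
with an advisory warning (flexibility over strictness).

Macros are purely textual templates (`Name(%a) := body`); %-tokens are
reserved, so hygienic capture cannot arise. Expansion rewrites
non-overlapping invocations per pass until a fixed point (hence
idempotence), with a static cycle check before any rewriting and a depth
limit of 16. In plain text, unregistered names pass through (they may be
ordinary tokens); explicit invocation objects with unknown names raise.
`strip_or_keep` policies: `keep` (verbatim), `expand` (invocations
rewritten, definitions kept), `discard` (definitions dropped after
expansion — lossless w.r.t. the expanded form).

## Free-text normalization

`textmap` is an anchored-regex rule set — deliberately not statistical —
so the mapping is auditable and reproduces the documented phrase table
byte-exactly under the declared canonicalization. Keywords match
case-insensitively; chemical names keep their case. Phrases with no agreed
formal mapping ("Tubes", "Triangular or rhombic") raise a not-yet-mapped
error instead of guessing, and unmatched phrases report the nearest known
patterns. Two table quirks are handled as typos/placeholders: the stray
`}` in the rod mapping is dropped, and the purity row's elided item list is
emitted as the `...` placeholder.

## Synthetic fixtures

`fixture_generate(seed, n)` draws representations covering every layer
kind: 1–3 components; morphology absent / categorical / harmonic / bbox
(30/25/7/38% weights); sizes absent / scalar / distribution-valued; crystal
and chirality tokens from small realistic pools; orderings as random
permutations; mixtures with Dirichlet fractions scaled to sum 0.9;
interfaces, typed comments and macro definitions at low rates. All outputs
validate cleanly and round-trip. The generator emulates the *syntactic*
diversity of curated records, not real measurement noise: passing
round-trip and validation tests demonstrates grammar/metric correctness,
not that any particular laboratory data distribution is captured.
`fixture_registries` similarly generates macro registries that are acyclic
by construction (references only point to later names), or, in cyclic mode,
contain a guaranteed directed cycle.

## Problem sizes and determinism

Default test and acceptance scales: 1000 representations for round trips,
100 registries for macro safety, 20 random distribution pairs × 10⁶
Monte-Carlo samples for the divergence oracle, 64×128 quadrature for
geometry, 2000×4000 brute-force grids for the independent mesh oracles.
Every stochastic path takes an explicit seed; identical inputs, config and
seed give byte-identical outputs.

## Known limitations

* The composition layer is opaque: no chemical-formula validation against
  InChI software.
* Canonicalization/uniqueness is out of scope by design.
* Dynamics (aged materials, time evolution) and a full domain-specific
  language are not modelled; the macro layer is the extent of
  programmability.
* Bounding-box shapes carry no metric geometry (no S/V for `bbox`).
* The inline bracket syntax and cross-layer prefixes are provisional
  choices pending a standards working group.
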