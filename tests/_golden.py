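"""Frozen Before/After rows of the published phrase tables.

The Before cells are kept verbatim (including the source's mixed
typography); outputs must match the After cells byte-exactly after the
package's declared ASCII/whitespace canonicalization.
"""

SIZE_GOLD = [
    ("Less than 100 nm", "cdf(100) nm"),
    ("At least 99.5% purity", "cdf(1, 0.995)"),
    ("90% is below 20 nm", "cdf(20, 0.9) nm"),
    ("Size between 60-100 nm", "rcdf(60)*cdf(100) nm"),
    ("50% < 5 nm, 30% 5–10", "cdf(5) nm, rcdf(5)*cdf(10) nm"),
    ("Mean 27 nm, stdev 8 nm", "pdf(27,σ =8) nm"),
    ("15 nm (size distribution 99%)", "pdf(15,ci=(u,0.99)) nm"),
    ("Mean 115 nm, mode 95 nm", "pdf(115,m=95) nm"),
]

SHAPE_GOLD = [
    ("Wire", "Y(0,0)*scale(100, 1, 1)"),
    # the published Rods cell carries a stray closing brace, treated as a typo
    ("Rods", "Y(0,0)*scale(4, 1, 1)"),
]

MIXTURE_GOLD = [
    ("50% < 5 nm, 30% 5–10", "{5 nm, 5–10 nm}:{0.5, 0.3}"),
    ("Mixture of spherical, prismatic and rod-shaped", "{sphere, prism, rod}:{}"),
    ("0.45% NaCl w/ 0.1% glucose", "{NaCl, glucose}:{0.0045,0.001}"),
    (
        "Mass-concentration proportions: (96 mg/L A, 60 mg/L B, 60 mg/L C, 4 mg/L D)",
        "{A, B, C, D}:{96, 60, 60, 4}mg/L",
    ),
    ("At least 99.5% purity", "…:{cdf(1,0.995)}"),
]

COMMENT_GOLD = [
    "Zpotential[− 35;mV;urlx]",
    "Taxonomy[crustacean]",
    'Publication[21/10/2019;"Author A., Coauthor B.";"J.Nan"]',
]

MACRO_GOLD = [
    ("Anatase", "2O.Ti/k[Ir_1/amd]"),
    ("Sphere (30e-9)", "Y(0,0)*30e-9"),
    ("Mystructure (Au,C8H8,30e-9)", "core(Au) coating(C8H8) sphere(30e-9)"),
]
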