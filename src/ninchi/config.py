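"""Run configuration: the package's paper-unspecified defaults in one place.

The alpha notation deliberately leaves several numerical conventions to the
implementation — the probability implied by a bare ``cdf(x)``, the default
distribution family, the logarithm base of the Jensen–Shannon divergence,
quadrature resolutions.  They are collected here (and in the plain-text
``key=value`` config file the CLI reads) so a revision by a standards
working group needs no code change.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from ._text import fmt_number


@dataclass
class RunConfig:
    coverage: float = 0.95          # mass implied by single-argument cdf/rcdf
    family: str = "gamma"           # default distribution family
    jsd_log_base: float = 2.0       # bounded [0, 1]
    quad_theta: int = 64            # Gauss-Legendre nodes in cos(theta)
    quad_phi: int = 128             # uniform nodes in phi
    legacy: bool = True             # emit legacy msp/msh category tokens
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError(f"coverage {self.coverage} outside (0, 1]")
        if self.family not in ("gamma", "normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.jsd_log_base <= 1:
            raise ValueError("jsd_log_base must exceed 1")
        if self.quad_theta < 4 or self.quad_phi < 4:
            raise ValueError("quadrature resolutions must be at least 4")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                if key in ("quad_theta", "quad_phi", "seed"):
                    kwargs[key] = int(val)
                elif key in ("coverage", "jsd_log_base"):
                    kwargs[key] = float(val)
                elif key == "legacy":
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = val
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, bool):
                    v = "true" if v else "false"
                elif isinstance(v, float):
                    v = fmt_number(v)
                fh.write(f"{f.name}={v}\n")
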