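"""Run configuration: every threshold the pipeline uses, in one place.

Defaults implement the published screening rules: tumors are called
IFNγ-positive when the marker exceeds 1 FPKM, co-expression edges require a
Pearson cc above 0.8, candidates must be upregulated at least 2-fold over
matched normals, the expression-landscape filter uses mean FPKM > 1 and a
Benjamini–Hochberg FDR of 0.05, hubs need more than 45 co-expressed
partners, and the dose-response report flags genes with cc > 0.94 across
the six marker-expression gradient bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Sequence

import yaml

from .errors import ConfigError

#: Gradient bin boundaries in FPKM, highest first. Together with the implicit
#: 0 floor they define six lower-inclusive, half-open bins:
#: [5, inf), [2, 5), [1, 2), [0.5, 1), [0.01, 0.5), [0, 0.01).
DEFAULT_GRADIENT_EDGES: tuple[float, ...] = (5.0, 2.0, 1.0, 0.5, 0.01)


@dataclass
class RunConfig:
    """All tunable thresholds for one pipeline run."""

    theta_marker: float = 1.0          # FPKM threshold splitting tumors into strata
    tau_cc: float = 0.8                # Pearson cc an edge must strictly exceed
    phi_fold: float = 2.0              # minimum (inclusive) candidate fold change
    alpha_fdr: float = 0.05            # BH FDR level for the landscape filter
    hub_degree: int = 45               # degree a hub must strictly exceed
    universe_min_fpkm: float = 1.0     # mean-FPKM floor for network inclusion
    pseudocount: float = 1.0           # additive constant for log/ratio operations
    gradient_edges: tuple[float, ...] = DEFAULT_GRADIENT_EDGES
    gradient_cc_floor: float = 0.94    # cc a gradient profile must strictly exceed
    log_transform: bool = True         # correlate on log2(FPKM + pseudocount)
    screen_include_marker: bool = False  # marker edges may satisfy partnership
    screen_require_component: bool = False  # candidates must share the marker's component
    screen_condition: str = "all_tumors"    # sample set for the screening network
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.gradient_edges = tuple(float(e) for e in self.gradient_edges)
        self.validate()

    def validate(self) -> None:
        if not self.theta_marker > 0:
            raise ConfigError(f"theta_marker must be > 0, got {self.theta_marker}")
        if not 0 < self.tau_cc < 1:
            raise ConfigError(f"tau_cc must be in (0, 1), got {self.tau_cc}")
        if not self.phi_fold >= 1:
            raise ConfigError(f"phi_fold must be >= 1, got {self.phi_fold}")
        if not 0 < self.alpha_fdr < 1:
            raise ConfigError(f"alpha_fdr must be in (0, 1), got {self.alpha_fdr}")
        if self.hub_degree < 0:
            raise ConfigError(f"hub_degree must be >= 0, got {self.hub_degree}")
        if self.pseudocount < 0:
            raise ConfigError(f"pseudocount must be >= 0, got {self.pseudocount}")
        edges = self.gradient_edges
        if len(edges) < 1 or any(e <= 0 for e in edges):
            raise ConfigError("gradient_edges must be positive FPKM values")
        if any(b >= a for a, b in zip(edges, edges[1:])):
            raise ConfigError(f"gradient_edges must be strictly decreasing, got {edges}")
        if self.screen_condition not in ("all_tumors", "positive"):
            raise ConfigError(
                f"screen_condition must be 'all_tumors' or 'positive', got {self.screen_condition!r}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gradient_edges"] = list(self.gradient_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path!r} must hold a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
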