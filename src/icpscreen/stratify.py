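"""Tumor stratification by marker expression, and gradient binning.

Conventions (fixed once, since published interval notation leaves the
boundaries open): a tumor is *positive* iff its marker FPKM strictly
exceeds ``theta``; gradient bins are lower-inclusive half-open intervals
covering the whole non-negative line, ordered from the highest-expression
bin down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .io import ExpressionMatrix, SampleTable

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class StratumAssignment:
    """Per-tumor positive/negative labels (normals are never labeled)."""

    labels: dict[str, str]   # tumor sample -> "positive" | "negative"
    marker_gene: str
    theta: float

    @property
    def positive(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == POSITIVE]

    @property
    def negative(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == NEGATIVE]

    def members(self, stratum: str) -> list[str]:
        if stratum not in (POSITIVE, NEGATIVE):
            raise ValidationError(f"unknown stratum {stratum!r}")
        return self.positive if stratum == POSITIVE else self.negative


@dataclass
class GradientBin:
    lower: float     # inclusive
    upper: float     # exclusive (inf for the top bin)
    members: list[str]


@dataclass
class GradientBinning:
    """Ordered bins (highest marker expression first) partitioning tumors."""

    bins: list[GradientBin]
    marker_gene: str = ""
    unbinned: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unbinned is None:
            self.unbinned = []

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def members_per_bin(self) -> list[list[str]]:
        return [list(b.members) for b in self.bins]

    @classmethod
    def from_members(cls, members: Sequence[Sequence[str]], marker_gene: str = "") -> "GradientBinning":
        """Build a binning from explicit membership lists (e.g. simulation truth)."""
        bins = [GradientBin(math.nan, math.nan, list(m)) for m in members]
        return cls(bins=bins, marker_gene=marker_gene)


def stratify(matrix: ExpressionMatrix, samples: SampleTable, marker: str,
             theta: float = 1.0) -> StratumAssignment:
    """Label each tumor positive iff its marker FPKM > theta (strict).

    The marker is read from the tumor sample only; the boundary value
    ``theta`` itself is negative.
    """
    if marker not in matrix:
        raise ValidationError(f"marker gene {marker!r} absent from matrix")
    if not theta > 0:
        raise ValidationError(f"theta must be > 0, got {theta}")
    row = matrix.df.loc[marker]
    labels = {
        t: (POSITIVE if float(row[t]) > theta else NEGATIVE)
        for t in samples.tumor_samples
    }
    return StratumAssignment(labels=labels, marker_gene=marker, theta=float(theta))


def bin_gradients(matrix: ExpressionMatrix, samples: SampleTable, marker: str,
                  edges: Sequence[float]) -> GradientBinning:
    """Partition tumors into marker-expression bins.

    ``edges`` are strictly decreasing positive FPKM boundaries
    (e.g. ``(5, 2, 1, 0.5, 0.01)``); the bins are ``[e0, inf)``,
    ``[e1, e0)``, ..., ``[0, e_last)`` — every tumor falls in exactly one.
    """
    if marker not in matrix:
        raise ValidationError(f"marker gene {marker!r} absent from matrix")
    edges = [float(e) for e in edges]
    if not edges or any(b >= a for a, b in zip(edges, edges[1:])):
        raise ValidationError(f"edges must be strictly decreasing, got {edges}")
    if edges[-1] <= 0:
        raise ValidationError("edges must be positive")
    bounds = [(edges[0], math.inf)]
    bounds += [(lo, hi) for hi, lo in zip(edges, edges[1:])]
    bounds.append((0.0, edges[-1]))
    bins = [GradientBin(lo, hi, []) for lo, hi in bounds]
    row = matrix.df.loc[marker]
    for t in samples.tumor_samples:
        v = float(row[t])
        for b in bins:
            if b.lower <= v < b.upper:
                b.members.append(t)
                break
    return GradientBinning(bins=bins, marker_gene=marker)
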