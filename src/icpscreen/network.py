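"""Thresholded Pearson co-expression networks around seed genes.

The network for a condition (e.g. IFNγ-positive tumors, all tumors, or
normals) keeps an undirected edge between two genes when their Pearson
correlation — by default on log2(FPKM + pseudocount) — strictly exceeds
``tau``.  By default only edges touching a seed gene are retained
(depth-1 seeded neighborhoods, matching networks drawn around a marker and
known checkpoint genes); an all-pairs mode serves the cross-condition set
analysis.  Genes whose mean raw FPKM over the condition's samples does not
exceed ``universe_min_fpkm`` are excluded up front.  Constant genes have
undefined (NaN) correlations and can never gain an edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix
from .stats import pearson_cc

__all__ = [
    "CoexpressionNetwork", "build_network", "connected_components",
    "hub_genes", "marker_correlations", "pearson_cc",
]


@dataclass
class CoexpressionNetwork:
    """Seeded co-expression network for one condition."""

    condition: str
    graph: nx.Graph                 # nodes: gene IDs; edge attr "cc"
    seeds: frozenset[str]
    universe: frozenset[str]
    tau: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, float(d["cc"])))
        return sorted(out)

    def degree(self, gene: str) -> int:
        return int(self.graph.degree(gene)) if gene in self.graph else 0


def _transformed(matrix: ExpressionMatrix, members: Sequence[str],
                 pseudocount: float, log_scale: bool) -> np.ndarray:
    X = matrix.df[list(members)].to_numpy()
    return np.log2(X + pseudocount) if log_scale else X


def _corr_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized matrix and a mask of constant (undefined) rows."""
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    ss = np.sqrt((Xc * Xc).sum(axis=1, keepdims=True))
    constant = ss[:, 0] == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = Xc / ss
    return Z, constant


def build_network(matrix: ExpressionMatrix, members: Sequence[str],
                  seeds: Sequence[str], *, tau: float = 0.8,
                  universe_min_fpkm: float = 1.0, pseudocount: float = 1.0,
                  log_scale: bool = True, all_pairs: bool = False,
                  condition: str = "") -> CoexpressionNetwork:
    """Build the thresholded network over the given condition samples.

    Universe = genes with mean raw FPKM > ``universe_min_fpkm`` across
    ``members``.  Retained edges: seed–gene and seed–seed pairs (or all
    universe pairs when ``all_pairs``) with cc strictly above ``tau``.
    """
    members = list(members)
    if len(members) < 3:
        raise ValidationError(f"condition {condition!r} has {len(members)} samples; need >= 3")
    seeds = [str(s) for s in seeds]
    missing = [s for s in seeds if s not in matrix]
    if missing:
        raise ValidationError(f"seed genes absent from matrix: {missing}")
    if not seeds:
        raise ValidationError("seed set must be non-empty")

    raw = matrix.df[members]
    universe = list(raw.index[raw.mean(axis=1).to_numpy() > universe_min_fpkm])
    uset = set(universe)
    live_seeds = [s for s in seeds if s in uset]
    graph = nx.Graph()
    graph.add_nodes_from(seeds)     # sub-floor seeds stay as isolated nodes
    if not live_seeds:
        warnings.warn(
            f"all seeds fall below the universe floor ({universe_min_fpkm} FPKM); "
            f"returning an empty network", stacklevel=2)
        return CoexpressionNetwork(condition, graph, frozenset(seeds),
                                   frozenset(universe), float(tau))

    sub = matrix.subset(genes=universe)
    X = _transformed(sub, members, pseudocount, log_scale)
    Z, constant = _corr_rows(X)
    gene_index = {g: i for i, g in enumerate(universe)}

    if all_pairs:
        full = Z @ Z.T                  # NaN rows propagate, never pass tau
        np.clip(full, -1.0, 1.0, out=full)
        with np.errstate(invalid="ignore"):
            mask = np.triu(full > tau, k=1)
        for a, b in zip(*np.nonzero(mask)):
            graph.add_edge(universe[a], universe[b], cc=float(full[a, b]))
    else:
        seed_rows = np.array([gene_index[s] for s in live_seeds])
        C = Z[seed_rows] @ Z.T          # NaN rows propagate, never pass tau
        np.clip(C, -1.0, 1.0, out=C)
        with np.errstate(invalid="ignore"):
            hits = C > tau
        for si, s in enumerate(live_seeds):
            for j in np.flatnonzero(hits[si]):
                g = universe[j]
                if g == s:
                    continue
                graph.add_edge(s, g, cc=float(C[si, j]))

    return CoexpressionNetwork(condition, graph, frozenset(seeds),
                               frozenset(universe), float(tau))


def connected_components(net: CoexpressionNetwork) -> list[set[str]]:
    """Components ordered by decreasing size, ties by smallest member."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def hub_genes(net: CoexpressionNetwork, min_degree: int = 45) -> set[str]:
    """Genes whose supra-threshold degree strictly exceeds ``min_degree``."""
    return {g for g, d in net.graph.degree if d > min_degree}


def marker_correlations(matrix: ExpressionMatrix, members: Sequence[str],
                        marker: str, panel: Sequence[str], *,
                        pseudocount: float = 1.0,
                        log_scale: bool = True) -> pd.DataFrame:
    """Pearson cc of the marker against each panel gene over the condition.

    Returns a DataFrame (gene, cc) sorted by descending cc, undefined last.
    """
    if marker not in matrix:
        raise ValidationError(f"marker gene {marker!r} absent from matrix")
    missing = [g for g in panel if g not in matrix]
    if missing:
        raise ValidationError(f"panel genes absent from matrix: {missing}")
    sub = matrix.subset(genes=[marker] + [g for g in panel if g != marker])
    X = _transformed(sub, list(members), pseudocount, log_scale)
    mrow = X[0]
    rows = []
    for g in panel:
        grow = X[sub.gene_ids.index(g)]
        rows.append((g, pearson_cc(mrow, grow)))
    out = pd.DataFrame(rows, columns=["gene", "cc"])
    return out.sort_values("cc", ascending=False, na_position="last",
                           kind="mergesort").reset_index(drop=True)
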