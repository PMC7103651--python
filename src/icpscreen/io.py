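"""Tabular input/output and the validated data model every stage consumes.

Three tab-separated inputs drive the pipeline:

* an expression matrix (genes as rows, samples as columns, FPKM units),
* a sample table pairing each tumor with its patient-matched normal,
* a gene annotation assigning roles (marker / icp / icprg_candidate / ...).

Co-expression networks are exported for visualization tools (e.g. Cytoscape)
as edge-list TSV, GraphML or SIF.

Values round-trip bit-for-bit through text: floats are written with Python's
shortest round-trip decimal representation.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

TISSUES = ("tumor", "normal")
ROLES = ("marker", "icp", "icprg_candidate", "immune", "signaling", "other")
STAGE_GROUPS = ("LST", "HST")

SAMPLE_TABLE_COLUMNS = ("sample_id", "patient_id", "tissue", "pair_id")
ANNOTATION_COLUMNS = ("gene_id", "role")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} ID {x!r}")
        seen.add(x)


class ExpressionMatrix:
    """Gene × sample FPKM abundances.

    Thin wrapper over a float64 DataFrame (index = gene IDs, columns =
    sample IDs) that enforces: unique IDs, finite non-negative values.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise ValidationError("ExpressionMatrix expects a DataFrame")
        _check_unique(list(data.index), "gene")
        _check_unique(list(data.columns), "sample")
        values = data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative FPKM at gene {data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        self._df = data.astype(float)
        self._df.index = self._df.index.astype(str)
        self._df.columns = self._df.columns.astype(str)
        self._df.index.name = "gene_id"

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def __contains__(self, gene: str) -> bool:
        return gene in self._df.index

    def row(self, gene: str) -> np.ndarray:
        """FPKM vector of one gene across all samples."""
        if gene not in self._df.index:
            raise ValidationError(f"gene {gene!r} absent from matrix")
        return self._df.loc[gene].to_numpy()

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        df = self._df
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise ValidationError(f"genes absent from matrix: {missing}")
            df = df.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise ValidationError(f"samples absent from matrix: {missing}")
            df = df[list(samples)]
        return ExpressionMatrix(df.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._df.equals(other._df)


class SampleTable:
    """Tumor/normal pairing of samples.

    Every ``pair_id`` must occur exactly twice — once with tissue ``tumor``
    and once with ``normal`` (a half pair, like the excluded T7/N7 in the
    original cohort, is rejected by name).
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"sample table missing required columns: {missing}")
        df = data.copy()
        for c in SAMPLE_TABLE_COLUMNS:
            df[c] = df[c].astype(str)
        if "stage_group" not in df.columns:
            df["stage_group"] = ""
        df["stage_group"] = df["stage_group"].fillna("").astype(str)
        bad_stage = sorted(set(df["stage_group"]) - set(STAGE_GROUPS) - {""})
        if bad_stage:
            raise ValidationError(f"invalid stage_group values: {bad_stage}")
        _check_unique(list(df["sample_id"]), "sample")
        bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
        if bad_tissue:
            raise ValidationError(f"invalid tissue values: {bad_tissue} (must be tumor/normal)")
        for pair_id, grp in df.groupby("pair_id", sort=False):
            tissues = sorted(grp["tissue"])
            if tissues != ["normal", "tumor"]:
                raise ValidationError(
                    f"pair {pair_id!r} must have exactly one tumor and one normal sample, "
                    f"got tissues {list(grp['tissue'])}"
                )
        self._df = df[["sample_id", "patient_id", "tissue", "pair_id", "stage_group"]].reset_index(drop=True)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df["sample_id"])

    @property
    def tumor_samples(self) -> list[str]:
        return list(self._df.loc[self._df["tissue"] == "tumor", "sample_id"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self._df.loc[self._df["tissue"] == "normal", "sample_id"])

    @property
    def n_pairs(self) -> int:
        return self._df["pair_id"].nunique()

    def pairs(self) -> list[tuple[str, str]]:
        """(tumor_sample, normal_sample) per pair, in first-appearance order."""
        out = []
        for pair_id, grp in self._df.groupby("pair_id", sort=False):
            t = grp.loc[grp["tissue"] == "tumor", "sample_id"].iloc[0]
            n = grp.loc[grp["tissue"] == "normal", "sample_id"].iloc[0]
            out.append((t, n))
        return out

    def matched_normal(self, tumor_sample: str) -> str:
        row = self._df[self._df["sample_id"] == tumor_sample]
        if row.empty or row["tissue"].iloc[0] != "tumor":
            raise ValidationError(f"{tumor_sample!r} is not a tumor sample")
        pair = row["pair_id"].iloc[0]
        grp = self._df[(self._df["pair_id"] == pair) & (self._df["tissue"] == "normal")]
        return grp["sample_id"].iloc[0]

    def check_against(self, matrix: ExpressionMatrix) -> None:
        """Every listed sample must exist in the matrix."""
        missing = [s for s in self.sample_ids if s not in set(matrix.sample_ids)]
        if missing:
            raise ValidationError(f"samples absent from expression matrix: {missing}")


class GeneAnnotation:
    """Gene → role assignment. Exactly one marker gene; a non-empty ICP set."""

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in ANNOTATION_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"gene annotation missing required columns: {missing}")
        df = data.copy()
        df["gene_id"] = df["gene_id"].astype(str)
        df["role"] = df["role"].astype(str)
        _check_unique(list(df["gene_id"]), "gene")
        bad = sorted(set(df["role"]) - set(ROLES))
        if bad:
            raise ValidationError(f"invalid roles: {bad} (allowed: {list(ROLES)})")
        markers = list(df.loc[df["role"] == "marker", "gene_id"])
        if len(markers) != 1:
            raise ValidationError(
                f"exactly one gene must have role=marker, got {len(markers)}: {markers}"
            )
        if (df["role"] == "icp").sum() == 0:
            raise ValidationError("annotation must list at least one gene with role=icp")
        self._df = df[["gene_id", "role"]].reset_index(drop=True)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def marker_gene(self) -> str:
        return self._df.loc[self._df["role"] == "marker", "gene_id"].iloc[0]

    def genes_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r}")
        return list(self._df.loc[self._df["role"] == role, "gene_id"])

    @property
    def icp_genes(self) -> list[str]:
        return self.genes_with_role("icp")

    @property
    def candidate_genes(self) -> list[str]:
        return self.genes_with_role("icprg_candidate")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str) -> ExpressionMatrix:
    """Parse a TSV with gene IDs in the first column and sample IDs as header."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed file
        raise ParseError(f"cannot parse expression matrix {path!r}: {exc}") from exc
    try:
        _check_unique([str(x) for x in df.index], "gene")
        _check_unique([str(x) for x in df.columns], "sample")
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc
    def _cell(value, gene, sample):
        # python float() is correctly rounded, so written values re-read exactly
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ParseError(
                f"non-numeric value {value!r} at gene {gene!r}, sample {sample!r}"
            ) from None

    if df.isna().to_numpy().any():
        g, s = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(f"missing value at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    numeric = pd.DataFrame(
        [[_cell(df.iat[g, s], df.index[g], df.columns[s])
          for s in range(df.shape[1])] for g in range(df.shape[0])],
        index=df.index, columns=df.columns)
    try:
        return ExpressionMatrix(numeric)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_expression_matrix(matrix: ExpressionMatrix, path: str) -> None:
    matrix.df.to_csv(path, sep="\t")


def _read_table(path: str, required: Sequence[str], kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise ParseError(f"cannot parse {kind} {path!r}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{kind} {path!r} missing required columns: {missing}")
    return df


def read_sample_table(path: str) -> SampleTable:
    df = _read_table(path, SAMPLE_TABLE_COLUMNS, "sample table")
    try:
        return SampleTable(df)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_sample_table(samples: SampleTable, path: str) -> None:
    samples.df.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str) -> GeneAnnotation:
    df = _read_table(path, ANNOTATION_COLUMNS, "gene annotation")
    try:
        return GeneAnnotation(df)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_gene_annotation(annotation: GeneAnnotation, path: str) -> None:
    annotation.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("edge-list", "graphml", "sif")


def _as_graph(net) -> nx.Graph:
    return net.graph if hasattr(net, "graph") and isinstance(net.graph, nx.Graph) else net


def canonical_edges(net) -> list[tuple[str, str, float]]:
    """Undirected edges as (geneA, geneB, cc) with geneA < geneB, sorted."""
    g = _as_graph(net)
    edges = []
    for u, v, d in g.edges(data=True):
        a, b = sorted((str(u), str(v)))
        edges.append((a, b, float(d.get("cc", float("nan")))))
    return sorted(edges)


def write_network(net, path: str, format: str = "edge-list") -> None:
    """Export a co-expression network.

    ``edge-list``: TSV ``geneA<TAB>geneB<TAB>cc``, lexicographically ordered.
    ``graphml``: full graph with cc as an edge attribute (preserves isolated nodes).
    ``sif``: Cytoscape simple-interaction lines using the relation token ``coexp``.
    """
    if format not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format {format!r} (allowed: {list(NETWORK_FORMATS)})")
    g = _as_graph(net)
    edges = canonical_edges(g)
    if format == "edge-list":
        with open(path, "w") as fh:
            fh.write("geneA\tgeneB\tcc\n")
            for a, b, cc in edges:
                fh.write(f"{a}\t{b}\t{cc!r}\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b, _ in edges:
                fh.write(f"{a}\tcoexp\t{b}\n")
            for n in sorted(g.nodes):
                if g.degree(n) == 0:
                    fh.write(f"{n}\n")
    else:  # graphml
        out = nx.Graph()
        out.add_nodes_from(sorted(str(n) for n in g.nodes))
        for a, b, cc in edges:
            out.add_edge(a, b, cc=cc)
        nx.write_graphml(out, path)


def read_network(path: str, format: str = "edge-list") -> nx.Graph:
    """Re-import an exported network. SIF carries no cc values."""
    if format not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format {format!r} (allowed: {list(NETWORK_FORMATS)})")
    g = nx.Graph()
    if format == "graphml":
        raw = nx.read_graphml(path)
        for n in raw.nodes:
            g.add_node(str(n))
        for u, v, d in raw.edges(data=True):
            g.add_edge(str(u), str(v), cc=float(d["cc"]))
        return g
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if format == "edge-list":
        if not lines or lines[0].split("\t")[:3] != ["geneA", "geneB", "cc"]:
            raise ParseError(f"edge list {path!r} missing 'geneA geneB cc' header")
        for ln in lines[1:]:
            parts = ln.split("\t")
            if len(parts) != 3:
                raise ParseError(f"malformed edge line in {path!r}: {ln!r}")
            g.add_edge(parts[0], parts[1], cc=float(parts[2]))
    else:  # sif
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) == 1:
                g.add_node(parts[0])
            elif len(parts) >= 3 and parts[1] == "coexp":
                for b in parts[2:]:
                    g.add_edge(parts[0], b)
            else:
                raise ParseError(f"malformed SIF line in {path!r}: {ln!r}")
    return g
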