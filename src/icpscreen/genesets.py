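"""Stacked-FPKM gene-set scores and between-strata comparison.

The stacked score of a set is the plain per-sample sum of its members' raw
FPKM rows (no pseudocount, no log) — e.g. the eight-cytotoxin panel PRF1 /
GZMM / GZMK / GZMH / GZMB / GZMA / FASLG / FAS.  Strata are compared with a
fold of pseudocounted means and a two-sided *unpaired* t test on
log2(score + pseudocount), unpaired because the two strata are different
patients.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .io import ExpressionMatrix
from .stats import unpaired_t_pvalue
from .stratify import StratumAssignment


def stacked_fpkm(matrix: ExpressionMatrix, geneset: Sequence[str]) -> pd.Series:
    """Per-sample sum of raw FPKM over the member genes."""
    genes = [str(g) for g in geneset]
    if not genes:
        raise ValidationError("gene set is empty")
    if len(set(genes)) != len(genes):
        raise ValidationError("gene set contains duplicate members")
    missing = [g for g in genes if g not in matrix]
    if missing:
        raise ValidationError(f"gene-set members absent from matrix: {missing}")
    return matrix.df.loc[genes].sum(axis=0)


def compare_strata(score: pd.Series, strata: StratumAssignment,
                   pseudocount: float = 1.0) -> tuple[float, float]:
    """(fold, p) of a stacked score between positive and negative tumors.

    fold = mean(positive + pc) / mean(negative + pc); p from an unpaired
    two-sided t test on log2(score + pc).
    """
    pos = strata.positive
    neg = strata.negative
    if not pos or not neg:
        raise ValidationError("both strata must be non-empty")
    missing = [s for s in pos + neg if s not in score.index]
    if missing:
        raise ValidationError(f"stratum samples missing from score vector: {missing}")
    a = score[pos].to_numpy(dtype=float)
    b = score[neg].to_numpy(dtype=float)
    fold = float((a.mean() + pseudocount) / (b.mean() + pseudocount))
    p = unpaired_t_pvalue(np.log2(a + pseudocount), np.log2(b + pseudocount))
    return fold, p


def read_gene_sets(path: str) -> dict[str, list[str]]:
    """Parse a two-column TSV (set_name, gene_id) into named gene lists."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse gene sets {path!r}: {exc}") from exc
    for col in ("set_name", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"gene sets {path!r} missing required column {col!r}")
    out: dict[str, list[str]] = {}
    for name, grp in df.groupby("set_name", sort=False):
        out[str(name)] = [str(g) for g in grp["gene_id"]]
    return out


def geneset_table(matrix: ExpressionMatrix, strata: StratumAssignment,
                  genesets: dict[str, Sequence[str]],
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """One row per set: stacked-score stratum means, fold and p."""
    rows = []
    for name, genes in genesets.items():
        score = stacked_fpkm(matrix, genes)
        fold, p = compare_strata(score, strata, pseudocount)
        rows.append({
            "set_name": name,
            "n_genes": len(genes),
            "mean_positive": float(score[strata.positive].mean()),
            "mean_negative": float(score[strata.negative].mean()),
            "fold": fold,
            "p_value": p,
        })
    return pd.DataFrame(rows)
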