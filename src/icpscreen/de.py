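"""Per-stratum paired tumor-vs-normal differential expression.

Fold change is the ratio of pseudocounted stratum means (tumor over matched
normal); significance comes from a two-sided paired t test on
log2(FPKM + pseudocount) within-pair differences; q-values are
Benjamini–Hochberg.  The expression-landscape filter then splits the gene
universe into expressed-and-DE / expressed-not-DE / low, mirroring the
"average FPKM > 1 and FDR < 0.05" screen applied to the original cohort.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, SampleTable
from .stats import bh_fdr, paired_t_pvalue, paired_t_pvalues_matrix

DE_COLUMNS = ("gene_id", "stratum", "fold_change", "p_value", "q_value",
              "mean_tumor_fpkm", "mean_normal_fpkm")


def _stratum_pairs(samples: SampleTable, stratum_members: Sequence[str]) -> list[tuple[str, str]]:
    members = set(stratum_members)
    pairs = [(t, n) for t, n in samples.pairs() if t in members]
    unknown = members - {t for t, _ in samples.pairs()}
    if unknown:
        raise ValidationError(f"stratum members are not tumor samples: {sorted(unknown)}")
    return pairs


def fold_change(matrix: ExpressionMatrix, samples: SampleTable,
                stratum_members: Sequence[str], gene: str,
                pseudocount: float = 1.0) -> float:
    """(mean tumor FPKM + pc) / (mean matched-normal FPKM + pc) within a stratum."""
    pairs = _stratum_pairs(samples, stratum_members)
    if len(pairs) < 2:
        raise ValidationError(f"stratum has {len(pairs)} pairs; need >= 2")
    row = matrix.df.loc[gene] if gene in matrix else None
    if row is None:
        raise ValidationError(f"gene {gene!r} absent from matrix")
    t = np.array([row[a] for a, _ in pairs], dtype=float)
    n = np.array([row[b] for _, b in pairs], dtype=float)
    return float((t.mean() + pseudocount) / (n.mean() + pseudocount))


def paired_test(matrix: ExpressionMatrix, samples: SampleTable,
                stratum_members: Sequence[str], gene: str,
                pseudocount: float = 1.0) -> float:
    """Two-sided paired t p-value on log2(FPKM + pc) within-pair differences."""
    pairs = _stratum_pairs(samples, stratum_members)
    if len(pairs) < 3:
        raise ValidationError(f"stratum has {len(pairs)} pairs; need >= 3")
    if gene not in matrix:
        raise ValidationError(f"gene {gene!r} absent from matrix")
    row = matrix.df.loc[gene]
    t = np.array([row[a] for a, _ in pairs], dtype=float)
    n = np.array([row[b] for _, b in pairs], dtype=float)
    diffs = np.log2(t + pseudocount) - np.log2(n + pseudocount)
    return paired_t_pvalue(diffs)


def compute_de(matrix: ExpressionMatrix, samples: SampleTable,
               stratum_members: Sequence[str], stratum_label: str,
               pseudocount: float = 1.0) -> pd.DataFrame:
    """Fold change, paired-t p and BH q for every gene, one stratum.

    Returns a DataFrame with columns :data:`DE_COLUMNS`, one row per gene in
    matrix order; ``attrs['stratum']`` records the stratum label.
    """
    pairs = _stratum_pairs(samples, stratum_members)
    if len(pairs) < 3:
        raise ValidationError(
            f"stratum {stratum_label!r} has {len(pairs)} pairs; need >= 3"
        )
    t_cols = [t for t, _ in pairs]
    n_cols = [n for _, n in pairs]
    T = matrix.df[t_cols].to_numpy()
    N = matrix.df[n_cols].to_numpy()
    diffs = np.log2(T + pseudocount) - np.log2(N + pseudocount)
    p = paired_t_pvalues_matrix(diffs)
    q = bh_fdr(p)
    mean_t = T.mean(axis=1)
    mean_n = N.mean(axis=1)
    de = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "stratum": stratum_label,
        "fold_change": (mean_t + pseudocount) / (mean_n + pseudocount),
        "p_value": p,
        "q_value": q,
        "mean_tumor_fpkm": mean_t,
        "mean_normal_fpkm": mean_n,
    })
    de.attrs["stratum"] = stratum_label
    return de


def landscape_filter(matrix: ExpressionMatrix, samples: SampleTable,
                     de: pd.DataFrame, min_fpkm: float = 1.0,
                     alpha: float = 0.05) -> dict[str, set[str]]:
    """Partition the gene universe by abundance and differential expression.

    ``expressed_de``: mean FPKM (over all listed samples) > min_fpkm and
    q < alpha; ``expressed_not_de``: above the floor but not significant;
    ``low``: everything else (including genes absent from the DE table).
    """
    mean_fpkm = matrix.df[samples.sample_ids].mean(axis=1)
    q_by_gene: Mapping[str, float] = dict(zip(de["gene_id"], de["q_value"])) if len(de) else {}
    expressed_de: set[str] = set()
    expressed_not_de: set[str] = set()
    low: set[str] = set()
    for gene in matrix.gene_ids:
        expressed = mean_fpkm[gene] > min_fpkm
        q = q_by_gene.get(gene)
        if expressed and q is not None and q < alpha:
            expressed_de.add(gene)
        elif expressed and q is not None:
            expressed_not_de.add(gene)
        else:
            low.add(gene)
    return {"expressed_de": expressed_de, "expressed_not_de": expressed_not_de, "low": low}
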