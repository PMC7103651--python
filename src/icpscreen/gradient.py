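"""Marker dose-response across expression-gradient bins.

Tumors are split into ordered marker-expression bins (six by default); per
bin the unweighted arithmetic mean of raw FPKM is taken for each gene of
interest, and the Pearson correlation between the marker's per-bin means
and each gene's per-bin means summarizes dose dependence.  A gene "tracks"
the marker when that cc strictly exceeds the floor (default 0.94).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix
from .stats import pearson_cc
from .stratify import GradientBinning


def gradient_profile(matrix: ExpressionMatrix, binning: GradientBinning,
                     marker: str, genes: Sequence[str]) -> pd.DataFrame:
    """Per-bin mean FPKM and marker correlation for each gene.

    Empty bins yield missing means and are dropped from the correlation;
    at least 3 usable bins are required.  Constant genes get a NaN cc.
    Columns: gene_id, mean_bin1..k, cc.
    """
    if marker not in matrix:
        raise ValidationError(f"marker gene {marker!r} absent from matrix")
    missing = [g for g in genes if g not in matrix]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    members = binning.members_per_bin()
    k = len(members)
    if k < 3:
        raise ValidationError(f"need >= 3 bins, got {k}")
    usable = [i for i, m in enumerate(members) if len(m) > 0]
    if len(usable) < 3:
        raise ValidationError(f"only {len(usable)} non-empty bins; need >= 3")

    def bin_means(gene: str) -> list[float]:
        row = matrix.df.loc[gene]
        return [float(row[m].mean()) if m else math.nan for m in members]

    marker_means = bin_means(marker)
    mvec = np.array([marker_means[i] for i in usable])
    rows = []
    for g in genes:
        means = bin_means(g)
        gvec = np.array([means[i] for i in usable])
        cc = pearson_cc(mvec, gvec)
        rows.append([g, *means, cc])
    cols = ["gene_id"] + [f"mean_bin{i + 1}" for i in range(k)] + ["cc"]
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["n_per_bin"] = [len(m) for m in members]
    out.attrs["marker_gene"] = marker
    return out


def gradient_report(profiles: pd.DataFrame, cc_floor: float = 0.94) -> pd.DataFrame:
    """Add a ``passes`` flag: cc strictly above the floor (NaN never passes)."""
    out = profiles.copy()
    cc = out["cc"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["passes"] = cc > cc_floor
    out.attrs.update(profiles.attrs)
    out.attrs["cc_floor"] = float(cc_floor)
    return out
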