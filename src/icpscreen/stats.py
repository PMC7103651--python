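"""Small statistical primitives shared by the pipeline stages.

Conventions for degenerate inputs are fixed here once:

* Pearson cc of a constant vector is undefined and returned as NaN (a
  flagged missing value, never 0); NaN never passes a strict threshold.
* A t test whose within-group variance is exactly zero returns p = 1 when
  the observed effect is zero and p = 0 otherwise (the limit of the t
  statistic as s -> 0).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    cc = float(xc @ yc) / np.sqrt(sx * sy)
    return float(min(1.0, max(-1.0, cc)))


def _zero_variance_p(effect: float) -> float:
    return 1.0 if effect == 0.0 else 0.0


def paired_t_pvalue(diffs: Sequence[float]) -> float:
    """Two-sided one-sample t test of mean(diffs) = 0, with s=0 conventions."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 3:
        raise ValidationError(f"paired test needs >= 3 pairs, got {d.size}")
    if np.ptp(d) == 0.0:
        return _zero_variance_p(float(d[0]))
    t, p = sps.ttest_rel(d, np.zeros_like(d))
    return float(p)


def unpaired_t_pvalue(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided two-sample (equal-variance) t test with s=0 conventions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("unpaired test needs >= 2 observations per group")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return _zero_variance_p(float(a[0] - b[0]))
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotonized, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([], dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_t_pvalues_matrix(diffs: np.ndarray) -> np.ndarray:
    """Row-wise two-sided paired t p-values for a (genes x pairs) diff matrix.

    Vectorized version of :func:`paired_t_pvalue` with the same zero-variance
    conventions, used by the differential-expression stage.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 2 or d.shape[1] < 3:
        raise ValidationError("diff matrix must be (genes x >=3 pairs)")
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.empty(d.shape[0], dtype=float)
    degenerate = np.ptp(d, axis=1) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    ok = ~degenerate
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), n - 1)
    p[degenerate] = np.where(mean[degenerate] == 0.0, 1.0, 0.0)
    return p
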