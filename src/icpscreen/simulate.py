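"""Synthetic paired tumor/normal FPKM cohorts with a planted latent
IFNγ-activity factor.

The generative model is a single latent factor: each tumor sample ``s``
carries a dimensionless activity ``a_s`` (two levels for the case/control
cohort, evenly spaced levels for the gradient cohort; matched normals have
``a = 0``).  For gene ``g`` with loading ``beta_g``,

    log2(FPKM + pseudocount) = mu_g + beta_g * a_s + eps,   eps ~ N(0, sigma^2)

and FPKM is back-transformed with the pseudocount subtracted and floored at
zero.  Module genes (the marker's co-expression module: ICPs, planted
candidates and other induced genes) share one loading ``beta``; background
("null") genes have loading zero.  The marker gene shares the module
loading but sits on a low fixed baseline so that, noise-free, active tumors
sit above the 1-FPKM stratification threshold and inactive tumors below it.

One factor reproduces the qualitative topology the screen assumes — the
marker, the ICPs and the candidates co-expressed within a single network
component against an uncorrelated background — while keeping every
population moment analytic (true fold change of a module gene in active
tumors is exactly ``2**(beta * activity_high)`` on the pseudocounted scale).

Draw order (all from one :func:`numpy.random.default_rng` stream seeded with
``rng_seed``): (1) per-gene baselines ``mu_g``; (2) the tumor-activity
permutation; (3) the full noise matrix, genes x (tumors then normals).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, GeneAnnotation, SampleTable

MARKER_GENE = "IFNG"
DEFAULT_ICPS = ("CTLA4", "PDCD1", "CD274", "HAVCR2", "IDO1", "LAG3")
DEFAULT_CANDIDATES = ("IFI30", "GBP1", "GBP4")

#: Noise-free marker FPKM in inactive tumors and normals (below the 1-FPKM
#: stratification threshold).
MARKER_BASELINE_FPKM = 0.1


@dataclass
class SimParams:
    """Knobs of the latent-activity cohort generator.

    ``n_module`` counts all activity-driven genes: the ICPs, the planted
    candidates and ``n_module - len(icps) - len(planted_candidates)``
    additional induced genes.  The marker is extra and always present; it
    shares the module loading ``beta`` by default but sits on a fixed low
    baseline (0.1 FPKM noise-free in inactive tumors and normals), so that
    active tumors clear the 1-FPKM stratification threshold and inactive
    tumors stay below it whenever ``beta`` is non-null.  Sharing the loading
    also makes every noise-free raw-FPKM bin mean an affine function of the
    marker's, hence gradient correlations of exactly 1.
    """

    n_pairs: int = 40
    frac_active: float = 0.4          # typical IFNg-positive fraction in CRC cohorts
    activity_high: float = 1.0
    activity_low: float = 0.0
    n_module: int = 20
    n_null: int = 1000
    beta: float = 2.0                 # log2-scale loading of module genes
    beta_marker: float | None = None  # None -> same loading as the module
    mu_range: tuple[float, float] = (2.0, 7.0)  # log2 baseline of non-marker genes
    sigma: float = 0.5                # log2-scale noise s.d.
    pseudocount: float = 1.0
    icps: tuple[str, ...] = DEFAULT_ICPS
    planted_candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValidationError(f"n_pairs must be positive, got {self.n_pairs}")
        if not 0 < self.frac_active < 1:
            raise ValidationError(f"frac_active must be in (0, 1), got {self.frac_active}")
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_null < 0:
            raise ValidationError(f"n_null must be >= 0, got {self.n_null}")
        core = len(self.icps) + len(self.planted_candidates)
        if core == 0 or self.n_module < core:
            raise ValidationError(
                f"n_module ({self.n_module}) must cover the {core} ICP/candidate genes"
            )
        if self.mu_range[0] > self.mu_range[1]:
            raise ValidationError(f"mu_range must be (lo, hi), got {self.mu_range}")

    @property
    def resolved_beta_marker(self) -> float:
        return self.beta if self.beta_marker is None else self.beta_marker

    def module_gene_ids(self) -> list[str]:
        extra = self.n_module - len(self.icps) - len(self.planted_candidates)
        others = [f"MOD{i + 1:02d}" for i in range(extra)]
        return list(self.icps) + list(self.planted_candidates) + others

    def null_gene_ids(self) -> list[str]:
        return [f"NULL{i + 1:04d}" for i in range(self.n_null)]


@dataclass
class GroundTruth:
    """Everything downstream stages should recover."""

    marker_gene: str
    active_samples: frozenset[str]          # tumors with a_s = activity_high
    module_genes: frozenset[str]
    null_genes: frozenset[str]
    planted_candidates: frozenset[str]
    activity: dict[str, float]              # per-tumor latent activity
    true_fold: dict[str, float]             # noise-free active-stratum T/N fold
    gradient_bins: list[list[str]] = field(default_factory=list)  # high -> low
    gradient_levels: list[float] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        d = {
            "marker_gene": self.marker_gene,
            "active_samples": sorted(self.active_samples),
            "module_genes": sorted(self.module_genes),
            "null_genes": sorted(self.null_genes),
            "planted_candidates": sorted(self.planted_candidates),
            "activity": dict(sorted(self.activity.items())),
            "true_fold": dict(sorted(self.true_fold.items())),
            "gradient_bins": self.gradient_bins,
            "gradient_levels": self.gradient_levels,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


class SimulatedCohort(NamedTuple):
    matrix: ExpressionMatrix
    samples: SampleTable
    annotation: GeneAnnotation
    truth: GroundTruth


def _sample_ids(n_pairs: int) -> tuple[list[str], list[str], list[str]]:
    width = max(2, len(str(n_pairs)))
    tumors = [f"T{i + 1:0{width}d}" for i in range(n_pairs)]
    normals = [f"N{i + 1:0{width}d}" for i in range(n_pairs)]
    pair_ids = [f"P{i + 1:0{width}d}" for i in range(n_pairs)]
    return tumors, normals, pair_ids


def _simulate(params: SimParams, levels: np.ndarray, counts: np.ndarray) -> SimulatedCohort:
    """Shared generator core: tumors get activity levels by shuffled chunks.

    ``levels`` (descending) and ``counts`` define how many tumors sit at each
    activity level; the tumor-to-level assignment uses a single permutation
    draw so the two-level cohort and the two-bin gradient cohort coincide at
    equal seeds.
    """
    rng = np.random.default_rng(params.rng_seed)
    marker = MARKER_GENE
    module = params.module_gene_ids()
    nulls = params.null_gene_ids()
    genes = [marker] + module + nulls
    if len(set(genes)) != len(genes):
        raise ValidationError("gene ID collision between marker/module/null genes")

    tumors, normals, pair_ids = _sample_ids(params.n_pairs)
    samples = tumors + normals

    # draw 1: baselines
    mu_other = rng.uniform(params.mu_range[0], params.mu_range[1], size=len(genes) - 1)
    mu_marker = math.log2(MARKER_BASELINE_FPKM + params.pseudocount)
    mu = np.concatenate([[mu_marker], mu_other])

    # draw 2: tumor activity assignment
    perm = rng.permutation(params.n_pairs)
    activity_t = np.empty(params.n_pairs, dtype=float)
    start = 0
    bins: list[list[str]] = []
    for lvl, cnt in zip(levels, counts):
        idx = perm[start:start + int(cnt)]
        activity_t[idx] = lvl
        bins.append(sorted(tumors[i] for i in idx))
        start += int(cnt)
    a = np.concatenate([activity_t, np.zeros(params.n_pairs)])  # normals: a = 0

    beta_vec = np.zeros(len(genes))
    beta_vec[0] = params.resolved_beta_marker
    beta_vec[1:1 + len(module)] = params.beta

    # draw 3: noise
    eps = rng.normal(0.0, params.sigma, size=(len(genes), len(samples))) if params.sigma > 0 \
        else np.zeros((len(genes), len(samples)))

    log2x = mu[:, None] + beta_vec[:, None] * a[None, :] + eps
    fpkm = np.maximum(np.exp2(log2x) - params.pseudocount, 0.0)

    matrix = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=samples))
    sample_df = pd.DataFrame({
        "sample_id": samples,
        "patient_id": pair_ids + pair_ids,
        "tissue": ["tumor"] * params.n_pairs + ["normal"] * params.n_pairs,
        "pair_id": pair_ids + pair_ids,
        "stage_group": [""] * len(samples),
    })
    table = SampleTable(sample_df)

    roles = (["marker"]
             + ["icp"] * len(params.icps)
             + ["icprg_candidate"] * len(params.planted_candidates)
             + ["immune"] * (len(module) - len(params.icps) - len(params.planted_candidates))
             + ["other"] * len(nulls))
    annotation = GeneAnnotation(pd.DataFrame({"gene_id": genes, "role": roles}))

    high = levels[0]
    active = frozenset(t for t, lvl in zip(tumors, activity_t) if lvl == high)
    true_fold = {marker: float(2.0 ** (params.resolved_beta_marker * high))}
    for g in module:
        true_fold[g] = float(2.0 ** (params.beta * high))
    for g in nulls:
        true_fold[g] = 1.0
    truth = GroundTruth(
        marker_gene=marker,
        active_samples=active,
        module_genes=frozenset(module),
        null_genes=frozenset(nulls),
        planted_candidates=frozenset(params.planted_candidates),
        activity={t: float(lvl) for t, lvl in zip(tumors, activity_t)},
        true_fold=true_fold,
        gradient_bins=bins,
        gradient_levels=[float(l) for l in levels],
    )
    return SimulatedCohort(matrix, table, annotation, truth)


def simulate_cohort(params: SimParams) -> SimulatedCohort:
    """Two-level cohort: a ``frac_active`` share of tumors at ``activity_high``,
    the rest at ``activity_low``; all normals at zero activity."""
    n_active = int(round(params.frac_active * params.n_pairs))
    n_active = min(max(n_active, 1), params.n_pairs - 1)  # both strata non-empty
    levels = np.array([params.activity_high, params.activity_low])
    counts = np.array([n_active, params.n_pairs - n_active])
    return _simulate(params, levels, counts)


def simulate_gradient_cohort(params: SimParams, n_bins: int) -> SimulatedCohort:
    """Cohort whose tumors sit on ``n_bins`` evenly spaced activity levels.

    ``n_bins = 2`` reduces exactly to :func:`simulate_cohort` (same seed,
    same active/inactive partition, same matrix).  For more bins, tumors are
    split into near-equal chunks, highest activity first, so the noise-free
    per-bin marker mean decreases strictly from bin 1 down.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    if n_bins == 2:
        return simulate_cohort(params)
    if n_bins > params.n_pairs:
        raise ValidationError(f"n_bins ({n_bins}) exceeds n_pairs ({params.n_pairs})")
    levels = np.linspace(params.activity_high, params.activity_low, n_bins)
    base, extra = divmod(params.n_pairs, n_bins)
    counts = np.array([base + (1 if i < extra else 0) for i in range(n_bins)])
    return _simulate(params, levels, counts)
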