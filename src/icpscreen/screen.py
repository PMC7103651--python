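"""The dual-criterion candidate screen and the cross-condition set partition.

A gene is called an immune-checkpoint-related candidate when it satisfies
both published criteria: (1) it is co-expressed (cc strictly above ``tau``)
with at least one known checkpoint gene — any single partner suffices — and
(2) its tumor/normal fold change in the screening stratum is at least
``phi`` (inclusive: "a minimum 2-fold" admits exactly 2.0).  Known
checkpoint genes and the marker itself are never candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import StratumMismatchError, ValidationError
from .network import CoexpressionNetwork, connected_components

CANDIDATE_COLUMNS = ("gene_id", "partners", "best_partner", "best_cc",
                     "fold_change", "q_value", "passes")


def screen_icprg(net: CoexpressionNetwork, de: pd.DataFrame,
                 known_icps: Sequence[str], *, tau: float | None = None,
                 phi: float = 2.0, marker: str | None = None,
                 include_marker: bool = False,
                 require_marker_component: bool = False,
                 stratum: str | None = None) -> pd.DataFrame:
    """Screen network genes against the co-expression + fold-change criteria.

    ``de`` must be a single-stratum differential-expression table (from
    :func:`icpscreen.de.compute_de`); if ``stratum`` is given it must match
    the table's stratum.  Returns a CandidateTable DataFrame sorted by
    descending fold change among passing genes first.
    """
    known_icps = [str(g) for g in known_icps]
    if not known_icps:
        raise ValidationError("known_icps must be non-empty")
    if tau is None:
        tau = net.tau
    de_strata = set(de["stratum"].unique()) if len(de) else set()
    if len(de_strata) > 1:
        raise ValidationError(f"DE table mixes strata: {sorted(de_strata)}")
    if stratum is not None and de_strata and de_strata != {stratum}:
        raise StratumMismatchError(
            f"network/screen stratum {stratum!r} vs DE stratum {sorted(de_strata)[0]!r}"
        )
    partners_allowed = set(known_icps)
    if include_marker and marker is not None:
        partners_allowed.add(marker)
    excluded = set(known_icps) | ({marker} if marker is not None else set())

    fold = dict(zip(de["gene_id"], de["fold_change"]))
    qval = dict(zip(de["gene_id"], de["q_value"]))

    marker_comp: set[str] = set()
    if require_marker_component and marker is not None:
        for comp in connected_components(net):
            if marker in comp:
                marker_comp = comp
                break

    rows = []
    for gene in sorted(net.nodes - excluded):
        partner_ccs = []
        for p in partners_allowed:
            if net.graph.has_edge(gene, p):
                cc = float(net.graph[gene][p]["cc"])
                if cc > tau:
                    partner_ccs.append((p, cc))
        partner_ccs.sort(key=lambda t: (-t[1], t[0]))
        if gene not in fold:
            raise ValidationError(f"gene {gene!r} missing from the DE table")
        fc = float(fold[gene])
        passes = bool(partner_ccs) and fc >= phi
        if require_marker_component and passes:
            passes = gene in marker_comp
        rows.append({
            "gene_id": gene,
            "partners": ";".join(f"{p}:{cc:.4f}" for p, cc in partner_ccs),
            "best_partner": partner_ccs[0][0] if partner_ccs else "",
            "best_cc": partner_ccs[0][1] if partner_ccs else float("nan"),
            "fold_change": fc,
            "q_value": float(qval.get(gene, float("nan"))),
            "passes": passes,
        })
    out = pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))
    out = out.sort_values(["passes", "fold_change", "gene_id"],
                          ascending=[False, False, True],
                          kind="mergesort").reset_index(drop=True)
    out.attrs["tau"] = float(tau)
    out.attrs["phi"] = float(phi)
    return out


def passing_candidates(table: pd.DataFrame) -> list[str]:
    return list(table.loc[table["passes"], "gene_id"])


@dataclass
class ConditionSetPartition:
    """Exclusive membership partition of per-condition gene (node) sets."""

    conditions: list[str]
    #: frozenset of condition labels -> genes present in exactly those conditions
    exclusive: dict[frozenset[str], set[str]] = field(default_factory=dict)

    @property
    def unique(self) -> dict[str, set[str]]:
        """Genes found in one condition only (empty set if none)."""
        return {c: set(self.exclusive.get(frozenset([c]), set())) for c in self.conditions}

    def shared(self, *conditions: str) -> set[str]:
        """Genes found in exactly the given conditions and no others."""
        key = frozenset(conditions)
        unknown = key - set(self.conditions)
        if unknown:
            raise ValidationError(f"unknown conditions: {sorted(unknown)}")
        return set(self.exclusive.get(key, set()))

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.exclusive.values():
            out |= genes
        return out

    def counts(self) -> dict[str, int]:
        return {"+".join(sorted(k)): len(v) for k, v in sorted(
            self.exclusive.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))}


def partition_condition_genes(
        nets: Mapping[str, CoexpressionNetwork | Iterable[str]] |
              Iterable[tuple[str, CoexpressionNetwork | Iterable[str]]]
) -> ConditionSetPartition:
    """Split genes by the exact combination of conditions they appear in.

    Accepts a mapping or (label, network-or-gene-set) pairs; at least two
    conditions; duplicate labels are rejected.
    """
    items = list(nets.items()) if isinstance(nets, Mapping) else list(nets)
    labels = [l for l, _ in items]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate condition labels in {labels}")
    if len(items) < 2:
        raise ValidationError("need at least 2 conditions to partition")
    node_sets = {
        label: set(obj.nodes) if isinstance(obj, CoexpressionNetwork) else set(obj)
        for label, obj in items
    }
    part = ConditionSetPartition(conditions=labels)
    union = set().union(*node_sets.values())
    for gene in union:
        key = frozenset(l for l, s in node_sets.items() if gene in s)
        part.exclusive.setdefault(key, set()).add(gene)
    return part
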