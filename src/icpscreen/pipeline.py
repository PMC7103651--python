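"""End-to-end orchestration: stratify -> DE -> networks -> screen ->
set partition -> gene sets -> gradient, with a machine-readable run report.

Everything is deterministic given the config and inputs: artifacts are
written with stable ordering and no timestamps, so two identical runs
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._version import __version__
from .config import RunConfig
from .de import compute_de, landscape_filter
from .errors import IcpscreenError, ValidationError
from .genesets import geneset_table
from .gradient import gradient_profile, gradient_report
from .io import (ExpressionMatrix, GeneAnnotation, SampleTable,
                 write_network)
from .network import CoexpressionNetwork, build_network, connected_components, hub_genes
from .screen import partition_condition_genes, passing_candidates, screen_icprg
from .stratify import bin_gradients, stratify

CONDITION_POSITIVE = "tumors_positive"
CONDITION_NEGATIVE = "tumors_negative"
CONDITION_NORMALS = "normals"
CONDITION_ALL_TUMORS = "tumors_all"


@dataclass
class RunReport:
    """Summary of one pipeline run; every number is recomputable from the
    stage artifacts it summarizes."""

    config: dict
    version: str
    rng_seed: int
    stages: dict = field(default_factory=dict)
    incomplete: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()).hexdigest()[:16],
            "version": self.version,
            "rng_seed": self.rng_seed,
            "stages": self.stages,
            "incomplete": self.incomplete,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


def _net_summary(net: CoexpressionNetwork, hub_degree: int) -> dict:
    comps = connected_components(net)
    return {
        "condition": net.condition,
        "n_nodes": len(net.nodes),
        "n_edges": net.n_edges,
        "n_components": len(comps),
        "largest_component": len(comps[0]) if comps else 0,
        "hubs": sorted(hub_genes(net, hub_degree)),
    }


def run_pipeline(config: RunConfig, matrix: ExpressionMatrix,
                 samples: SampleTable, annotation: GeneAnnotation,
                 genesets: Mapping[str, Sequence[str]] | None = None,
                 outdir: str | None = None) -> RunReport:
    """Execute the full screen on one cohort.

    Stages that cannot run (e.g. a stratum with fewer than 3 pairs) are
    recorded in ``report.incomplete`` instead of aborting the run.
    """
    config.validate()
    samples.check_against(matrix)
    marker = annotation.marker_gene
    icps = annotation.icp_genes
    if marker not in matrix:
        raise ValidationError(f"marker gene {marker!r} absent from matrix")

    report = RunReport(config=config.to_dict(), version=__version__,
                       rng_seed=config.rng_seed)
    artifacts: dict[str, pd.DataFrame] = {}
    networks: dict[str, CoexpressionNetwork] = {}

    # --- stratification -----------------------------------------------------
    strata = stratify(matrix, samples, marker, config.theta_marker)
    binning = bin_gradients(matrix, samples, marker, config.gradient_edges)
    bin_of = {}
    for i, members in enumerate(binning.members_per_bin()):
        for s in members:
            bin_of[s] = i + 1
    strat_df = pd.DataFrame({
        "sample_id": samples.tumor_samples,
        "stratum": [strata.labels[t] for t in samples.tumor_samples],
        "gradient_bin": [bin_of.get(t, 0) for t in samples.tumor_samples],
    })
    artifacts["stratum.tsv"] = strat_df
    report.stages["stratification"] = {
        "marker": marker,
        "theta": config.theta_marker,
        "n_positive": len(strata.positive),
        "n_negative": len(strata.negative),
        "bin_sizes": [len(m) for m in binning.members_per_bin()],
    }

    # --- differential expression -------------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    for label, members in (("positive", strata.positive),
                           ("negative", strata.negative),
                           ("all", samples.tumor_samples)):
        if len(members) < 3:
            report.incomplete.append(f"de_{label}: only {len(members)} pairs")
            continue
        de = compute_de(matrix, samples, members, label, config.pseudocount)
        de_tables[label] = de
        artifacts[f"de_{label}.tsv"] = de
    if "all" in de_tables:
        landscape = landscape_filter(matrix, samples, de_tables["all"],
                                     config.universe_min_fpkm, config.alpha_fdr)
        report.stages["landscape"] = {k: len(v) for k, v in landscape.items()}
    report.stages["de"] = {
        label: {
            "n_genes": len(t),
            "n_q_lt_alpha": int((t["q_value"] < config.alpha_fdr).sum()),
        } for label, t in de_tables.items()
    }

    # --- co-expression networks --------------------------------------------
    seeds = [marker] + icps
    conditions = {
        CONDITION_POSITIVE: strata.positive,
        CONDITION_NEGATIVE: strata.negative,
        CONDITION_NORMALS: samples.normal_samples,
        CONDITION_ALL_TUMORS: samples.tumor_samples,
    }
    for cond, members in conditions.items():
        if len(members) < 3:
            report.incomplete.append(f"network_{cond}: only {len(members)} samples")
            continue
        networks[cond] = build_network(
            matrix, members, seeds, tau=config.tau_cc,
            universe_min_fpkm=config.universe_min_fpkm,
            pseudocount=config.pseudocount, log_scale=config.log_transform,
            condition=cond)
    report.stages["networks"] = {
        cond: _net_summary(net, config.hub_degree) for cond, net in networks.items()
    }

    # --- candidate screen ---------------------------------------------------
    screen_cond = (CONDITION_ALL_TUMORS if config.screen_condition == "all_tumors"
                   else CONDITION_POSITIVE)
    if screen_cond in networks and "positive" in de_tables:
        candidates = screen_icprg(
            networks[screen_cond], de_tables["positive"], icps,
            tau=config.tau_cc, phi=config.phi_fold, marker=marker,
            include_marker=config.screen_include_marker,
            require_marker_component=config.screen_require_component,
            stratum="positive")
        artifacts["candidates.tsv"] = candidates
        report.stages["screen"] = {
            "condition": screen_cond,
            "n_screened": len(candidates),
            "n_passing": int(candidates["passes"].sum()),
            "passing": passing_candidates(candidates),
        }
    else:
        report.incomplete.append("screen: missing network or positive-stratum DE")

    # --- cross-condition partition -----------------------------------------
    part_conditions = [c for c in (CONDITION_POSITIVE, CONDITION_NEGATIVE,
                                   CONDITION_NORMALS) if c in networks]
    if len(part_conditions) >= 2:
        partition = partition_condition_genes(
            {c: networks[c] for c in part_conditions})
        report.stages["partition"] = {
            "counts": partition.counts(),
            "unique": {c: sorted(g) for c, g in partition.unique.items()},
        }
    else:
        report.incomplete.append("partition: fewer than 2 condition networks")

    # --- gene sets ----------------------------------------------------------
    if genesets:
        if strata.positive and strata.negative:
            gs = geneset_table(matrix, strata, dict(genesets), config.pseudocount)
            artifacts["genesets.tsv"] = gs
            report.stages["genesets"] = {
                row["set_name"]: {"fold": row["fold"], "p_value": row["p_value"]}
                for _, row in gs.iterrows()
            }
        else:
            report.incomplete.append("genesets: a stratum is empty")

    # --- gradient dose-response ---------------------------------------------
    panel = [marker] + icps + annotation.candidate_genes
    usable_bins = sum(1 for m in binning.members_per_bin() if m)
    if usable_bins >= 3:
        profiles = gradient_report(
            gradient_profile(matrix, binning, marker, panel),
            config.gradient_cc_floor)
        artifacts["gradient.tsv"] = profiles
        report.stages["gradient"] = {
            "n_per_bin": profiles.attrs["n_per_bin"],
            "cc_floor": config.gradient_cc_floor,
            "passing": sorted(profiles.loc[profiles["passes"], "gene_id"]),
        }
    else:
        report.incomplete.append(f"gradient: only {usable_bins} non-empty bins")

    # --- artifacts ----------------------------------------------------------
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        config.to_yaml(os.path.join(outdir, "config.yaml"))
        for name, df in artifacts.items():
            df.to_csv(os.path.join(outdir, name), sep="\t", index=False)
        for cond, net in networks.items():
            write_network(net, os.path.join(outdir, f"network_{cond}.edges.tsv"),
                          "edge-list")
            write_network(net, os.path.join(outdir, f"network_{cond}.graphml"),
                          "graphml")
        report.write(os.path.join(outdir, "report.json"))
    return report
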