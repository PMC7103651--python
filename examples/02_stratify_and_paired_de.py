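"""Stratify tumors by marker expression and run paired differential
expression within the positive stratum.

Tumors with marker FPKM > 1 form the positive stratum.  For each gene the
fold change is the ratio of pseudocounted stratum means (tumor over matched
normal) and the p-value comes from a two-sided paired t test on
log2(FPKM + 1); q-values are Benjamini-Hochberg.  Induced module genes
should show folds near 4 (2**beta) at tiny q; background genes should not.
"""

import icpscreen as ic

matrix, samples, annotation, truth = ic.simulate_cohort(
    ic.SimParams(rng_seed=1))

strata = ic.stratify(matrix, samples, annotation.marker_gene, theta=1.0)
print(f"{len(strata.positive)} positive / {len(strata.negative)} negative tumors "
      f"(truth: {len(truth.active_samples)} active)")

de = ic.compute_de(matrix, samples, strata.positive, "positive")
show = de.set_index("gene_id").loc[
    [annotation.marker_gene, "IDO1", "GBP1", "NULL0001"],
    ["fold_change", "p_value", "q_value"]]
print(show.round(4))

landscape = ic.landscape_filter(matrix, samples,
                                ic.compute_de(matrix, samples,
                                              samples.tumor_samples, "all"))
print({k: len(v) for k, v in landscape.items()},
      "<- expressed-and-DE / expressed-not-DE / low gene counts")
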