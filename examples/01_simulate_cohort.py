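"""Generate a synthetic paired tumor/normal cohort with planted structure.

A latent IFNγ-activity factor drives a 20-gene module (the marker IFNG,
six checkpoint genes, three planted candidate genes and eleven other
induced genes) on top of 1000 uncorrelated background genes.  The printed
fold changes are the noise-free tumor/normal ratios the generator plants
for active tumors; everything downstream tries to recover them.
"""

import icpscreen as ic

params = ic.SimParams(n_pairs=40, n_module=20, n_null=1000,
                      beta=2.0, sigma=0.5, rng_seed=1)
matrix, samples, annotation, truth = ic.simulate_cohort(params)

print(f"cohort: {matrix.shape[0]} genes x {matrix.shape[1]} samples "
      f"({samples.n_pairs} tumor/normal pairs)")
print(f"active tumors (high latent activity): {len(truth.active_samples)} of "
      f"{len(samples.tumor_samples)}")
print(f"marker gene: {truth.marker_gene}; "
      f"checkpoint genes: {', '.join(annotation.icp_genes)}")
print(f"planted candidates: {', '.join(sorted(truth.planted_candidates))}")
print(f"planted fold change of a module gene in active tumors: "
      f"{truth.true_fold['GBP1']:.1f} (= 2**beta)")
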