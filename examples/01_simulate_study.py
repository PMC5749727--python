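"""Generate a synthetic two-cohort GWAS with a planted network module.

The generator produces everything the pipeline consumes: a scale-free
interaction network, gene models on a synthetic chromosome, per-gene
expression summaries, and discovery/validation summary statistics in which
only the SNPs of a connected 'planted' gene set carry true effects.
"""
import gwasmodules as gm

study = gm.simulate_study(seed=42, n_genes=500, planted_size=15, n_intergenic=300)

n_causal = len(study.truth.causal_snps)
print(f"network: {study.network.number_of_nodes()} genes, "
      f"{study.network.number_of_edges()} interactions")
print(f"planted module: {len(study.planted)} connected genes, "
      f"{n_causal} causal SNPs, per-allele effect {study.truth.true_effect:.3f} SD")
print(f"SNPs simulated: {len(study.discovery)} "
      f"(discovery n={study.truth.n_discovery}, validation n={study.truth.n_validation})")

causal = set(study.truth.causal_snps.values())
med_p = sorted(study.discovery[s].pvalue for s in causal)[n_causal // 2]
print(f"median causal discovery p: {med_p:.2e}  "
      "(the signal strength the search has to find)")
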