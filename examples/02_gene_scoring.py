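"""Score genes by the minimum SNP p-value in a strand-aware window.

Each gene's window spans 110 kb upstream to 40 kb downstream of its
transcribed span; the gene inherits the smallest p-value among mapped SNPs
and a z-score z_i = Phi^-1(1 - p_i).
"""
import gwasmodules as gm

study = gm.simulate_study(seed=42, n_genes=500, planted_size=15, n_intergenic=300)

assignment = gm.assign_snps_to_genes(study.discovery, study.gene_models)
scores = gm.score_genes(assignment, study.discovery)

n_mapped = sum(len(s) for s in assignment.values())
print(f"{n_mapped} SNP-gene mappings over {len(assignment)} genes "
      f"(SNPs outside every window are excluded)")

best = sorted(scores.values(), key=lambda s: s.p_i)[:5]
print("top scoring genes (min-p rule):")
for s in best:
    flag = "planted" if s.gene_id in study.planted else ""
    print(f"  {s.gene_id}  p={s.p_i:.2e}  z={s.z_i:.2f}  via {s.best_snp}  {flag}")
print("a z above ~4.5 is far beyond what the per-gene min-p selection bias "
      "alone produces here")
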