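"""Meta-analysis, summary-statistic polygenic scores, LD pruning and
regulatory overlap on the two synthetic cohorts."""
import gwasmodules as gm

study = gm.simulate_study(seed=42, n_genes=500, planted_size=15, n_intergenic=300)

# inverse-variance fixed-effect meta-analysis with double genomic control
meta = gm.fixed_effect_meta([study.discovery, study.validation], double_gc=True)
causal = set(study.truth.causal_snps.values())
any_meta = next(iter(meta.values()))
best = min((meta[s] for s in causal), key=lambda r: r.p_meta)
print(f"meta-analysis of {len(meta)} SNPs; "
      f"lambdas {any_meta.lambda_by_study}, lambda_meta={any_meta.lambda_meta:.3f}")
print(f"strongest causal SNP after meta: {best.snp_id} "
      f"beta={best.beta_meta:.3f} p={best.p_meta:.2e}")

# PRS from discovery weights, tested in the validation cohort
top_snps = sorted(causal, key=lambda s: study.discovery[s].pvalue)[:10]
weights = {s: abs(study.discovery[s].beta) for s in top_snps}
target = {
    s: rec if study.discovery[s].beta >= 0 else gm.align_alleles(
        study.discovery[s], rec)
    for s, rec in ((s, study.validation[s]) for s in top_snps)
}
prs = gm.prs_association(weights, target)
print(f"PRS association: alpha={prs.alpha_hat:.3f} (se {prs.se_alpha:.3f}, "
      f"p={prs.p:.2e}, {prs.n_snps} SNPs) — per unit of weighted allele score")

# LD pruning (synthetic r2 block) and regulatory-element overlap
ld = {frozenset((top_snps[0], top_snps[1])): 0.95}
pruned = gm.ld_prune(top_snps, ld, threshold=0.8,
                     pvalues={s: study.discovery[s].pvalue for s in top_snps})
print(f"LD pruning at r2 < 0.8: {len(top_snps)} -> {len(pruned)} SNPs")

snp0 = top_snps[0]
pos = study.discovery[snp0].pos
elements = [("chr1", pos - 100, pos + 100, "active_enhancer")]
snps = {snp0: ("chr1", pos)}
table = gm.regulatory_overlap(snps, {}, elements)
print(f"regulatory overlap for {snp0}: "
      f"active_enhancer={bool(table.loc[snp0, 'active_enhancer'])}")
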