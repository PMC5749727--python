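# gwasmodules

Network-based discovery and replication of association signal in GWAS
summary statistics.

Single-SNP tests in a modestly sized GWAS of a deeply phenotyped trait —
for example insulin secretion measured under a hyperglycemic clamp —
rarely clear genome-wide significance. If the trait's biology runs through
a protein complex or pathway, however, the *joint* signal of many
sub-threshold SNPs hitting interacting genes can be detectable.
`gwasmodules` implements that strategy end to end for people working with
summary statistics only (no genotypes required):

1. **Gene scoring** — each gene gets the minimum p-value among SNPs in a
   strand-aware window (default 110 kb upstream to 40 kb downstream of the
   transcribed span, covering the bulk of cis-eQTLs), transformed to
   `z_i = Φ⁻¹(1 − p_i)`.
2. **Tissue-specific network** — a global protein–protein interaction
   network is pruned to genes expressed in the target tissue
   (25th-percentile RPKM ≥ 1), sparing an explicit keep-list of lineage
   transcription factors.
3. **Active-module search** — connected modules maximizing the aggregate
   score `z_A = Σᵢ zᵢ / √k` are grown greedily from the top-scoring seed
   nodes; `z_A` is standardized against Monte-Carlo random gene sets of
   matching size, `s_A = (z_A − μ_k)/σ_k`, and the whole search is re-run
   on permuted gene scores to provide an honest selection-aware null.
4. **Consensus network** — the (typically large) top module is searched
   again from every internal seed; genes recurring among the top
   second-order modules form a compact consensus, each carrying its best
   ("driving") SNP.
5. **Replication** — the consensus SNPs with discovery p < 5×10⁻⁴ are
   tested in an independent cohort: a combined z-score `Σzⱼ/√m` against an
   empirical null of random same-size SNP sets from the network, an exact
   binomial sign test of directional consistency, inverse-variance
   fixed-effect meta-analysis with double genomic control, and a
   summary-statistic polygenic-score association, plus LD pruning and
   regulatory-element overlap utilities.

A synthetic-data module generates complete two-cohort studies with a
planted, connected signal module, so every stage is testable without any
external data.

## Worked example

```python
import gwasmodules as gm

study = gm.simulate_study(seed=42, n_genes=500, planted_size=15, n_intergenic=300)
cfg = gm.RunConfig(n_calibration=5000, n_empirical=10_000, max_module_size=100,
                   rng_seed=42)
res = gm.run_discovery(study.discovery, study.gene_models, study.network,
                       study.expression, study.keep_list, cfg)
rep = gm.run_replication(res, study.discovery, study.validation, cfg)
top = res.modules[0]
print(top.k, round(top.z_A, 2), round(top.s_A, 2))
print(len(study.planted & top.nodes), len(res.consensus.genes))
print(round(rep.combined_z, 2), rep.empirical.empirical_p, rep.n_consistent, rep.n_total)
```

prints

```
16 16.49 12.76
12 14
12.44 9.999000099990002e-05 11 11
```

The top module holds 16 genes with raw aggregate score `z_A = 16.49`
(calibrated `s_A = 12.76`) and contains 12 of the 15 planted genes; the
distilled consensus has 14 genes. In the validation cohort the 11
consensus SNPs passing the discovery threshold reach a combined z of
12.44 — higher than every one of 10,000 random same-size SNP sets
(empirical p ≈ 1×10⁻⁴) — and all 11 effects point the same way as in
discovery. On null data (no planted effects) the same pipeline leaves the
combined z unremarkable and the empirical p uniform.

The `examples/` directory has one short narrative script per capability;
each builds a small input, runs the method and explains the printed
numbers. A thin CLI mirrors the library
(`gwasmodules simulate | score-genes | prune-network | find-modules |
consensus | replicate | meta | prs | overlap`); see `gwasmodules --help`.

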