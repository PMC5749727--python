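"""Find active network modules with Monte-Carlo calibrated greedy search.

A module's raw score z_A = sum(z_i)/sqrt(k) is standardized against random
gene sets of the same size, s_A = (z_A - mu_k)/sigma_k. Because the greedy
search maximizes over many seeds and sizes, the honest null reference for
the final top score is a rerun on permuted gene scores.
"""
import gwasmodules as gm

study = gm.simulate_study(seed=42, n_genes=500, planted_size=15, n_intergenic=300)
cfg = gm.RunConfig(n_calibration=5000, max_module_size=100, rng_seed=42)
res = gm.run_discovery(study.discovery, study.gene_models, study.network,
                       study.expression, study.keep_list, cfg)

top = res.modules[0]
overlap = len(study.planted & top.nodes)
print(f"top module: {top.k} genes, raw z_A={top.z_A:.2f}, calibrated s_A={top.s_A:.2f}")
print(f"planted-gene recovery: {overlap}/{len(study.planted)} in the top module")

ref = gm.permutation_reference(res.pruned_network, res.gene_scores, res.calibration,
                               n_perm=5, seed=43, max_size=cfg.max_module_size)
print(f"permuted-score reference: observed top {ref.observed_top:.2f} vs "
      f"permuted mean {ref.permuted_mean:.2f} "
      f"(95% band {ref.band95[0]:.2f}-{ref.band95[1]:.2f})")
print("the gap between observed and permuted tops — not s_A alone — "
      "is the evidence that signal is concentrated in the network")
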