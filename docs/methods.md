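# Methods

## Model and procedure

`gwasmodules` looks for *active modules*: connected subgraphs of a
tissue-specific protein–protein interaction (PPI) network whose member
genes jointly carry unusually strong GWAS association signal.

**Gene significance.** A SNP belongs to a gene if it falls in the gene's
scoring window — `window_up` (default 110,000 bp) upstream and
`window_down` (default 40,000 bp) downstream of the transcribed span, both
boundaries inclusive. The asymmetric window reflects where cis-regulatory
variation concentrates relative to transcription. Upstream/downstream are
interpreted relative to strand; the field's annotation sources are
ambiguous on this point, so unstranded records default to `+` and the
choice is isolated in `gene_window`. A gene's score is the minimum p-value
over its mapped SNPs (ties broken by lexicographic SNP id; SNPs mapping to
no window are discarded), transformed to `z_i = Φ⁻¹(1 − p_i)`. p-values
are clamped to `[eps, 1 − eps]` (`p_clamp_eps`, default 1e-12) so z stays
finite; the transform is evaluated in whichever normal tail is accurate.
Min-p scoring is deliberately LD-naive — no effective-number-of-tests
correction — because the downstream calibration is computed on the same
scores and absorbs the selection bias that is uniform across genes.

**Tissue network.** Starting from a global undirected simple interaction
graph, genes whose 25th-percentile RPKM across expression samples is below
`rpkm_threshold` (default 1.0) are removed, as are genes absent from the
expression table: absence of evidence counts against a gene when the goal
is a tissue-credible network. An explicit keep-list overrides removal —
the motivating case is lineage transcription factors whose transcripts are
low-abundance yet functionally decisive. Surviving isolated nodes are kept
by default (they can seed the search); `drop_isolated=True` removes them.

**Module scoring and calibration.** A module A with k member genes scores
`z_A = Σ_{i∈A} z_i / √k`; genes without a mapped SNP contribute the
null-neutral z = 0 and never seed the search, but may be absorbed when
they bridge high-scoring genes. Because z_A drifts with k even under the
null (the scores are not mean-zero after min-p selection), raw scores are
standardized against Monte-Carlo samples: for each k up to
`max_module_size` (default 300), `n_calibration` uniform k-subsets of the
scored node set give `μ_k` and `σ_k`, and `s_A = (z_A − μ_k)/σ_k`. Random
subsets are *not* required to be connected — the reference question is
"how large is z_A for an arbitrary same-size gene set". Draws are nested
permutation prefixes (each sample is the first `max_k` entries of a random
node permutation), so one pass serves every k; per fixed k the subset is
exactly uniform, and moments across k share draws, which only reduces
Monte-Carlo cost, not correctness. `σ_k` is floored at 1e-6 to keep
degenerate fixtures (constant scores) finite. `n_calibration` defaults to
100,000; the test suite and the acceptance script run 10,000, which puts
≈1% Monte-Carlo error on `μ_k` — negligible against the effects measured.

**Greedy search.** From each of the `n_seeds` (default 100) highest-z
scored nodes, the module grows one node at a time: among the current
frontier (neighbors of the module), the candidate maximizing the
calibrated score is added. At a fixed target size that candidate is simply
the highest-z frontier node, since `μ_{k+1}` and `σ_{k+1}` do not depend
on the choice — the implementation exploits this for an O(E) expansion
with ties broken by lexicographic node id. Growth stops at the first
non-improving addition, at `max_module_size`, or when the frontier
empties. There is no node removal and no simulated annealing: pure greedy
expansion keeps the procedure deterministic given the scores. Identical
node sets from different seeds are deduplicated; modules are ranked by
`s_A` (then raw `z_A`, then node set, for a total order).

**What s_A does and does not mean.** The size calibration answers "is this
set better than a random set of the same size" — it does not correct for
having greedily *searched* for the best set. Under a global null the top
seed alone is the maximum of thousands of gene scores, ~3σ above the mean,
and greedy growth compounds this: measured over 20 null studies of 800
genes, the top `s_A` lies between 8 and 15. A fixed threshold on `s_A`
(e.g. the folklore "score > 3") is therefore meaningless for the *top*
module of a search. The honest null is `permutation_reference`: the whole
search is rerun on gene scores shuffled across nodes (topology fixed, score
multiset unchanged — the calibration table still applies), and the observed
top is compared with the permuted tops (reported with a mean ± 1.96·SEM
band over `n_score_permutations`, default 10, reruns). Under a planted
signal the observed top clears every permuted top by a wide margin; under
the null it sits inside the band.

**Second-order search and consensus.** The top module is usually too large
to interpret, so the search is rerun inside its induced subgraph (seeds:
the top `n_seeds` scorers within). Genes appearing in at least
`min_occurrence` (default 2) of the top `n_second_order_modules` (default
15) second-order modules form the consensus network, annotated with
induced edges and each gene's best SNP. Two design points were genuinely
open:

* *Calibration universe.* The pipeline reuses the first-order calibration
  table rather than recomputing `μ_k, σ_k` on the top module's own node
  set. Recalibrating on an already-selected high-scoring module re-centers
  the null on the module itself; the greedy then stalls after the few
  above-local-average genes and the consensus degenerates to a small
  fragment (~40% of a planted module in simulation, versus 70–85% when the
  first-order reference is kept). Local recalibration remains available
  (`calibration=None`).
* *Degenerate unanimity.* Deduplication means "appeared more than once"
  can be unsatisfiable when every seed converges to the same set; the
  occurrence threshold is capped at the number of distinct modules
  counted, so a unanimous single module yields itself rather than an empty
  consensus.
* *Ranking.* Second-order modules are ranked by calibrated score, like
  first-order ones.

**Replication.** The consensus genes' driving SNPs with discovery
p < `snp_selection_p` (default 5e-4, strict inequality) are tested in an
independent cohort. The combined z is `Σ z_j/√m` over the m SNPs present
in the validation table (z from the *two-sided* validation p, so the
statistic is direction-agnostic; direction is tested separately). Its null
is empirical: `n_empirical` (default 100,000) random m-subsets of the pool
formed by the best SNP of every scored gene in the pruned network — the
same SNPs the gene-scoring step singled out — with
`p = (r + 1)/(N + 1)`, which can never be zero. Subsets are drawn without
replacement within a draw and independently across draws. Directional
consistency counts sign agreement of discovery and validation effects
after orienting alleles (swap flips the sign; strand complement does not;
A/T and C/G palindromic SNPs are retained with a logged ambiguity warning
rather than dropped), and is tested with the one-sided exact binomial
upper tail at success probability 1/2 — one-sided because the alternative
of interest is *excess* consistency; 14 consistent of 28 gives p = 0.57.

**Meta-analysis and PRS.** Fixed-effect inverse-variance meta-analysis
combines ≥2 cohorts after allele alignment; with `double_gc`, each
study's SEs are pre-inflated by `√max(λ_study, 1)` (λ = median association
χ² / 0.4549, computed from that study's full p-value vector), and the meta
χ² statistics are post-deflated by `max(λ_meta, 1)` with the meta SE
inflated correspondingly, so `beta/se` and p stay consistent. Genomic
control is applied only when λ > 1, the standard convention. The
polygenic-score association uses the summary-statistic approximation
`α̂ = Σ wᵢbᵢ/sᵢ² ÷ Σ wᵢ²/sᵢ²`, `se(α̂) = (Σ wᵢ²/sᵢ²)^{-1/2}` with weights
taken from discovery effect sizes in effect-raising orientation; it is
exactly invariant to jointly flipping any SNP's orientation in weights and
target. Greedy LD pruning walks SNPs in ascending p and keeps a SNP iff
its r² with every kept SNP is below `ld_r2_prune` (default 0.8; absent
pairs count as 0). Regulatory overlap expands each index SNP with proxies
at r² > `ld_r2_proxy` (default 0.8, strict) and intersects the locus
positions with half-open BED intervals per element class.

## Synthetic data: what it emulates, what it does not

`simulate_study` builds the statistical structure the method assumes: a
scale-free network (preferential attachment, mean degree ~6) over 2,000
genes; a 30-gene planted module grown by BFS from a *uniformly random*
node (not a hub, which would be trivially easy to recover); gene bodies of
5–50 kb placed sequentially on a synthetic chromosome with gaps exceeding
one window span; 5 SNPs per gene uniform in the gene's window plus 2,000
intergenic SNPs outside every window; one causal SNP per planted gene.
Effect estimates follow standard GWAS asymptotics: allele frequency
f ~ U(0.05, 0.5) (every SNP clears the usual MAF ≥ 5% filter),
`se = 1/√(2f(1−f)n)` per cohort, `β̂ ~ N(β·1[causal], se)`, two-sided
normal p. Discovery n = 1,500 and validation n = 1,000; both cohorts share
the true effect and differ only in noise, matching a two-cohort
replication design. The default true effect (≈0.18 phenotype SD) is sized
so a causal SNP's median discovery p is 1e-5 — strong enough to
concentrate signal, far below genome-wide significance. 15% of non-planted
genes are lowly expressed (rpkm_q25 ~ U(0,1)); planted genes always
express ≥ 1, and a 10-gene keep-list is forced below threshold to exercise
the keep-list contract. Fixing the seed fixes every output byte.

Deliberately absent: LD between SNPs (each SNP independent — so the
pipeline's LD utilities are exercised on supplied r² tables, not emergent
structure), population stratification, relatedness, genotyping error and
imputation uncertainty. Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness to
those real-data complications.

## Problem sizes used by the test suite and acceptance script

Planted-module recovery runs the full default study (2,000 genes) over 10
seeds with 10,000 calibration samples; null calibration uses 800-gene null
studies (50 in the test, 20 in the acceptance script) with 4,000
calibration samples and `max_module_size` 150; the empirical-p uniformity
check uses 200 repetitions of 499 draws; estimator-recovery runs 500
(meta) and 1,500 (PRS) replicates. These sizes keep per-quantity
Monte-Carlo error well below the decision margins being tested.

## Numerical choices and degenerate inputs

* Ties everywhere (min-p SNP, greedy candidate, module ranking) break
  lexicographically, making every output deterministic given a seed.
* `σ_k` floor 1e-6; p-value clamp 1e-12; simulated p floored at 5e-324 to
  avoid exact zeros from extreme draws.
* Duplicate SNP ids on load are an error, not last-wins: silent summary-
  statistic merges are the main corruption risk this I/O layer guards
  against. Rows violating record invariants are dropped with a logged
  reason.
* Internal coordinates are 1-based inclusive everywhere; BED converts at
  the file boundary, and the conversion is its own inverse.
* Empty scored sets, empty pools, single-study meta, `m = 0` combined z
  and an all-removed network raise immediately rather than degrade.

## Known limitations

* The greedy search is a heuristic: it can undershoot the optimal
  connected subgraph (verified ≤ exhaustive optimum on small graphs) and
  its top score needs the permutation reference for inference (above).
* Min-p gene scoring favors long genes and dense SNP coverage; no
  gene-length or LD correction is applied.
* The combined z treats validation evidence as direction-agnostic; a
  directionally signed variant would be more powerful when discovery signs
  are trustworthy, and the sign test covers that axis separately.
* The expression gate is a hard threshold on one summary quantile;
  borderline genes live or die by it, which is why the keep-list exists.
* Palindromic SNPs are aligned on the direct-match interpretation; with
  allele frequencies near 0.5 this can silently flip direction, and such
  SNPs are flagged in the log.
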