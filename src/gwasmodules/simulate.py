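"""Synthetic two-cohort GWAS with a planted network module.

The generator emulates the statistical structure the pipeline assumes: a
scale-free protein-interaction network in which a connected subset of genes
("the planted module") harbours true association signal, two cohorts of
summary statistics with independent noise but a shared true effect, an
expression table that lets the planted genes survive tissue pruning, and
gene models laid out on a synthetic chromosome so every causal SNP falls in
its gene's scoring window.

Noise model: standard GWAS asymptotics. For a SNP with effect-allele
frequency f in a cohort of n individuals, the standard error of the
per-allele effect (phenotype in SD units) is 1 / sqrt(2 f (1 - f) n); the
estimated effect is Normal(true_effect * I[causal], se) and the p-value the
two-sided normal tail. SNPs are simulated independently (no LD), and
frequencies are drawn from Uniform(0.05, 0.5) so every SNP clears the usual
MAF >= 5% inclusion threshold.
"""
from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .exceptions import SimulationError
from .types import ExpressionSummary, GeneModel, SimulationTruth, SnpAssoc

__all__ = [
    "simulate_network", "simulate_gene_models_and_snps", "simulate_summary_stats",
    "simulate_expression", "effect_for_median_p", "simulate_study", "SimulatedStudy",
]

_BASES = ("A", "C", "G", "T")


def simulate_network(
    n_genes: int,
    mean_degree: float,
    planted_size: int,
    seed: int,
) -> Tuple[nx.Graph, Set[str]]:
    """Scale-free-like random network with a connected planted gene set.

    Genes are labelled G0000, G0001, ... The planted set is grown by
    breadth-first traversal from a uniformly random node — not from a hub —
    so recovering it is not trivially easy.
    """
    if planted_size > n_genes:
        raise ValueError("planted_size must not exceed n_genes")
    if mean_degree < 2:
        raise ValueError("mean_degree must be at least 2")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(mean_degree / 2)))
    graph = nx.barabasi_albert_graph(n_genes, m, seed=int(rng.integers(2**31)))
    width = max(4, len(str(n_genes - 1)))
    mapping = {i: f"G{i:0{width}d}" for i in graph.nodes}
    graph = nx.relabel_nodes(graph, mapping)
    graph.graph["provenance"] = "global"

    start = mapping[int(rng.integers(n_genes))]
    planted: List[str] = []
    seen = {start}
    queue = [start]
    while queue and len(planted) < planted_size:
        node = queue.pop(0)
        planted.append(node)
        neighbors = [str(n) for n in rng.permutation(sorted(graph.adj[node]))]
        for nb in neighbors:
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    if len(planted) < planted_size:
        raise SimulationError(
            f"could not grow a connected planted set of {planted_size} nodes "
            f"from {start} (component too small)"
        )
    return graph, set(planted)


def simulate_gene_models_and_snps(
    genes: Sequence[str],
    genome_length: int,
    snps_per_gene: int,
    seed: int,
    n_intergenic: int = 0,
    window_up: int = 110_000,
    window_down: int = 40_000,
    gene_length_range: Tuple[int, int] = (5_000, 50_000),
    min_gap: Optional[int] = None,
) -> Tuple[Dict[str, GeneModel], Dict[str, Tuple[str, int, Optional[str]]]]:
    """Place genes sequentially on one synthetic chromosome and drop SNPs.

    Each gene receives ``snps_per_gene`` SNPs uniform in its strand-aware
    scoring window, plus a pool of ``n_intergenic`` SNPs outside every
    window. Gaps between consecutive gene bodies exceed one window span, so
    bodies never overlap; the windows of close neighbors can still touch,
    and a SNP near a gene boundary may then map to both genes — as happens
    with real annotations.

    Returns (gene models, SNP position table mapping snp_id ->
    (chrom, pos, gene_id-or-None)).
    """
    rng = np.random.default_rng(seed)
    span = window_up + window_down
    if min_gap is None:
        min_gap = span + 10_000  # bodies well separated; windows may abut

    models: Dict[str, GeneModel] = {}
    snp_table: Dict[str, Tuple[str, int, Optional[str]]] = {}
    chrom = "chr1"
    cursor = window_up + 1  # leave room for the first upstream window
    snp_idx = 0
    gene_windows = []
    for gene_id in genes:
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        start = cursor
        end = start + length - 1
        if end + window_up > genome_length:
            raise SimulationError(
                f"genome_length {genome_length} too small to place {len(genes)} genes"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        models[gene_id] = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand, tx_start=start, tx_end=end
        )
        if strand == "+":
            w_lo, w_hi = start - window_up, end + window_down
        else:
            w_lo, w_hi = start - window_down, end + window_up
        gene_windows.append((w_lo, w_hi))
        for pos in rng.integers(w_lo, w_hi + 1, size=snps_per_gene):
            snp_table[f"rs{snp_idx}"] = (chrom, int(pos), gene_id)
            snp_idx += 1
        cursor = end + min_gap + int(rng.integers(0, 50_000))

    # intergenic pool: rejection-sample positions outside every window
    lo_bound, hi_bound = 1, genome_length
    placed = 0
    attempts = 0
    while placed < n_intergenic:
        attempts += 1
        if attempts > 100 * max(n_intergenic, 1):
            raise SimulationError("genome too dense to place intergenic SNPs")
        pos = int(rng.integers(lo_bound, hi_bound + 1))
        if any(lo <= pos <= hi for lo, hi in gene_windows):
            continue
        snp_table[f"rs{snp_idx}"] = (chrom, pos, None)
        snp_idx += 1
        placed += 1
    return models, snp_table


def effect_for_median_p(
    target_p: float, n: int, freq: float = 0.275
) -> float:
    """Per-allele effect (phenotype SD units) giving a median two-sided p of
    ``target_p`` for a causal SNP at frequency ``freq`` in a cohort of ``n``.

    The Wald statistic is Normal(lambda, 1) with noncentrality
    lambda = effect * sqrt(2 f (1-f) n); its median |z| is approximately
    lambda for lambda >> 1, so effect = Phi^-1(1 - p/2) / sqrt(2 f (1-f) n).
    """
    z_target = float(stats.norm.isf(target_p / 2))
    return z_target / math.sqrt(2 * freq * (1 - freq) * n)


def simulate_summary_stats(
    truth: SimulationTruth,
    snp_table: Mapping[str, Tuple[str, int, Optional[str]]],
    seed: int,
) -> Tuple[Dict[str, SnpAssoc], Dict[str, SnpAssoc]]:
    """Discovery and validation summary statistics for every SNP.

    Causal SNPs (one per planted gene, per ``truth.causal_snps``) carry the
    same true effect in both cohorts — the sign is shared, only the noise is
    independent — mirroring a two-cohort replication design. All other SNPs
    are null. Allele frequency and effect/other alleles are shared across
    cohorts.
    """
    rng = np.random.default_rng(seed)
    causal_ids = set(truth.causal_snps.values())

    discovery: Dict[str, SnpAssoc] = {}
    validation: Dict[str, SnpAssoc] = {}
    for snp_id in snp_table:
        chrom, pos, _gene = snp_table[snp_id]
        f = float(rng.uniform(0.05, 0.5))
        ea, oa = rng.choice(len(_BASES), size=2, replace=False)
        ea, oa = _BASES[int(ea)], _BASES[int(oa)]
        beta_true = truth.true_effect if snp_id in causal_ids else 0.0
        for cohort, n, store in (
            ("disc", truth.n_discovery, discovery),
            ("val", truth.n_validation, validation),
        ):
            se = 1.0 / math.sqrt(2 * f * (1 - f) * n)
            beta_hat = float(rng.normal(beta_true, se))
            p = float(2 * stats.norm.sf(abs(beta_hat / se)))
            p = max(p, 5e-324)  # avoid exact zero from extreme draws
            store[snp_id] = SnpAssoc(
                snp_id=snp_id, chrom=chrom, pos=pos,
                effect_allele=ea, other_allele=oa,
                beta=beta_hat, se=se, pvalue=p, eaf=f,
            )
    return discovery, validation


def simulate_expression(
    genes: Iterable[str],
    fraction_low: float,
    keep_list: Iterable[str] = (),
    seed: int = 0,
    planted_genes: Iterable[str] = (),
) -> Dict[str, ExpressionSummary]:
    """Expression summaries: a ``fraction_low`` share of non-planted genes
    fall below the RPKM threshold (Uniform(0,1)), the rest are clearly
    expressed (Uniform(1,100)). Planted genes always score >= 1 so the true
    module survives tissue pruning; keep-listed genes may be low — the
    pruning step, not the generator, is responsible for sparing them.
    """
    if not (0 <= fraction_low < 1):
        raise ValueError("fraction_low must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    planted = set(planted_genes)
    out: Dict[str, ExpressionSummary] = {}
    for gene in genes:
        if gene in planted:
            val = float(rng.uniform(1, 100))
        elif rng.random() < fraction_low:
            val = float(rng.uniform(0, 1))
        else:
            val = float(rng.uniform(1, 100))
        out[gene] = ExpressionSummary(gene_id=gene, rpkm_q25=val)
    return out


class SimulatedStudy:
    """Bundle of everything one synthetic study comprises."""

    def __init__(self, network, planted, gene_models, snp_table, expression,
                 keep_list, discovery, validation, truth):
        self.network = network
        self.planted = planted
        self.gene_models = gene_models
        self.snp_table = snp_table
        self.expression = expression
        self.keep_list = keep_list
        self.discovery = discovery
        self.validation = validation
        self.truth = truth


def simulate_study(
    seed: int,
    n_genes: int = 2000,
    mean_degree: float = 6.0,
    planted_size: int = 30,
    snps_per_gene: int = 5,
    n_intergenic: int = 2000,
    n_discovery: int = 1500,
    n_validation: int = 1000,
    median_causal_p: float = 1e-5,
    fraction_low: float = 0.15,
    true_effect: Optional[float] = None,
    window_up: int = 110_000,
    window_down: int = 40_000,
) -> SimulatedStudy:
    """Generate a complete synthetic study with the default conditions.

    Defaults: a 2,000-gene network of mean degree ~6 with a 30-gene planted
    module; 5 SNPs per gene plus 2,000 intergenic SNPs; discovery n = 1,500
    and validation n = 1,000; the true effect sized so a causal SNP's median
    discovery p is ~1e-5; 15% of non-planted genes lowly expressed.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = [int(s) for s in rng.integers(2**31, size=5)]

    network, planted = simulate_network(n_genes, mean_degree, planted_size, sub_seeds[0])
    genes = sorted(network.nodes)
    genome_length = n_genes * (50_000 + window_up + window_down + 60_000) + 10 * (
        window_up + window_down
    )
    gene_models, snp_table = simulate_gene_models_and_snps(
        genes, genome_length, snps_per_gene, sub_seeds[1],
        n_intergenic=n_intergenic, window_up=window_up, window_down=window_down,
    )
    if true_effect is None:
        true_effect = effect_for_median_p(median_causal_p, n_discovery)

    # one causal SNP per planted gene, chosen among the SNPs in its window
    snps_by_gene: Dict[str, List[str]] = {}
    for sid, (_c, _p, gid) in snp_table.items():
        if gid is not None:
            snps_by_gene.setdefault(gid, []).append(sid)
    causal = {
        g: sorted(snps_by_gene[g])[int(rng.integers(len(snps_by_gene[g])))]
        for g in sorted(planted)
    }
    truth = SimulationTruth(
        planted_genes=planted, causal_snps=causal, true_effect=true_effect,
        n_discovery=n_discovery, n_validation=n_validation,
    )
    discovery, validation = simulate_summary_stats(truth, snp_table, sub_seeds[2])

    # keep-list: a handful of low-expressed non-planted genes, emulating
    # tissue transcription factors that must survive pruning
    non_planted = [g for g in genes if g not in planted]
    keep_list = set(
        np.random.default_rng(sub_seeds[3]).choice(non_planted, size=min(10, len(non_planted)),
                                                   replace=False).tolist()
    )
    expression = simulate_expression(
        genes, fraction_low, keep_list=keep_list, seed=sub_seeds[4],
        planted_genes=planted,
    )
    # force keep-listed genes below threshold so the keep-list contract is exercised
    keep_rng = np.random.default_rng(sub_seeds[3] + 1)
    for g in sorted(keep_list):
        expression[g] = ExpressionSummary(gene_id=g, rpkm_q25=float(keep_rng.uniform(0, 1)))
    return SimulatedStudy(
        network=network, planted=planted, gene_models=gene_models,
        snp_table=snp_table, expression=expression, keep_list=keep_list,
        discovery=discovery, validation=validation, truth=truth,
    )
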