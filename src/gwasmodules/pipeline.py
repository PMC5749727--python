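"""End-to-end orchestration: from summary statistics to a validated consensus.

Stages: (1) map SNPs to gene windows and score genes by minimum p;
(2) prune the global network to the tissue; (3) Monte-Carlo size
calibration and greedy module search; (4) second-order search inside the
top module and consensus distillation; (5) replication of the consensus
SNPs in the validation cohort (combined z against an empirical SNP-set
null, sign test of directional consistency).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from . import modules as mod
from . import replication as rep
from .network import prune_network
from .scoring import assign_snps_to_genes, score_genes
from .types import (
    ConsensusNetwork, EmpiricalTestResult, GeneModel, GeneScore, RunConfig,
    ScoredModule, SnpAssoc,
)

__all__ = ["DiscoveryResult", "ReplicationResult", "run_discovery", "run_replication"]


@dataclass
class DiscoveryResult:
    gene_scores: Dict[str, GeneScore]
    pruned_network: nx.Graph
    calibration: "mod.CalibrationTable"
    modules: List[ScoredModule]
    consensus: ConsensusNetwork


@dataclass
class ReplicationResult:
    selected_snps: List[str]
    combined_z: float
    empirical: EmpiricalTestResult
    n_consistent: int
    n_total: int
    sign_p: float


def run_discovery(
    discovery_stats: Mapping[str, SnpAssoc],
    gene_models: Mapping[str, GeneModel],
    network: nx.Graph,
    expression,
    keep_list=(),
    config: Optional[RunConfig] = None,
) -> DiscoveryResult:
    """Run gene scoring, pruning, module search and consensus distillation."""
    cfg = config or RunConfig()
    assignment = assign_snps_to_genes(
        discovery_stats, gene_models, cfg.window_up, cfg.window_down
    )
    gene_scores = score_genes(assignment, discovery_stats, eps=cfg.p_clamp_eps)
    pruned = prune_network(network, expression, keep_list, cfg.rpkm_threshold)

    n_scored = sum(1 for n in pruned.nodes if n in gene_scores)
    max_k = min(cfg.max_module_size, n_scored)
    table = mod.calibrate_scores(
        pruned, gene_scores, n_samples=cfg.n_calibration, max_k=max_k, seed=cfg.rng_seed
    )
    found = mod.greedy_search(
        pruned, gene_scores, table, n_seeds=cfg.n_seeds, max_size=cfg.max_module_size
    )
    consensus = mod.second_order_consensus(
        pruned, found[0], gene_scores,
        n_modules=cfg.n_second_order_modules, min_occurrence=cfg.min_occurrence,
        n_samples=cfg.n_calibration, seed=cfg.rng_seed + 1,
        n_seeds=cfg.n_seeds, max_size=cfg.max_module_size,
        calibration=table,
    )
    return DiscoveryResult(
        gene_scores=gene_scores, pruned_network=pruned, calibration=table,
        modules=found, consensus=consensus,
    )


def run_replication(
    discovery: DiscoveryResult,
    discovery_stats: Mapping[str, SnpAssoc],
    validation_stats: Mapping[str, SnpAssoc],
    config: Optional[RunConfig] = None,
) -> ReplicationResult:
    """Validate the consensus SNPs in an independent cohort.

    The empirical null pool is the best SNP of every scored gene in the
    pruned network — the same SNPs the gene-scoring step already singled
    out. Directional consistency compares effect signs after orienting the
    validation record to the discovery effect allele.
    """
    cfg = config or RunConfig()
    selected = rep.select_validation_snps(
        discovery.consensus, discovery_stats, cfg.snp_selection_p
    )
    if not selected:
        raise ValueError("no consensus SNP passes the discovery p threshold")
    usable = [s for s in selected if s in validation_stats]
    combined = rep.combined_zscore(usable, validation_stats, eps=cfg.p_clamp_eps)

    pool = sorted({
        discovery.gene_scores[g].best_snp
        for g in discovery.pruned_network.nodes
        if g in discovery.gene_scores
    })
    empirical = rep.empirical_snpset_test(
        combined, pool, m=len(usable), validation_stats=validation_stats,
        n_draws=cfg.n_empirical, seed=cfg.rng_seed + 2, eps=cfg.p_clamp_eps,
    )

    n_consistent = 0
    for s in usable:
        aligned = rep.align_alleles(discovery_stats[s], validation_stats[s])
        if np.sign(aligned.beta) == np.sign(discovery_stats[s].beta):
            n_consistent += 1
    sign_p = rep.sign_test(n_consistent, len(usable))
    return ReplicationResult(
        selected_snps=usable, combined_z=combined, empirical=empirical,
        n_consistent=n_consistent, n_total=len(usable), sign_p=sign_p,
    )
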