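"""Greedy active-module discovery with Monte-Carlo size calibration.

A module A of k genes is scored by the normalized sum of its member
z-scores, z_A = sum_i z_i / sqrt(k). Because z_A drifts with k even under
the null, raw scores are standardized against random gene sets of matching
size drawn from the scored node set: s_A = (z_A - mu_k) / sigma_k. The
search is purely greedy: from each of the top-scoring seed nodes the module
grows one neighboring node at a time, always the one maximizing the
calibrated score, and stops at the first non-improving step.

The size calibration corrects for module size only — it does not correct
for the selection bias of the greedy maximization itself. The honest null
reference for the final top score is the permuted-score comparison
(`permutation_reference`), which reruns the whole search on shuffled gene
scores.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .types import CalibrationTable, ConsensusNetwork, GeneScore, ScoredModule

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6

__all__ = [
    "module_zscore", "calibrate_scores", "corrected_score", "score_module",
    "greedy_search", "permutation_reference", "PermutationReference",
    "second_order_consensus",
]


def _z_of(node: str, gene_scores: Mapping[str, GeneScore]) -> float:
    """Unscored nodes (no mapped SNP) contribute the null-neutral z = 0."""
    gs = gene_scores.get(node)
    return 0.0 if gs is None else gs.z_i


def module_zscore(nodes: Iterable[str], gene_scores: Mapping[str, GeneScore]) -> float:
    """Aggregate score z_A = sum(z_i) / sqrt(k) over the module's k nodes."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty node set")
    total = math.fsum(_z_of(n, gene_scores) for n in nodes)
    return total / math.sqrt(len(nodes))


def calibrate_scores(
    network: nx.Graph,
    gene_scores: Mapping[str, GeneScore],
    n_samples: int,
    max_k: int,
    seed: int,
) -> CalibrationTable:
    """Monte-Carlo moments of z_A over uniform random k-subsets, k = 1..max_k.

    Subsets are drawn (without replacement within a subset) from the
    network's scored node set; they are not required to be connected — the
    table answers "how large is z_A for an arbitrary gene set of this size",
    which is the reference the calibrated score standardizes against.
    Nested subsets share draws across k for efficiency: each sample is a
    random permutation prefix, so for each fixed k the k-subset is uniform.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100 for stable moments")
    scored = sorted(n for n in network.nodes if n in gene_scores)
    n_nodes = len(scored)
    if max_k > n_nodes:
        raise ValueError(f"max_k ({max_k}) exceeds number of scored nodes ({n_nodes})")
    if max_k < 1:
        raise ValueError("max_k must be positive")

    z = np.array([gene_scores[n].z_i for n in scored], dtype=np.float64)
    rng = np.random.default_rng(seed)

    sums = np.zeros(max_k)
    sumsq = np.zeros(max_k)
    sqrt_k = np.sqrt(np.arange(1, max_k + 1, dtype=np.float64))
    chunk = max(1, int(2e7 // max(n_nodes, 1)))
    done = 0
    while done < n_samples:
        rows = min(chunk, n_samples - done)
        # random permutation prefixes via argsort of uniform keys
        order = np.argsort(rng.random((rows, n_nodes)), axis=1)[:, :max_k]
        za = np.cumsum(z[order], axis=1) / sqrt_k
        sums += za.sum(axis=0)
        sumsq += (za * za).sum(axis=0)
        done += rows

    mu = sums / n_samples
    var = (sumsq - n_samples * mu * mu) / (n_samples - 1)
    sigma = np.sqrt(np.maximum(var, 0.0))
    degenerate = sigma < SIGMA_FLOOR
    if degenerate.any():
        logger.warning(
            "calibration sigma floored at %g for %d size(s) (degenerate score variance)",
            SIGMA_FLOOR, int(degenerate.sum()),
        )
        sigma = np.maximum(sigma, SIGMA_FLOOR)
    return CalibrationTable(mu=mu, sigma=sigma, n_samples=n_samples)


def corrected_score(module: ScoredModule, table: CalibrationTable) -> float:
    """Size-calibrated score s_A = (z_A - mu_k) / sigma_k."""
    if module.k > table.max_k:
        raise ValueError(f"calibration table covers k <= {table.max_k}, module has k = {module.k}")
    return (module.z_A - table.mu_k(module.k)) / table.sigma_k(module.k)


def score_module(
    nodes: Iterable[str],
    gene_scores: Mapping[str, GeneScore],
    table: CalibrationTable,
) -> ScoredModule:
    """Build a ScoredModule with both raw and calibrated scores."""
    node_set = frozenset(nodes)
    z_a = module_zscore(node_set, gene_scores)
    partial = ScoredModule(nodes=node_set, k=len(node_set), z_A=z_a, s_A=float("nan"))
    return ScoredModule(nodes=node_set, k=len(node_set), z_A=z_a,
                        s_A=corrected_score(partial, table))


def _grow_from_seed(
    seed_node: str,
    adjacency: Mapping[str, Sequence[str]],
    z: Mapping[str, float],
    table: CalibrationTable,
    max_size: int,
) -> Tuple[frozenset, float, float]:
    """Greedy expansion from one seed; returns (nodes, z_A, s_A).

    At a fixed target size the calibrated score is maximized by the highest-z
    candidate (mu_k, sigma_k do not depend on the candidate), so each step
    adds the best-z frontier node — ties broken by lexicographic node id —
    and stops as soon as that best addition fails to improve s_A.
    """
    module = {seed_node}
    z_sum = z[seed_node]
    k = 1
    s_cur = (z_sum - table.mu_k(1)) / table.sigma_k(1)
    frontier = {n for n in adjacency[seed_node] if n not in module}

    limit = min(max_size, table.max_k)
    while frontier and k < limit:
        best = min(frontier, key=lambda n: (-z[n], n))
        z_new = z_sum + z[best]
        s_new = (z_new / math.sqrt(k + 1) - table.mu_k(k + 1)) / table.sigma_k(k + 1)
        if s_new <= s_cur:
            break
        module.add(best)
        z_sum = z_new
        k += 1
        s_cur = s_new
        frontier.discard(best)
        frontier.update(n for n in adjacency[best] if n not in module)
    return frozenset(module), z_sum / math.sqrt(k), s_cur


def greedy_search(
    network: nx.Graph,
    gene_scores: Mapping[str, GeneScore],
    table: CalibrationTable,
    n_seeds: int = 100,
    max_size: int = 300,
    n_keep: Optional[int] = None,
) -> List[ScoredModule]:
    """Greedy module search from the top-scoring seed nodes.

    Seeds are the ``n_seeds`` highest-z scored nodes present in the network
    (unscored nodes contribute z = 0 to aggregates but never seed). Each
    seed's greedy trajectory yields one module; identical node sets are
    deduplicated and the surviving modules are ranked by calibrated score.
    """
    scored_in_net = [n for n in network.nodes if n in gene_scores]
    if not scored_in_net:
        raise ValueError("network contains no scored nodes")

    z: Dict[str, float] = {n: _z_of(n, gene_scores) for n in network.nodes}
    adjacency = {n: list(network.adj[n]) for n in network.nodes}
    seeds = sorted(scored_in_net, key=lambda n: (-z[n], n))[:n_seeds]

    seen: Dict[frozenset, ScoredModule] = {}
    for seed_node in seeds:
        nodes, z_a, s_a = _grow_from_seed(seed_node, adjacency, z, table, max_size)
        if nodes not in seen:
            seen[nodes] = ScoredModule(nodes=nodes, k=len(nodes), z_A=z_a, s_A=s_a)

    ranked = sorted(
        seen.values(), key=lambda m: (-m.s_A, -m.z_A, tuple(sorted(m.nodes)))
    )
    return ranked[:n_keep] if n_keep is not None else ranked


@dataclass
class PermutationReference:
    """Observed top calibrated score against score-permutation reruns.

    ``band95`` is the permuted mean +/- 1.96 * SEM over the ``n_perm`` reruns.
    """

    observed_top: float
    permuted_tops: List[float]
    permuted_mean: float
    band95: Tuple[float, float]


def permutation_reference(
    network: nx.Graph,
    gene_scores: Mapping[str, GeneScore],
    table: CalibrationTable,
    n_perm: int = 10,
    seed: int = 0,
    n_seeds: int = 100,
    max_size: int = 300,
) -> PermutationReference:
    """Rerun the greedy search on permuted gene scores.

    Shuffling z-values across the scored nodes (network topology fixed)
    preserves the score multiset — so the size-calibration table still
    applies — while destroying any spatial concentration of signal. The
    spread of permuted top scores is the proper yardstick for the observed
    top score, since both undergo the same greedy maximization.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    observed = greedy_search(network, gene_scores, table, n_seeds=n_seeds, max_size=max_size)
    observed_top = observed[0].s_A

    scored = sorted(n for n in network.nodes if n in gene_scores)
    rng = np.random.default_rng(seed)
    tops: List[float] = []
    for _ in range(n_perm):
        perm = rng.permutation(len(scored))
        shuffled = {
            scored[i]: gene_scores[scored[int(perm[i])]] for i in range(len(scored))
        }
        # rebind gene ids so z (and p/best_snp, which ride along) are permuted
        shuffled = {
            gid: GeneScore(gene_id=gid, p_i=gs.p_i, best_snp=gs.best_snp, z_i=gs.z_i)
            for gid, gs in shuffled.items()
        }
        perm_modules = greedy_search(network, shuffled, table, n_seeds=n_seeds, max_size=max_size)
        tops.append(perm_modules[0].s_A)

    mean = float(np.mean(tops))
    sem = float(np.std(tops, ddof=1) / math.sqrt(n_perm)) if n_perm > 1 else 0.0
    return PermutationReference(
        observed_top=observed_top, permuted_tops=tops, permuted_mean=mean,
        band95=(mean - 1.96 * sem, mean + 1.96 * sem),
    )


def second_order_consensus(
    network: nx.Graph,
    top_module: ScoredModule,
    gene_scores: Mapping[str, GeneScore],
    n_modules: int = 15,
    min_occurrence: int = 2,
    n_samples: int = 10_000,
    seed: int = 0,
    n_seeds: int = 100,
    max_size: int = 300,
    calibration: Optional[CalibrationTable] = None,
) -> ConsensusNetwork:
    """Distill a large top module into a consensus network.

    The greedy search is rerun inside the induced subgraph of the top
    module. When ``calibration`` is given (normally the first-order table)
    it is reused, so second-order scores stay referenced to random gene sets
    of the whole network; when omitted, the table is recomputed on the
    restricted node universe. Reusing the first-order reference is the
    default pipeline behavior: recalibrating on the already-selected
    high-scoring module re-centers the null on the module itself and the
    search then keeps only its above-average half. Genes appearing in at
    least ``min_occurrence`` of the top ``n_modules`` second-order modules
    form the consensus; each carries its best (driving) SNP and the induced
    edges.
    """
    if top_module.k < 2:
        raise ValueError("top module must have at least 2 nodes")
    sub = network.subgraph(top_module.nodes).copy()
    scored_in_sub = [n for n in sub.nodes if n in gene_scores]
    if not scored_in_sub:
        raise ValueError("top module contains no scored nodes")

    max_k = min(max_size, len(scored_in_sub))
    if calibration is not None:
        table = calibration
        max_k = min(max_k, table.max_k)
    else:
        table = calibrate_scores(sub, gene_scores, n_samples=n_samples, max_k=max_k, seed=seed)
    modules = greedy_search(sub, gene_scores, table, n_seeds=n_seeds, max_size=max_k)
    if len(modules) < n_modules:
        logger.info(
            "only %d distinct second-order modules found (requested top %d); using all",
            len(modules), n_modules,
        )
    top = modules[:n_modules]

    occurrence: Dict[str, int] = {}
    for m in top:
        for g in m.nodes:
            occurrence[g] = occurrence.get(g, 0) + 1
    # with fewer distinct modules than min_occurrence the rule can never be
    # met (modules are deduplicated); cap the threshold so unanimity over a
    # single distinct module yields that module rather than nothing
    effective_min = min(min_occurrence, len(top))
    genes = {g for g, c in occurrence.items() if c >= effective_min}
    edges = {frozenset((a, b)) for a, b in sub.edges if a in genes and b in genes}
    driving = {
        g: gene_scores[g].best_snp for g in genes if g in gene_scores
    }
    return ConsensusNetwork(
        genes=genes, driving_snps=driving, edges=edges,
        occurrence={g: occurrence[g] for g in genes},
    )
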