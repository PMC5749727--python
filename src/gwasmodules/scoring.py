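"""Gene significance scoring from SNP association p-values.

Each gene is scored by the minimum p-value over SNPs falling in its window:
110 kb upstream and 40 kb downstream of the transcribed span by default, a
span chosen to cover the vast majority of cis-eQTLs of a gene. Upstream and
downstream are interpreted relative to strand; unstranded annotations are
treated as '+'. The minimum p is transformed to a z-score via the inverse
normal CDF, z_i = Phi^-1(1 - p_i), so that small p-values map to large
positive z.
"""
from __future__ import annotations

from typing import Dict, Iterable, Mapping, Set

import numpy as np
from scipy import stats

from .exceptions import DataError
from .types import GeneModel, GeneScore, SnpAssoc

__all__ = ["assign_snps_to_genes", "score_genes", "p_to_z", "gene_window"]


def gene_window(gene: GeneModel, window_up: int = 110_000, window_down: int = 40_000):
    """Return the (inclusive) scoring window of a gene, strand-aware.

    For a '+' gene the window is [tx_start - up, tx_end + down]; for a '-'
    gene the upstream extension lies beyond tx_end, giving
    [tx_start - down, tx_end + up].
    """
    if gene.strand == "+":
        return gene.tx_start - window_up, gene.tx_end + window_down
    return gene.tx_start - window_down, gene.tx_end + window_up


def assign_snps_to_genes(
    snps: Mapping[str, SnpAssoc],
    genes: Mapping[str, GeneModel],
    window_up: int = 110_000,
    window_down: int = 40_000,
) -> Dict[str, Set[str]]:
    """Map SNPs to genes whose window contains them (boundaries inclusive).

    A SNP may map to several genes with overlapping windows; SNPs mapping
    nowhere are dropped. Only genes with at least one mapped SNP appear in
    the returned dict.
    """
    if window_up < 0 or window_down < 0:
        raise ValueError("windows must be non-negative")
    if not genes:
        raise ValueError("empty gene set")

    # group SNP positions per chromosome, sorted, for binary-search lookup
    by_chrom: Dict[str, list] = {}
    for snp in snps.values():
        by_chrom.setdefault(snp.chrom, []).append((snp.pos, snp.snp_id))
    pos_arrays = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        pos_arrays[chrom] = (
            np.array([p for p, _ in pairs], dtype=np.int64),
            [sid for _, sid in pairs],
        )

    assignment: Dict[str, Set[str]] = {}
    for gene in genes.values():
        if gene.chrom not in pos_arrays:
            continue
        lo, hi = gene_window(gene, window_up, window_down)
        positions, ids = pos_arrays[gene.chrom]
        i = np.searchsorted(positions, lo, side="left")
        j = np.searchsorted(positions, hi, side="right")
        if j > i:
            assignment[gene.gene_id] = set(ids[i:j])
    return assignment


def p_to_z(p: float, eps: float = 1e-12) -> float:
    """Transform a p-value to z = Phi^-1(1 - p), clamped to stay finite.

    p is clamped into [eps, 1 - eps] before the transform, so p -> 0 yields a
    large finite positive z and p = 1 a large negative one.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    p = max(p, eps)
    if p <= 0.5:
        return float(stats.norm.isf(p))
    # evaluate in the lower tail for accuracy near p = 1
    q = max(1.0 - p, eps)
    return float(-stats.norm.isf(q))


def score_genes(
    assignment: Mapping[str, Iterable[str]],
    snp_stats: Mapping[str, SnpAssoc],
    eps: float = 1e-12,
) -> Dict[str, GeneScore]:
    """Assign each gene the lowest p-value among its mapped SNPs.

    Ties for the minimum are broken by lexicographic snp_id so output is
    deterministic. Genes with no mapped SNPs are absent from the input
    assignment and hence from the scored set.
    """
    scores: Dict[str, GeneScore] = {}
    for gene_id, snp_ids in assignment.items():
        best_p = np.inf
        best_snp = None
        for sid in sorted(snp_ids):
            if sid not in snp_stats:
                raise DataError(f"gene {gene_id}: no statistics for assigned SNP {sid}")
            p = snp_stats[sid].pvalue
            if p < best_p:
                best_p, best_snp = p, sid
        if best_snp is None:
            continue
        scores[gene_id] = GeneScore(
            gene_id=gene_id, p_i=float(best_p), best_snp=best_snp,
            z_i=p_to_z(float(best_p), eps=eps),
        )
    return scores
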