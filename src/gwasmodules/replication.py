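"""Replication statistics for a prioritized SNP set.

Given the consensus network's driving SNPs and an independent validation
cohort, this module provides:

* a combined z-score, sum(z_j)/sqrt(m) over the set's validation z-values,
  tested against an empirical null of random same-size SNP sets drawn from
  the scored network's best SNPs;
* an exact one-sided binomial sign test of directional consistency between
  discovery and validation effects;
* inverse-variance fixed-effect meta-analysis with double genomic control;
* a summary-statistic polygenic-score association (inverse-variance
  approximation of regressing the phenotype on a weighted allele score);
* greedy LD pruning and regulatory-element interval overlap.

The combined z uses the direction-agnostic two-sided validation p: whether
effects point the same way is assessed separately by the sign test,
reproducing a two-statistic validation design.
"""
from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .exceptions import DataError
from .scoring import p_to_z
from .types import (
    ConsensusNetwork, EmpiricalTestResult, GeneScore, MetaResult, PrsResult, SnpAssoc,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "select_validation_snps", "combined_zscore", "empirical_snpset_test",
    "sign_test", "align_alleles", "gc_lambda", "fixed_effect_meta",
    "prs_association", "ld_prune", "regulatory_overlap", "is_palindromic",
]


def select_validation_snps(
    consensus: ConsensusNetwork,
    discovery_stats: Mapping[str, SnpAssoc],
    p_threshold: float = 5e-4,
) -> List[str]:
    """Best SNP per consensus gene with discovery p strictly below threshold.

    Genes sharing a driving SNP contribute it once; the returned list is
    sorted for determinism.
    """
    selected: Set[str] = set()
    for gene in sorted(consensus.genes):
        snp = consensus.driving_snps.get(gene)
        if snp is None or snp not in discovery_stats:
            continue
        if discovery_stats[snp].pvalue < p_threshold:
            selected.add(snp)
    if not selected:
        logger.warning("no consensus SNP passes discovery p < %g", p_threshold)
    return sorted(selected)


def combined_zscore(
    snp_list: Sequence[str],
    validation_stats: Mapping[str, SnpAssoc],
    eps: float = 1e-12,
) -> float:
    """Combined z = sum(z_j) / sqrt(m) over the m SNPs found in validation.

    z_j = Phi^-1(1 - p_j) from the validation two-sided p-value. SNPs absent
    from the validation table (e.g. failed QC) are dropped with a log line.
    """
    retained = [s for s in snp_list if s in validation_stats]
    dropped = len(snp_list) - len(retained)
    if dropped:
        logger.info("combined z: %d of %d SNPs missing from validation, dropped",
                    dropped, len(snp_list))
    if not retained:
        raise ValueError("no SNP from the list is present in the validation statistics")
    total = math.fsum(p_to_z(validation_stats[s].pvalue, eps=eps) for s in retained)
    return total / math.sqrt(len(retained))


def empirical_snpset_test(
    observed: float,
    snp_pool: Sequence[str],
    m: int,
    validation_stats: Mapping[str, SnpAssoc],
    n_draws: int = 100_000,
    seed: int = 0,
    eps: float = 1e-12,
) -> EmpiricalTestResult:
    """Empirical p of an observed combined z against random same-size SNP sets.

    ``snp_pool`` should hold the best SNP of every scored gene in the pruned
    network. Each draw is a uniform m-subset (without replacement within a
    draw, independent across draws); the estimator is (r+1)/(N+1) with
    r = #{null >= observed}, so the p-value is never zero.
    """
    pool = [s for s in snp_pool if s in validation_stats]
    if m > len(pool):
        raise ValueError(f"pool of {len(pool)} usable SNPs is smaller than m = {m}")
    if m < 1:
        raise ValueError("m must be positive")
    z = np.array([p_to_z(validation_stats[s].pvalue, eps=eps) for s in pool])
    rng = np.random.default_rng(seed)

    sqrt_m = math.sqrt(m)
    n_pool = len(pool)
    null_sum = 0.0
    null_sumsq = 0.0
    n_ge = 0
    done = 0
    chunk = max(1, int(5e6 // max(n_pool, 1)))
    while done < n_draws:
        rows = min(chunk, n_draws - done)
        keys = rng.random((rows, n_pool))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        draws = z[idx].sum(axis=1) / sqrt_m
        n_ge += int((draws >= observed).sum())
        null_sum += float(draws.sum())
        null_sumsq += float((draws * draws).sum())
        done += rows

    mean = null_sum / n_draws
    var = max(null_sumsq / n_draws - mean * mean, 0.0)
    return EmpiricalTestResult(
        observed=observed, null_draws=n_draws, n_ge=n_ge,
        empirical_p=(n_ge + 1) / (n_draws + 1),
        null_mean=mean, null_sd=math.sqrt(var),
    )


def sign_test(n_consistent: int, n_total: int) -> float:
    """One-sided exact binomial upper tail P(X >= n_consistent), X ~ Bin(n, 1/2).

    Tests whether discovery/validation effect signs agree more often than
    the coin-flip expectation.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_consistent <= n_total):
        raise ValueError("n_consistent must lie in [0, n_total]")
    return float(stats.binom.sf(n_consistent - 1, n_total, 0.5))


def is_palindromic(a: str, b: str) -> bool:
    """A/T and C/G pairs are strand-ambiguous."""
    return _COMPLEMENT.get(a.upper()) == b.upper()


def align_alleles(source: SnpAssoc, target: SnpAssoc) -> SnpAssoc:
    """Orient the target's effect to the source's effect allele.

    Handles swapped effect/other alleles (beta sign flips), opposite-strand
    reports (alleles complemented), and the combination. Palindromic SNPs
    (A/T, C/G) are aligned on the direct-match interpretation with a logged
    ambiguity warning. Returns a new record; inputs are not mutated.
    """
    s_ea, s_oa = source.effect_allele.upper(), source.other_allele.upper()
    t_ea, t_oa = target.effect_allele.upper(), target.other_allele.upper()

    if is_palindromic(s_ea, s_oa):
        logger.warning("SNP %s is palindromic (%s/%s): strand alignment ambiguous",
                       source.snp_id, s_ea, s_oa)

    def flipped(rec: SnpAssoc) -> SnpAssoc:
        return SnpAssoc(
            snp_id=rec.snp_id, chrom=rec.chrom, pos=rec.pos,
            effect_allele=s_ea, other_allele=s_oa,
            beta=-rec.beta, se=rec.se, pvalue=rec.pvalue,
            eaf=None if rec.eaf is None else 1 - rec.eaf,
        )

    def kept(rec: SnpAssoc) -> SnpAssoc:
        return SnpAssoc(
            snp_id=rec.snp_id, chrom=rec.chrom, pos=rec.pos,
            effect_allele=s_ea, other_allele=s_oa,
            beta=rec.beta, se=rec.se, pvalue=rec.pvalue, eaf=rec.eaf,
        )

    if (t_ea, t_oa) == (s_ea, s_oa):
        return kept(target)
    if (t_ea, t_oa) == (s_oa, s_ea):
        return flipped(target)
    c_ea = _COMPLEMENT.get(t_ea)
    c_oa = _COMPLEMENT.get(t_oa)
    if (c_ea, c_oa) == (s_ea, s_oa):
        return kept(target)
    if (c_ea, c_oa) == (s_oa, s_ea):
        return flipped(target)
    raise DataError(
        f"SNP {source.snp_id}: alleles {t_ea}/{t_oa} irreconcilable with {s_ea}/{s_oa}"
    )


_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


def gc_lambda(pvalues: Iterable[float]) -> float:
    """Genomic-control inflation factor: median association chi-square over
    the null chi-square median (0.4549)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def fixed_effect_meta(
    study_stats: Sequence[Mapping[str, SnpAssoc]],
    double_gc: bool = False,
    align_to_first: bool = True,
) -> Dict[str, MetaResult]:
    """Inverse-variance fixed-effect meta-analysis across >= 2 studies.

    With ``double_gc``, each study's SEs are first inflated by
    sqrt(max(lambda_study, 1)) — lambda computed from that study's full
    p-value vector — and after combining, the meta chi-squares are deflated
    by max(lambda_meta, 1) computed over all meta-analyzed SNPs (the meta SE
    is inflated by the same factor's square root, keeping beta/se and p
    consistent). Alleles are oriented to the first study's effect allele.
    """
    if len(study_stats) < 2:
        raise ValueError("meta-analysis requires at least two studies")

    lambdas = {}
    for i, stats_i in enumerate(study_stats):
        lam = gc_lambda([s.pvalue for s in stats_i.values()])
        lambdas[f"study{i + 1}"] = lam

    shared = set(study_stats[0])
    for stats_i in study_stats[1:]:
        shared &= set(stats_i)

    betas: Dict[str, List[float]] = {}
    ses: Dict[str, List[float]] = {}
    for snp_id in sorted(shared):
        ref = study_stats[0][snp_id]
        b_list, s_list = [], []
        for i, stats_i in enumerate(study_stats):
            rec = stats_i[snp_id]
            if align_to_first and i > 0:
                rec = align_alleles(ref, rec)
            infl = math.sqrt(max(lambdas[f"study{i + 1}"], 1.0)) if double_gc else 1.0
            b_list.append(rec.beta)
            s_list.append(rec.se * infl)
        betas[snp_id] = b_list
        ses[snp_id] = s_list

    raw: Dict[str, Tuple[float, float]] = {}
    for snp_id in betas:
        w = np.array([1.0 / s**2 for s in ses[snp_id]])
        b = np.array(betas[snp_id])
        beta_meta = float((w * b).sum() / w.sum())
        se_meta = float(1.0 / math.sqrt(w.sum()))
        raw[snp_id] = (beta_meta, se_meta)

    # second genomic-control pass on the meta statistics themselves
    chi2_meta = {s: (b / se) ** 2 for s, (b, se) in raw.items()}
    if double_gc and chi2_meta:
        p_meta_raw = [float(stats.chi2.sf(c, df=1)) for c in chi2_meta.values()]
        lambda_meta = gc_lambda(p_meta_raw)
    else:
        lambda_meta = 1.0
    deflate = max(lambda_meta, 1.0)

    out: Dict[str, MetaResult] = {}
    for snp_id, (beta_meta, se_meta) in raw.items():
        chi2_adj = chi2_meta[snp_id] / deflate
        out[snp_id] = MetaResult(
            snp_id=snp_id,
            beta_meta=beta_meta,
            se_meta=se_meta * math.sqrt(deflate),
            p_meta=float(stats.chi2.sf(chi2_adj, df=1)),
            lambda_by_study=dict(lambdas),
            lambda_meta=lambda_meta,
        )
    return out


def prs_association(
    weights: Mapping[str, float],
    target_stats: Mapping[str, SnpAssoc],
) -> PrsResult:
    """Summary-statistic polygenic-score association.

    For SNP weights w_i (discovery effect sizes, effect-raising orientation)
    and target per-SNP effects b_i with SEs s_i, the inverse-variance
    approximation of regressing the phenotype on the weighted allele score is

        alpha_hat = sum(w_i b_i / s_i^2) / sum(w_i^2 / s_i^2)
        se(alpha_hat) = (sum(w_i^2 / s_i^2))^(-1/2)

    with a two-sided normal p-value. Alleles must already be aligned.
    """
    shared = sorted(set(weights) & set(target_stats))
    if not shared:
        raise ValueError("no SNP shared between weights and target statistics")
    w = np.array([weights[s] for s in shared])
    b = np.array([target_stats[s].beta for s in shared])
    s2 = np.array([target_stats[s].se ** 2 for s in shared])
    denom = float((w * w / s2).sum())
    alpha = float((w * b / s2).sum() / denom)
    se_alpha = 1.0 / math.sqrt(denom)
    p = float(2 * stats.norm.sf(abs(alpha / se_alpha)))
    return PrsResult(alpha_hat=alpha, se_alpha=se_alpha, p=max(p, 5e-324), n_snps=len(shared))


def ld_prune(
    snps_by_p: Sequence[str],
    ld_r2: Mapping[frozenset, float],
    threshold: float = 0.8,
    pvalues: Optional[Mapping[str, float]] = None,
) -> List[str]:
    """Greedy LD pruning: walk SNPs in ascending p, keep a SNP iff its r2
    with every already-kept SNP is below threshold.

    ``snps_by_p`` may be pre-sorted; passing ``pvalues`` sorts here (ties
    broken by snp_id). Absent pairs count as r2 = 0.
    """
    ordered = list(snps_by_p)
    if pvalues is not None:
        ordered.sort(key=lambda s: (pvalues[s], s))
    kept: List[str] = []
    for snp in ordered:
        if all(ld_r2.get(frozenset((snp, k)), 0.0) < threshold for k in kept):
            kept.append(snp)
    return kept


def regulatory_overlap(
    snps: Mapping[str, Tuple[str, int]],
    proxy_table: Mapping[str, Sequence[Tuple[str, int, float]]],
    elements: Sequence[Tuple[str, int, int, str]],
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Overlap of each SNP locus with classed regulatory elements.

    A locus is the index SNP plus its proxies with r2 strictly above
    ``r2_threshold``; ``snps`` maps snp_id -> (chrom, 1-based position) and
    ``proxy_table`` maps snp_id -> [(chrom, pos, r2), ...]. ``elements`` are
    half-open BED tuples (chrom, start, end, class label): a 1-based
    position p overlaps [start, end) iff start <= p - 1 < end. Returns a
    boolean DataFrame indexed by snp_id with one column per element class.
    """
    classes = sorted({label for _c, _s, _e, label in elements})
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for chrom, start, end, label in elements:
        trees.setdefault((chrom, label), IntervalTree()).addi(start, end)

    rows = {}
    for snp_id in sorted(snps):
        positions = [snps[snp_id]]
        for chrom, pos, r2 in proxy_table.get(snp_id, ()):
            if r2 > r2_threshold:
                positions.append((chrom, pos))
        row = {}
        for label in classes:
            row[label] = any(
                bool(trees.get((chrom, label), IntervalTree())[pos - 1])
                for chrom, pos in positions
            )
        rows[snp_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=classes)
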