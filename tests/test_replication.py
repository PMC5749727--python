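"""Replication statistics: combined z, empirical nulls, sign test, allele
alignment, genomic control, meta-analysis, PRS, LD pruning and overlap."""
import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import gwasmodules as gm
from gwasmodules.exceptions import DataError

from conftest import make_snp


class TestSelectValidationSnps:
    def _consensus(self, driving):
        return gm.ConsensusNetwork(genes=set(driving), driving_snps=dict(driving),
                                   edges=set(), occurrence={g: 2 for g in driving})

    def test_strict_threshold_boundary(self):
        cons = self._consensus({"Ga": "rs_in", "Gb": "rs_out"})
        disc = {"rs_in": make_snp(snp_id="rs_in", pvalue=4.9e-4),
                "rs_out": make_snp(snp_id="rs_out", pvalue=5.0e-4)}
        assert gm.select_validation_snps(cons, disc) == ["rs_in"]

    def test_shared_snp_deduplicated(self):
        cons = self._consensus({"Ga": "rs_shared", "Gb": "rs_shared"})
        disc = {"rs_shared": make_snp(snp_id="rs_shared", pvalue=1e-5)}
        assert gm.select_validation_snps(cons, disc) == ["rs_shared"]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(30)
        driving = {f"G{i}": f"rs{int(rng.integers(0, 40))}" for i in range(60)}
        disc = {f"rs{j}": make_snp(snp_id=f"rs{j}", pvalue=float(rng.uniform(1e-6, 1e-2)))
                for j in range(40)}
        cons = self._consensus(driving)
        expected = sorted({s for s in driving.values() if disc[s].pvalue < 5e-4})
        assert gm.select_validation_snps(cons, disc) == expected


class TestCombinedZ:
    def test_single_median_p_gives_zero(self):
        val = {"rs1": make_snp(pvalue=0.5)}
        assert gm.combined_zscore(["rs1"], val) == pytest.approx(0.0, abs=1e-9)

    def test_four_snps_quantile_arithmetic(self):
        val = {f"rs{i}": make_snp(snp_id=f"rs{i}", pvalue=0.0227501) for i in range(4)}
        assert gm.combined_zscore(list(val), val) == pytest.approx(4.0, abs=2e-3)

    def test_shares_formula_with_module_zscore(self):
        rng = np.random.default_rng(31)
        val = {f"rs{i}": make_snp(snp_id=f"rs{i}", pvalue=float(rng.uniform(1e-4, 1)))
               for i in range(17)}
        scores = {f"rs{i}": gm.GeneScore(gene_id=f"rs{i}", p_i=val[f"rs{i}"].pvalue,
                                         best_snp=f"rs{i}",
                                         z_i=gm.p_to_z(val[f"rs{i}"].pvalue))
                  for i in range(17)}
        assert gm.combined_zscore(list(val), val) == pytest.approx(
            gm.module_zscore(list(val), scores), abs=1e-12)

    def test_missing_snps_dropped(self, caplog):
        val = {"rs1": make_snp(pvalue=0.5)}
        with caplog.at_level("INFO"):
            z = gm.combined_zscore(["rs1", "rs_gone"], val)
        assert z == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            gm.combined_zscore(["rs_gone"], val)


class TestEmpiricalSnpsetTest:
    def test_estimator_definition_when_observed_tops_all(self):
        rng = np.random.default_rng(32)
        val = {f"rs{i}": make_snp(snp_id=f"rs{i}", pvalue=float(rng.uniform(0.5, 1)))
               for i in range(50)}
        res = gm.empirical_snpset_test(50.0, list(val), m=5, validation_stats=val,
                                       n_draws=99, seed=0)
        assert res.n_ge == 0 and res.empirical_p == pytest.approx(1 / 100)

    def test_same_seed_identical_counts(self):
        rng = np.random.default_rng(33)
        val = {f"rs{i}": make_snp(snp_id=f"rs{i}", pvalue=float(rng.uniform()))
               for i in range(60)}
        r1 = gm.empirical_snpset_test(1.0, list(val), 6, val, n_draws=500, seed=5)
        r2 = gm.empirical_snpset_test(1.0, list(val), 6, val, n_draws=500, seed=5)
        assert r1.n_ge == r2.n_ge

    def test_pool_smaller_than_m_is_error(self):
        val = {"rs1": make_snp()}
        with pytest.raises(ValueError):
            gm.empirical_snpset_test(0.0, ["rs1"], 2, val, n_draws=100, seed=0)

    def test_empirical_p_bounds(self):
        rng = np.random.default_rng(34)
        val = {f"rs{i}": make_snp(snp_id=f"rs{i}", pvalue=float(rng.uniform()))
               for i in range(40)}
        res = gm.empirical_snpset_test(-50.0, list(val), 4, val, n_draws=200, seed=1)
        assert res.empirical_p == pytest.approx(1.0)
        assert 1 / 201 <= res.empirical_p <= 1


class TestSignTest:
    def test_observed_half_split(self):
        assert round(gm.sign_test(14, 28), 2) == 0.57

    def test_degenerate_tails(self):
        assert gm.sign_test(0, 28) == pytest.approx(1.0)
        assert gm.sign_test(28, 28) == pytest.approx(2.0 ** -28, rel=1e-9)

    @pytest.mark.parametrize("n_total", [1, 2, 7, 16, 30])
    def test_matches_exact_binomial_enumeration(self, n_total):
        for n_cons in range(n_total + 1):
            exact = sum(
                Fraction(math.comb(n_total, k), 2 ** n_total)
                for k in range(n_cons, n_total + 1)
            )
            assert gm.sign_test(n_cons, n_total) == pytest.approx(float(exact), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gm.sign_test(1, 0)
        with pytest.raises(ValueError):
            gm.sign_test(5, 4)


class TestAlignAlleles:
    source = make_snp(snp_id="rsX", ea="A", oa="G", beta=0.1)

    def test_swapped_alleles_flip_beta(self):
        target = make_snp(snp_id="rsX", ea="G", oa="A", beta=0.2, eaf=0.3)
        aligned = gm.align_alleles(self.source, target)
        assert aligned.beta == pytest.approx(-0.2)
        assert aligned.effect_allele == "A" and aligned.eaf == pytest.approx(0.7)

    def test_opposite_strand_keeps_sign(self):
        target = make_snp(snp_id="rsX", ea="T", oa="C", beta=0.2)
        aligned = gm.align_alleles(self.source, target)
        assert aligned.beta == pytest.approx(0.2) and aligned.effect_allele == "A"

    def test_strand_and_swap_flips(self):
        target = make_snp(snp_id="rsX", ea="C", oa="T", beta=0.2)
        assert gm.align_alleles(self.source, target).beta == pytest.approx(-0.2)

    def test_palindromic_logged_not_dropped(self, caplog):
        src = make_snp(snp_id="rsP", ea="A", oa="T", beta=0.1)
        tgt = make_snp(snp_id="rsP", ea="A", oa="T", beta=0.3)
        with caplog.at_level("WARNING"):
            aligned = gm.align_alleles(src, tgt)
        assert aligned.beta == pytest.approx(0.3)
        assert any("palindromic" in r.message for r in caplog.records)

    def test_irreconcilable_is_data_error(self):
        with pytest.raises(DataError):
            gm.align_alleles(self.source, make_snp(snp_id="rsX", ea="A", oa="C"))

    def test_alignment_idempotent_on_random_fixture(self):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rng = np.random.default_rng(35)
        for i in range(100):
            ea, oa = ("A", "G") if rng.random() < 0.5 else ("C", "A")
            src = make_snp(snp_id=f"rs{i}", ea=ea, oa=oa, beta=float(rng.normal()))
            t_ea, t_oa = ea, oa
            beta = float(rng.normal())
            if rng.random() < 0.5:
                t_ea, t_oa = t_oa, t_ea
            if rng.random() < 0.5:
                t_ea, t_oa = comp[t_ea], comp[t_oa]
            tgt = make_snp(snp_id=f"rs{i}", ea=t_ea, oa=t_oa, beta=beta)
            once = gm.align_alleles(src, tgt)
            twice = gm.align_alleles(src, once)
            assert once == twice


class TestGcLambda:
    def test_uniform_quantiles_give_one(self):
        p = (np.arange(1, 10_001) - 0.5) / 10_000
        assert gm.gc_lambda(p) == pytest.approx(1.0, abs=1e-3)

    def test_null_simulation_in_band(self):
        rng = np.random.default_rng(36)
        z = rng.standard_normal(10_000)
        p = 2 * stats.norm.sf(np.abs(z))
        assert 0.95 < gm.gc_lambda(p) < 1.05

    def test_scale_equivariance(self):
        rng = np.random.default_rng(37)
        chi2 = stats.chi2.rvs(1, size=5000, random_state=rng)
        p1 = stats.chi2.sf(chi2, 1)
        p2 = stats.chi2.sf(2 * chi2, 1)
        assert gm.gc_lambda(p2) == pytest.approx(2 * gm.gc_lambda(p1), rel=1e-9)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            gm.gc_lambda([])


class TestFixedEffectMeta:
    def _study(self, spec):
        return {sid: make_snp(snp_id=sid, beta=b, se=s, pvalue=p)
                for sid, b, s, p in spec}

    def test_equal_studies_closed_form(self):
        s1 = self._study([("rs1", 0.3, 0.1, 0.5)])
        s2 = self._study([("rs1", 0.3, 0.1, 0.5)])
        res = gm.fixed_effect_meta([s1, s2])["rs1"]
        assert res.beta_meta == pytest.approx(0.3)
        assert res.se_meta == pytest.approx(0.1 / math.sqrt(2))

    def test_hand_computed_two_study(self):
        s1 = self._study([("rs1", 0.3, 0.1, 0.5)])
        s2 = self._study([("rs1", 0.0, 0.2, 0.5)])
        res = gm.fixed_effect_meta([s1, s2])["rs1"]
        assert res.beta_meta == pytest.approx(0.24, abs=1e-12)
        assert res.se_meta == pytest.approx(1 / math.sqrt(125), rel=1e-9)

    def test_infinite_se_reduces_to_other_study(self):
        s1 = self._study([("rs1", 0.25, 0.05, 0.1)])
        s2 = self._study([("rs1", -3.0, 1e6, 0.9)])
        res = gm.fixed_effect_meta([s1, s2])["rs1"]
        assert res.beta_meta == pytest.approx(0.25, abs=1e-6)
        assert res.se_meta == pytest.approx(0.05, rel=1e-6)

    def test_single_study_is_error(self):
        with pytest.raises(ValueError):
            gm.fixed_effect_meta([self._study([("rs1", 0.1, 0.1, 0.5)])])

    def test_alleles_aligned_before_combining(self):
        s1 = {"rs1": make_snp(snp_id="rs1", ea="A", oa="G", beta=0.3, se=0.1)}
        s2 = {"rs1": make_snp(snp_id="rs1", ea="G", oa="A", beta=-0.3, se=0.1)}
        res = gm.fixed_effect_meta([s1, s2])["rs1"]
        assert res.beta_meta == pytest.approx(0.3)

    def test_null_meta_pvalues_uniform(self):
        rng = np.random.default_rng(38)
        n = 4000
        mk = lambda seed_rng: {
            f"rs{i}": make_snp(snp_id=f"rs{i}", beta=float(b), se=0.1,
                               pvalue=float(2 * stats.norm.sf(abs(b) / 0.1)))
            for i, b in enumerate(seed_rng.normal(0, 0.1, size=n))
        }
        res = gm.fixed_effect_meta([mk(rng), mk(rng)])
        pvals = [r.p_meta for r in res.values()]
        assert stats.kstest(pvals, "uniform").statistic < 1.63 / math.sqrt(n)

    def test_double_gc_inflates_se_only_when_lambda_high(self):
        rng = np.random.default_rng(39)
        n = 3000
        inflate = 1.3
        def study():
            out = {}
            for i in range(n):
                b = float(rng.normal(0, 0.1 * math.sqrt(inflate)))
                out[f"rs{i}"] = make_snp(snp_id=f"rs{i}", beta=b, se=0.1,
                                         pvalue=float(2 * stats.norm.sf(abs(b) / 0.1)))
            return out
        res = gm.fixed_effect_meta([study(), study()], double_gc=True)
        first = next(iter(res.values()))
        assert all(lam > 1.1 for lam in first.lambda_by_study.values())
        # after double GC the meta statistics should be roughly calibrated
        lam_after = gm.gc_lambda([r.p_meta for r in res.values()])
        assert 0.9 < lam_after <= 1.05


class TestPrsAssociation:
    def test_single_snp_reduction(self):
        tgt = {"rs1": make_snp(beta=0.2, se=0.1, pvalue=0.0455)}
        res = gm.prs_association({"rs1": 1.0}, tgt)
        assert res.alpha_hat == pytest.approx(0.2)
        assert res.se_alpha == pytest.approx(0.1)
        assert res.p == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-9)

    def test_hand_computed_two_snp(self):
        tgt = {"rs1": make_snp(snp_id="rs1", beta=0.2, se=0.1),
               "rs2": make_snp(snp_id="rs2", beta=0.4, se=0.1)}
        res = gm.prs_association({"rs1": 1.0, "rs2": 1.0}, tgt)
        assert res.alpha_hat == pytest.approx(0.3, abs=1e-12)
        assert res.se_alpha == pytest.approx(1 / math.sqrt(200), rel=1e-9)
        assert res.n_snps == 2

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(40)
        weights = {f"rs{i}": float(rng.uniform(0.05, 0.5)) for i in range(12)}
        tgt = {s: make_snp(snp_id=s, beta=float(rng.normal()), se=float(rng.uniform(0.05, 0.3)))
               for s in weights}
        base = gm.prs_association(weights, tgt)
        flipped_w = {s: -w if i % 2 else w for i, (s, w) in enumerate(weights.items())}
        flipped_t = {
            s: make_snp(snp_id=s, beta=-tgt[s].beta if i % 2 else tgt[s].beta,
                        se=tgt[s].se)
            for i, s in enumerate(weights)
        }
        flipped = gm.prs_association(flipped_w, flipped_t)
        assert flipped.alpha_hat == pytest.approx(base.alpha_hat, rel=1e-12)
        assert flipped.se_alpha == pytest.approx(base.se_alpha, rel=1e-12)

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError):
            gm.prs_association({"rs1": 1.0}, {"rs2": make_snp(snp_id="rs2")})


class TestLdPrune:
    def test_no_ld_identity(self):
        assert gm.ld_prune(["rs1", "rs2", "rs3"], {}) == ["rs1", "rs2", "rs3"]

    def test_perfect_ld_keeps_smaller_p(self):
        ld = {frozenset(("rs1", "rs2")): 1.0}
        pv = {"rs1": 0.01, "rs2": 0.001}
        assert gm.ld_prune(["rs1", "rs2"], ld, pvalues=pv) == ["rs2"]

    def test_matches_greedy_definition_on_block_fixture(self):
        rng = np.random.default_rng(41)
        snps = [f"rs{i}" for i in range(20)]
        pv = {s: float(rng.uniform()) for s in snps}
        ld = {}
        for i in range(20):
            for j in range(i + 1, 20):
                if i // 5 == j // 5:  # block structure
                    ld[frozenset((snps[i], snps[j]))] = float(rng.uniform(0.5, 1.0))
        result = gm.ld_prune(snps, ld, threshold=0.8, pvalues=pv)
        # exhaustive check of the greedy definition
        kept = []
        for s in sorted(snps, key=lambda x: (pv[x], x)):
            if all(ld.get(frozenset((s, k)), 0.0) < 0.8 for k in kept):
                kept.append(s)
        assert result == kept


class TestRegulatoryOverlap:
    elements = [("chr1", 100, 200, "promoter"), ("chr1", 300, 400, "active_enhancer")]

    def test_containment_and_half_open_boundary(self):
        snps = {"rs_in": ("chr1", 151), "rs_edge": ("chr1", 201)}
        # 1-based 151 -> 0-based 150 inside [100,200); 201 -> 200 excluded
        table = gm.regulatory_overlap(snps, {}, self.elements)
        assert bool(table.loc["rs_in", "promoter"]) is True
        assert bool(table.loc["rs_edge", "promoter"]) is False

    def test_proxy_extends_locus(self):
        snps = {"rs1": ("chr1", 900)}
        proxies = {"rs1": [("chr1", 350, 0.9), ("chr1", 150, 0.5)]}
        table = gm.regulatory_overlap(snps, proxies, self.elements)
        assert bool(table.loc["rs1", "active_enhancer"]) is True
        assert bool(table.loc["rs1", "promoter"]) is False  # r2 0.5 not > 0.8

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        elements = [("chr1", int(s), int(s) + int(rng.integers(50, 500)),
                     rng.choice(["promoter", "enhancer", "ctcf"]))
                    for s in rng.integers(0, 50_000, size=40)]
        snps = {f"rs{i}": ("chr1", int(rng.integers(1, 50_500))) for i in range(30)}
        proxies = {
            f"rs{i}": [("chr1", int(rng.integers(1, 50_500)), float(rng.uniform()))
                       for _ in range(rng.integers(0, 4))]
            for i in range(30)
        }
        table = gm.regulatory_overlap(snps, proxies, elements, r2_threshold=0.8)
        for sid, (chrom, pos) in snps.items():
            locus = [(chrom, pos)] + [(c, p) for c, p, r2 in proxies.get(sid, [])
                                      if r2 > 0.8]
            for label in {e[3] for e in elements}:
                expected = any(
                    c == ec and es <= p - 1 < ee
                    for c, p in locus
                    for ec, es, ee, el in elements if el == label
                )
                assert bool(table.loc[sid, label]) == expected
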