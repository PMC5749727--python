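import networkx as nx
import numpy as np
import pytest

import gwasmodules as gm


@pytest.fixture(scope="session")
def small_study():
    """A small planted-signal study shared by read-only tests."""
    return gm.simulate_study(7, n_genes=300, planted_size=12, n_intergenic=200)


@pytest.fixture(scope="session")
def small_discovery(small_study):
    """Discovery-stage result for the small study (cheap calibration)."""
    cfg = gm.RunConfig(n_calibration=2000, max_module_size=80, rng_seed=7)
    return gm.run_discovery(
        small_study.discovery, small_study.gene_models, small_study.network,
        small_study.expression, small_study.keep_list, cfg,
    )


@pytest.fixture
def line_graph():
    """Four-node path with known z-scores for greedy-search arithmetic."""
    g = nx.path_graph(["n1", "n2", "n3", "n4"])
    scores = {
        n: gm.GeneScore(gene_id=n, p_i=0.5, best_snp=f"rs_{n}", z_i=z)
        for n, z in [("n1", 4.0), ("n2", 3.0), ("n3", 2.0), ("n4", -5.0)]
    }
    return g, scores


def make_snp(snp_id="rs1", chrom="chr1", pos=100, ea="A", oa="G", beta=0.1,
             se=0.05, pvalue=0.05, eaf=0.3):
    return gm.SnpAssoc(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                       other_allele=oa, beta=beta, se=se, pvalue=pvalue, eaf=eaf)
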