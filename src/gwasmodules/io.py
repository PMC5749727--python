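"""Readers and writers for every file format the pipeline touches.

Conventions
-----------
* Summary statistics: tab-delimited with a header row naming the columns
  ``snp_id chrom pos effect_allele other_allele beta se pvalue`` and an
  optional ``eaf`` column.
* Gene models and regulatory elements: BED (0-based, half-open); internal
  coordinates are converted to 1-based inclusive on load and back on write.
* Network: two-column tab-delimited gene-id edge list, optional third
  confidence column (stored as an edge attribute, otherwise unused).
* Module reports: a ranked TSV plus the consensus network as GML and a
  gene/SNP TSV.

Loaders never mutate their inputs and reject rows that violate the record
invariants, logging a reason for each rejection.
"""
from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .exceptions import DataError, FormatError
from .types import ConsensusNetwork, ExpressionSummary, GeneModel, ScoredModule, SnpAssoc

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue",
]


def load_summary_stats(path) -> Dict[str, SnpAssoc]:
    """Load a tab-delimited summary-statistics file keyed by SNP id.

    Rows violating the per-SNP invariants (non-positive SE, p outside (0, 1],
    identical alleles) are dropped with a logged reason; a duplicated snp_id
    is an error because silent last-wins merges are the main corruption risk
    when combining cohorts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_eaf = "eaf" in df.columns

    out: Dict[str, SnpAssoc] = {}
    for row in df.itertuples(index=False):
        eaf = getattr(row, "eaf", None) if has_eaf else None
        if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
            eaf = None
        rec = SnpAssoc(
            snp_id=str(row.snp_id), chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=str(row.effect_allele), other_allele=str(row.other_allele),
            beta=float(row.beta), se=float(row.se), pvalue=float(row.pvalue),
            eaf=None if eaf is None else float(eaf),
        )
        reason = rec.validate()
        if reason is not None:
            logger.warning("%s: rejected SNP %s: %s", path, rec.snp_id, reason)
            continue
        if rec.snp_id in out:
            raise DataError(f"{path}: duplicate snp_id {rec.snp_id}")
        out[rec.snp_id] = rec
    return out


def write_summary_stats(snps: Dict[str, SnpAssoc], path) -> None:
    # floats written with repr() so load(write(x)) is bit-exact
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS + ["eaf"]) + "\n")
        for s in snps.values():
            eaf = "" if s.eaf is None else repr(s.eaf)
            fh.write(
                f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.effect_allele}\t{s.other_allele}"
                f"\t{s.beta!r}\t{s.se!r}\t{s.pvalue!r}\t{eaf}\n"
            )


def load_gene_models(path) -> Dict[str, GeneModel]:
    """Load gene models from a BED6 file (chrom, start, end, gene_id, score, strand).

    BED coordinates (0-based, half-open) are converted to the internal
    1-based inclusive convention; strand '.' is treated as '+' with a warning.
    """
    out: Dict[str, GeneModel] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{line_no}: expected 6 BED columns, got {len(parts)}")
            chrom, start, end, gene_id, _score, strand = parts[:6]
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise DataError(f"{path}:{line_no}: start {start_i} > end {end_i}")
            if strand == ".":
                logger.warning("%s:%d: gene %s has strand '.', treating as '+'", path, line_no, gene_id)
                strand = "+"
            if gene_id in out:
                raise DataError(f"{path}:{line_no}: duplicate gene_id {gene_id}")
            out[gene_id] = GeneModel(
                gene_id=gene_id, chrom=chrom, strand=strand,
                tx_start=start_i + 1, tx_end=end_i,
            )
    return out


def write_gene_models(genes: Dict[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes.values():
            fh.write(f"{g.chrom}\t{g.tx_start - 1}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\n")


def load_edge_list(path) -> nx.Graph:
    """Load a two/three-column edge list as an undirected simple graph.

    Self-loops are dropped (the node is retained); duplicate edges collapse.
    A third column, when present, is stored as the edge's ``confidence``.
    """
    graph = nx.Graph(provenance="global")
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{line_no}: expected at least 2 columns")
            a, b = parts[0], parts[1]
            if a == b:
                logger.warning("%s:%d: self-loop on %s dropped (node kept)", path, line_no, a)
                graph.add_node(a)
                continue
            attrs = {}
            if len(parts) >= 3 and parts[2] != "":
                attrs["confidence"] = float(parts[2])
            graph.add_edge(a, b, **attrs)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            conf = data.get("confidence")
            if conf is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{conf}\n")
        # isolated nodes round-trip as self-pair lines: the loader drops the
        # self-loop but keeps the node
        connected = {n for e in graph.edges for n in e}
        for node in sorted(set(graph.nodes) - connected):
            fh.write(f"{node}\t{node}\n")


def load_expression(path) -> Dict[str, ExpressionSummary]:
    """Load a per-gene expression summary TSV (gene_id, rpkm_q25)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("gene_id", "rpkm_q25"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    out: Dict[str, ExpressionSummary] = {}
    for row in df.itertuples(index=False):
        gid = str(row.gene_id)
        if gid in out:
            raise DataError(f"{path}: duplicate gene_id {gid}")
        out[gid] = ExpressionSummary(gene_id=gid, rpkm_q25=float(row.rpkm_q25))
    return out


def write_expression(expr: Dict[str, ExpressionSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trpkm_q25\n")
        for e in expr.values():
            fh.write(f"{e.gene_id}\t{e.rpkm_q25!r}\n")


def load_keep_list(path) -> set:
    """Load a transcription-factor keep-list: one gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def load_ld_table(path) -> Dict[frozenset, float]:
    """Load a pairwise LD table (snp_a, snp_b, r2); absent pairs mean r2 = 0."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    table: Dict[frozenset, float] = {}
    for row in df.itertuples(index=False):
        key = frozenset((str(row.snp_a), str(row.snp_b)))
        r2 = float(row.r2)
        if key in table and abs(table[key] - r2) > 1e-12:
            raise DataError(f"{path}: conflicting r2 for pair {sorted(key)}")
        table[key] = r2
    return table


def load_bed_intervals(path) -> List[Tuple[str, int, int, str]]:
    """Load labelled BED intervals (chrom, start, end, label) as half-open tuples."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{line_no}: expected 4 BED columns (chrom start end label)")
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise FormatError(f"{path}:{line_no}: empty or inverted interval")
            out.append((chrom, start, end, label))
    return out


def write_module_report(
    modules: Sequence[ScoredModule],
    consensus: Optional[ConsensusNetwork],
    path_prefix,
    gene_scores: Optional[dict] = None,
) -> List[str]:
    """Write the ranked module TSV and, if given, the consensus network.

    Produces ``<prefix>_modules.tsv`` (rank, size, raw z_A, calibrated s_A,
    member genes) and, when ``consensus`` is not None,
    ``<prefix>_consensus.gml`` plus ``<prefix>_consensus_genes.tsv``
    (gene, driving SNP, occurrence count, and the gene's p/z when
    ``gene_scores`` is supplied). Returns the list of paths written.
    """
    if not modules:
        raise ValueError("module list is empty")
    prefix = str(path_prefix)
    written = []

    mod_path = f"{prefix}_modules.tsv"
    with open(mod_path, "w") as fh:
        fh.write("rank\tsize\tz_A\ts_A\tgenes\n")
        for rank, m in enumerate(modules, 1):
            genes = ",".join(sorted(m.nodes))
            fh.write(f"{rank}\t{m.k}\t{m.z_A:.6g}\t{m.s_A:.6g}\t{genes}\n")
    written.append(mod_path)

    if consensus is not None:
        graph = nx.Graph()
        graph.add_nodes_from(sorted(consensus.genes))
        graph.add_edges_from(sorted(tuple(sorted(e)) for e in consensus.edges))
        gml_path = f"{prefix}_consensus.gml"
        nx.write_gml(graph, gml_path)
        written.append(gml_path)

        genes_path = f"{prefix}_consensus_genes.tsv"
        with open(genes_path, "w") as fh:
            fh.write("gene_id\tdriving_snp\toccurrence\tp_i\tz_i\n")
            for gene in sorted(consensus.genes):
                snp = consensus.driving_snps.get(gene, "")
                occ = consensus.occurrence.get(gene, 0)
                if gene_scores is not None and gene in gene_scores:
                    gs = gene_scores[gene]
                    fh.write(f"{gene}\t{snp}\t{occ}\t{gs.p_i:.6g}\t{gs.z_i:.6g}\n")
                else:
                    fh.write(f"{gene}\t{snp}\t{occ}\t\t\n")
        written.append(genes_path)
    return written
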