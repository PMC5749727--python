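"""Tissue-specific pruning of a global protein-interaction network.

Genes unlikely to be expressed in the tissue — 25th-percentile RPKM below a
threshold (default 1) across expression samples — are removed from the
global network, except genes on an explicit keep-list (e.g. lineage
transcription factors whose transcripts are low-abundance yet functionally
present). Genes absent from the expression table are treated as not
expressed and removed unless keep-listed: the goal is a tissue-credible
network, so absence of evidence counts against a gene.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx

from .types import ExpressionSummary

logger = logging.getLogger(__name__)

__all__ = ["prune_network"]


def prune_network(
    network: nx.Graph,
    expression: Mapping[str, ExpressionSummary],
    keep_list: Iterable[str] = (),
    rpkm_threshold: float = 1.0,
    drop_isolated: bool = False,
) -> nx.Graph:
    """Return the induced subgraph on genes expressed in the tissue.

    A node survives iff its 25th-percentile RPKM is >= ``rpkm_threshold`` or
    it is on ``keep_list``. Isolated surviving nodes are retained by default
    (they can still seed a module search); pass ``drop_isolated=True`` to
    remove them. The input graph is not mutated.
    """
    keep = set(keep_list)
    surviving = set()
    for node in network.nodes:
        if node in keep:
            surviving.add(node)
        elif node in expression and expression[node].rpkm_q25 >= rpkm_threshold:
            surviving.add(node)
    if not surviving:
        raise ValueError("pruning removed every node; check expression table and threshold")

    pruned = network.subgraph(surviving).copy()
    if drop_isolated:
        pruned.remove_nodes_from([n for n in pruned.nodes if pruned.degree(n) == 0])
    pruned.graph["provenance"] = "pruned"
    logger.info(
        "pruned network: %d/%d nodes, %d/%d edges retained",
        pruned.number_of_nodes(), network.number_of_nodes(),
        pruned.number_of_edges(), network.number_of_edges(),
    )
    return pruned
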