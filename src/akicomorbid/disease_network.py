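"""Build and serialize the AKI-centered disease network.

The network is a star: one hub node for AKI, one node per retained
comorbidity partner, and one edge per pair. Node attributes carry the ICD-10
chapter and an importance score (sup * kulc); edge attributes carry kulc,
lift and the verification status.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Tuple

import networkx as nx

from .icd_processing import AKI_ITEM, chapter_of
from .pair_validation import ValidationVerdict, canonical_pair
from .rule_mining import PairRule

SUPPORTED_FORMATS = ("graphml", "json")


def build_network(
    pairs: Iterable[PairRule],
    verdicts: Optional[Iterable[ValidationVerdict]] = None,
    top_k: int = 284,
    aki_item: str = AKI_ITEM,
) -> nx.Graph:
    """Star graph over the ``top_k`` pairs ranked by sup * kulc.

    Ties at the cut are broken by partner code ascending, so the smaller
    code is retained. ``top_k <= 0`` yields the hub alone.
    """
    status: Mapping[Tuple[str, str], str] = {}
    if verdicts is not None:
        status = {v.pair: v.final for v in verdicts}

    ranked = sorted(pairs, key=lambda r: (-r.importance, r.partner(aki_item)))
    retained = ranked[: max(top_k, 0)]

    graph = nx.Graph()
    graph.add_node(aki_item, chapter="hub", importance=0.0)
    for rule in retained:
        partner = rule.partner(aki_item)
        graph.add_node(
            partner,
            chapter=chapter_of(partner),
            importance=rule.importance,
        )
        graph.add_edge(
            aki_item,
            partner,
            kulc=rule.kulc,
            lift=rule.lift,
            sup=rule.sup,
            verification=status.get(canonical_pair(aki_item, partner), "unverified"),
        )
    return graph


def export_graph(graph: nx.Graph, path, format: str = "graphml") -> Path:
    """Write the graph as GraphML or node-link JSON; re-importable losslessly."""
    if format not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    else:
        data = nx.node_link_data(graph, edges="edges")
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    return path


def import_graph(path, format: str = "graphml") -> nx.Graph:
    if format not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    return nx.node_link_graph(json.loads(path.read_text()), edges="edges")
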