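"""Gene-set overlap networks and core-gene-set extraction.

Survival-significant sets (screen FDR below threshold) become nodes, split
into a "negative" network (hazard ratio >= 1) and a "positive" network
(hazard ratio < 1).  Edges connect pairs whose Jaccard overlap
(|intersection| / |union|) is at least the threshold (default 0.20).  The
module with the most robust-flagged nodes is selected and its core gene
set extracted as the genes present in at least 40% of the module's sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .survival import SurvivalScreenResult

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 0.20
DEFAULT_CORE_FREQ = 0.40


def overlap_score(set_a, set_b) -> float:
    """Jaccard overlap |A n B| / |A u B| of two gene lists."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap_score requires non-empty sets")
    return len(a & b) / len(a | b)


@dataclass
class CoreGeneSet:
    genes: list[str]
    frequencies: pd.Series  # per retained gene, fraction of module sets containing it
    module: list[str]
    threshold: float
    direction: str = ""


def build_network(
    screen: SurvivalScreenResult,
    collection: GeneSetCollection,
    q_threshold: float = 0.01,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    robust_names: list[str] | None = None,
) -> tuple[nx.Graph, nx.Graph]:
    """Overlap networks over the screen's significant sets.

    Returns (negative, positive): the hazard-ratio >= 1 network and the
    hazard-ratio < 1 network.  Nodes carry p, q, hr, size and a robust
    flag; edges carry the overlap score and exist only within one
    direction group at overlap >= ``min_overlap``.
    """
    robust = set(robust_names or [])
    shared = [n for n in screen.set_names if n in collection]
    table = screen.table.loc[shared]
    significant = table.index[table["q"] < q_threshold]
    if len(significant) == 0:
        logger.warning("no sets at FDR < %g; returning empty networks", q_threshold)

    graphs: dict[str, nx.Graph] = {}
    for direction, mask in (
        ("negative", table.loc[significant, "hr"] >= 1.0),
        ("positive", table.loc[significant, "hr"] < 1.0),
    ):
        names = list(significant[mask])
        g = nx.Graph(direction=direction, q_threshold=q_threshold, min_overlap=min_overlap)
        for name in names:
            row = table.loc[name]
            g.add_node(
                name,
                p=float(row["p"]),
                q=float(row["q"]),
                hr=float(row["hr"]),
                size=len(collection.genes(name)),
                robust=name in robust,
                node_size=float(-np.log10(max(row["p"], np.finfo(float).tiny))),
            )
        members = {n: set(collection.genes(n)) for n in names}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = len(members[a] & members[b])
                if inter == 0:
                    continue
                score = inter / len(members[a] | members[b])
                if score >= min_overlap:
                    g.add_edge(a, b, overlap_score=score)
        graphs[direction] = g
        logger.info("%s network: %d nodes, %d edges", direction, g.number_of_nodes(),
                    g.number_of_edges())
    return graphs["negative"], graphs["positive"]


def select_core_module(network: nx.Graph, method: str = "components") -> list[str]:
    """Module of the network richest in robust-flagged nodes.

    With ``method='components'`` modules are connected components; the one
    with the most robust nodes wins (ties: larger component, then
    lexicographically smallest member).  ``method='greedy_modularity'``
    uses community detection instead.  If no module contains a robust
    node, the largest module is returned with a warning.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if method == "components":
        modules = [sorted(c) for c in nx.connected_components(network)]
    elif method == "greedy_modularity":
        modules = [sorted(c) for c in nx.community.greedy_modularity_communities(network)]
    else:
        raise ValueError(f"unknown module method {method!r}")

    def robust_count(mod: list[str]) -> int:
        return sum(1 for n in mod if network.nodes[n].get("robust", False))

    # prefer more robust nodes, then larger modules, then the
    # lexicographically smallest first member
    best = sorted(modules, key=lambda mod: (-robust_count(mod), -len(mod), mod[0]))[0]
    if robust_count(best) == 0:
        logger.warning("no module contains a robust set; returning the largest module")
    return best


def derive_core_set(
    module: list[str],
    collection: GeneSetCollection,
    freq_threshold: float = DEFAULT_CORE_FREQ,
    direction: str = "",
) -> CoreGeneSet:
    """Genes present in at least ``freq_threshold`` of the module's sets."""
    if not module:
        raise ValueError("module must be non-empty")
    counts: dict[str, int] = {}
    for name in module:
        for g in collection.genes(name):
            counts[g] = counts.get(g, 0) + 1
    freq = pd.Series(counts, dtype=float) / len(module)
    kept = freq[freq >= freq_threshold].sort_values(ascending=False)
    if kept.empty:
        logger.warning("no gene reaches frequency %g in the %d-set module", freq_threshold,
                       len(module))
    return CoreGeneSet(
        genes=list(kept.index),
        frequencies=kept,
        module=list(module),
        threshold=freq_threshold,
        direction=direction,
    )


def gene_frequency(
    group: list[str], collection: GeneSetCollection, min_fraction: float
) -> pd.Series:
    """Per-gene membership frequency across a group of sets, filtered to
    genes present in at least ``min_fraction`` of them."""
    if not group:
        raise ValueError("group must be non-empty")
    counts: dict[str, int] = {}
    for name in group:
        for g in collection.genes(name):
            counts[g] = counts.get(g, 0) + 1
    freq = pd.Series(counts, dtype=float) / len(group)
    return freq[freq >= min_fraction].sort_values(ascending=False)


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def write_sif(network: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: ``A overlap B`` per edge, isolated nodes bare."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b in network.edges:
            fh.write(f"{a}\toverlap\t{b}\n")
        for n in network.nodes:
            if network.degree[n] == 0:
                fh.write(f"{n}\n")
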