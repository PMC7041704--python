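"""Gene-list overlap reporting and seed-neighborhood subnetwork extraction.

The subnetwork stage emulates a functional-interaction analysis: starting
from a seed gene list (e.g. GWAS candidates that are also IL-10-regulated),
it expands to all first neighbors in a user-supplied undirected interaction
edge list, keeps only nodes significantly deregulated in the wild-type
IL-10+LPS vs LPS contrast, and returns the induced graph with per-node fold
changes and directions.  Retention is by FDR alone by default — deregulation
strength is carried as a continuous node attribute — with an optional joint
FDR + fold-change gate.

Gene identifiers are matched exactly (case-preserving); symbol alias
resolution is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .datamodel import AnalysisConfig, DETable

log = logging.getLogger("matchloci")


@dataclass(frozen=True)
class OverlapReport:
    """Exact intersection of two gene lists."""

    size_a: int
    size_b: int
    size_intersection: int
    intersection_genes: tuple

    def as_dict(self) -> dict:
        return {
            "size_a": self.size_a,
            "size_b": self.size_b,
            "size_intersection": self.size_intersection,
            "intersection_genes": list(self.intersection_genes),
        }


def intersect_gene_lists(a, b) -> OverlapReport:
    """Set intersection of two gene lists (exact identifier match)."""
    sa, sb = set(a), set(b)
    inter = sorted(sa & sb)
    return OverlapReport(
        size_a=len(sa),
        size_b=len(sb),
        size_intersection=len(inter),
        intersection_genes=tuple(inter),
    )


def build_graph(edges) -> nx.Graph:
    """Undirected graph from (a, b) pairs; self-loops and duplicate or
    reversed edges collapse away."""
    graph = nx.Graph()
    n_self = 0
    for a, b in edges:
        if a == b:
            n_self += 1
            continue
        graph.add_edge(a, b)
    if n_self:
        log.warning("dropped %d self-loop edge(s)", n_self)
    return graph


@dataclass
class Subnetwork:
    """First-neighbor subnetwork filtered to deregulated genes.

    ``graph`` nodes carry ``is_seed``, ``log2fc`` (WT IL-10+LPS vs LPS),
    ``direction`` ('up'/'down') and, when a mutant table was supplied,
    ``ko_log2fc`` for annotation.  Seeds failing the DE filter are listed in
    ``dropped_seeds`` rather than retained.
    """

    graph: nx.Graph
    dropped_seeds: tuple

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def extract_subnetwork(
    seeds,
    interactions: nx.Graph,
    de_wt: DETable,
    config: AnalysisConfig,
    de_ko: DETable | None = None,
) -> Subnetwork:
    """Seeds plus first neighbors, retained if deregulated in the WT contrast.

    Seeds absent from the edge list stay candidates (isolated, with a
    warning); an empty retained set is a valid empty subnetwork.
    """
    seed_set = set(seeds)
    missing = sorted(g for g in seed_set if g not in interactions)
    if missing:
        log.warning("%d seed(s) absent from the edge list: %s",
                    len(missing), missing)
    candidates = set(seed_set)
    for s in seed_set:
        if s in interactions:
            candidates.update(interactions.neighbors(s))

    frame = de_wt.frame
    retained = {}
    for g in sorted(candidates):
        if g not in frame.index:
            continue
        row = frame.loc[g]
        fdr, log2fc = float(row["fdr"]), float(row["log2fc"])
        if fdr >= config.alpha:
            continue
        if config.subnet_fold_change_gate and abs(log2fc) <= config.log2fc_min:
            continue
        retained[g] = log2fc

    graph = nx.Graph()
    for g, log2fc in retained.items():
        attrs = {
            "is_seed": g in seed_set,
            "log2fc": log2fc,
            "direction": "up" if log2fc > 0 else "down",
        }
        if de_ko is not None and g in de_ko.frame.index:
            attrs["ko_log2fc"] = float(de_ko.frame.loc[g, "log2fc"])
        graph.add_node(g, **attrs)
    for a, b in interactions.edges:
        if a in retained and b in retained:
            graph.add_edge(a, b)

    dropped = tuple(sorted(seed_set - set(retained)))
    if not retained:
        log.warning("subnetwork is empty: no candidate passed the DE filter")
    if dropped:
        log.info("%d seed(s) dropped by the DE filter", len(dropped))
    return Subnetwork(graph=graph, dropped_seeds=dropped)
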