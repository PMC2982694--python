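"""Assembly of the background molecular interaction network.

The background network integrates three heterogeneous interaction sources —
protein–protein interactions (PPI), protein–DNA (transcription factor →
target) interactions, and curated signaling-pathway edges — into a single
undirected graph G = (V, E, W).  PPI edges are kept only when supported by a
minimum number of distinct experimental methods; the integrated graph is then
restricted to genes actually expressed on the array platform, and its largest
weakly connected component becomes the background for subnetwork detection.

Protein–DNA and signaling edges are directed as loaded, but the network
stores every edge as an unordered pair: the downstream flow model sends flow
in both directions along each interaction, so only undirected reachability
matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

SOURCE_TYPES = ("ppi", "protein_dna", "signaling")


def _norm_symbol(symbol: str) -> str:
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("gene symbol must be non-empty")
    return s


@dataclass(frozen=True)
class InteractionRecord:
    """One raw interaction edge with its provenance.

    ``evidence_count`` is the number of distinct experimental methods
    supporting the edge; it is meaningful for PPI records and defaults to 0
    for the other sources.
    """

    gene_a: str
    gene_b: str
    source_type: str = "ppi"
    evidence_count: int = 0
    directed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_a", _norm_symbol(self.gene_a))
        object.__setattr__(self, "gene_b", _norm_symbol(self.gene_b))
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}")
        if self.evidence_count < 0:
            raise ValueError("evidence_count must be >= 0")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair, lexicographically sorted."""
        return tuple(sorted((self.gene_a, self.gene_b)))


class MolecularNetwork:
    """Undirected molecular interaction graph with optional node weights.

    Thin wrapper around :class:`networkx.Graph` enforcing the invariants of
    the background network: no self-loops, no duplicate edges, non-negative
    node weights defined only on member genes.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "MolecularNetwork":
        g = nx.Graph()
        g.add_nodes_from(_norm_symbol(n) for n in nodes)
        for a, b in edges:
            a, b = _norm_symbol(a), _norm_symbol(b)
            if a != b:
                g.add_edge(a, b)
        return cls(g)

    # -- views ------------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    # -- weights ----------------------------------------------------------
    @property
    def node_weights(self) -> dict[str, float] | None:
        w = nx.get_node_attributes(self.graph, "weight")
        return w or None

    def set_weights(self, weights: Mapping[str, float], missing: float = 0.0) -> None:
        """Attach node weights; genes absent from ``weights`` get ``missing``.

        Raises if any weight is negative or refers to a non-member gene.
        """
        unknown = set(weights) - self.nodes
        if unknown:
            raise ValueError(f"weights refer to genes outside the network: {sorted(unknown)[:5]}")
        for g in self.graph.nodes:
            w = float(weights.get(g, missing))
            if w < 0:
                raise ValueError(f"negative weight for {g}")
            self.graph.nodes[g]["weight"] = w

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"MolecularNetwork(|V|={self.n_nodes}, |E|={self.n_edges})"


def clean_ppi(
    records: Iterable[InteractionRecord], min_methods: int = 2
) -> list[InteractionRecord]:
    """Filter raw PPI records: drop self-interactions, collapse duplicates
    (keeping the maximum evidence count), and keep only pairs supported by at
    least ``min_methods`` distinct experimental methods.
    """
    best: dict[tuple[str, str], InteractionRecord] = {}
    for rec in records:
        if rec.source_type != "ppi":
            raise ValueError("clean_ppi expects ppi records only")
        if rec.gene_a == rec.gene_b:
            continue
        key = rec.pair
        prev = best.get(key)
        if prev is None or rec.evidence_count > prev.evidence_count:
            best[key] = rec
    return [r for _, r in sorted(best.items()) if r.evidence_count >= min_methods]


def integrate(
    ppi: Iterable[InteractionRecord],
    pdi: Iterable[InteractionRecord] = (),
    signaling: Iterable[InteractionRecord] = (),
) -> MolecularNetwork:
    """Merge the three edge sets into one undirected network.

    Duplicate edges across sources collapse to a single undirected edge; the
    contributing source types are kept in the ``sources`` edge attribute for
    provenance.  Self-loops from any source are dropped.
    """
    g = nx.Graph()
    for rec in (*ppi, *pdi, *signaling):
        if rec.gene_a == rec.gene_b:
            continue
        a, b = rec.pair
        if g.has_edge(a, b):
            srcs = g.edges[a, b]["sources"]
            if rec.source_type not in srcs:
                srcs.append(rec.source_type)
        else:
            g.add_edge(a, b, sources=[rec.source_type])
    return MolecularNetwork(g)


def restrict_to_expressed(
    net: MolecularNetwork, expressed: Iterable[str]
) -> MolecularNetwork:
    """Induced subgraph on genes observed as expressed in the array data.

    Isolated nodes are retained here; the component step prunes them.
    """
    keep = net.nodes & {_norm_symbol(g) for g in expressed}
    return MolecularNetwork(net.graph.subgraph(keep).copy())


def largest_component(net: MolecularNetwork) -> MolecularNetwork:
    """Largest weakly connected component of the integrated network.

    All edges are treated as undirected.  Ties on component size are broken
    toward the component containing the lexicographically smallest gene
    symbol, so the result is deterministic.
    """
    if net.n_nodes == 0:
        logger.warning("largest_component called on an empty network")
        return MolecularNetwork()
    comps = list(nx.connected_components(net.graph))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    return MolecularNetwork(net.graph.subgraph(best).copy())


def build_background_network(
    ppi: Iterable[InteractionRecord],
    pdi: Iterable[InteractionRecord],
    signaling: Iterable[InteractionRecord],
    expressed: Iterable[str] | None = None,
    min_methods: int = 2,
) -> MolecularNetwork:
    """Full pipeline: clean PPI -> integrate -> restrict -> largest component."""
    net = integrate(clean_ppi(ppi, min_methods=min_methods), pdi, signaling)
    if expressed is not None:
        net = restrict_to_expressed(net, expressed)
    return largest_component(net)
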