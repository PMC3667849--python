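"""Pathway networks: graph containers, topological node weights, distances.

A biochemical pathway is represented as a directed graph of gene nodes.
Signal typically flows from receptor-like entry points toward a small set
of "terminus" nodes (out-degree zero) that trigger transcription; genes
near a terminus receive larger topological weight, and gene-gene proximity
is measured by undirected shortest-path distance on the same graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "PathwayNetwork",
    "NodeWeighting",
    "DistanceTable",
    "OrthologyMap",
    "PathwayCollection",
    "LoadReport",
    "PathwayParseError",
    "EmptyPanelError",
    "load_pathways",
    "load_gmt",
    "gmt_to_networks",
    "node_weights",
    "pairwise_distances",
    "shared_panel",
    "write_pathways_tsv",
]


class PathwayParseError(ValueError):
    """Raised for malformed rows in a pathway edge-list file."""


class EmptyPanelError(ValueError):
    """Raised when no pathway is shared by all requested species."""


@dataclass(frozen=True)
class PathwayNetwork:
    """One pathway as a directed graph of gene nodes.

    Undirected interactions are stored as two ordered pairs.  Self-loops
    are disallowed; every edge endpoint must be a node.
    """

    pathway_id: str
    species: str
    nodes: frozenset
    edges: frozenset  # of (source, target) tuples
    category: str | None = None

    def __post_init__(self):
        if not self.nodes:
            raise ValueError(f"pathway {self.pathway_id!r}: empty node set")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"pathway {self.pathway_id!r}: self-loop at {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(
                    f"pathway {self.pathway_id!r}: edge ({u!r},{v!r}) endpoint not in nodes"
                )

    def to_directed(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class NodeWeighting:
    pathway_id: str
    weights: Mapping[str, float]

    def __post_init__(self):
        for v, w in self.weights.items():
            if not w >= 1.0:
                raise ValueError(f"weight for {v!r} is {w}, must be >= 1")


class DistanceTable:
    """Symmetric unweighted shortest-path distances within one pathway.

    Disconnected pairs are ``math.inf`` — carried explicitly so proximity
    kernels can map disconnection to zero affinity.
    """

    def __init__(self, pathway_id: str, distances: Mapping[tuple, int]):
        self.pathway_id = pathway_id
        self._d = {}
        for (u, v), d in distances.items():
            key = (u, v) if u <= v else (v, u)
            self._d[key] = d

    def get(self, u, v) -> float:
        if u == v:
            return 0
        key = (u, v) if u <= v else (v, u)
        return self._d.get(key, math.inf)

    def items(self):
        return self._d.items()


@dataclass
class OrthologyMap:
    """Maps (species, species-local gene id) to a canonical ortholog token."""

    pairs: Mapping[tuple, str] = field(default_factory=dict)

    def canonical(self, species: str, gene: str) -> str:
        return self.pairs.get((species, gene), gene)


@dataclass
class LoadReport:
    n_rows: int = 0
    n_edges: int = 0
    n_self_loops_skipped: int = 0
    n_duplicates_collapsed: int = 0


class PathwayCollection(dict):
    """Mapping pathway_id -> PathwayNetwork for one species, plus a load report."""

    def __init__(self, networks: Iterable[PathwayNetwork] = (), report: LoadReport | None = None):
        super().__init__()
        for net in networks:
            if net.pathway_id in self:
                raise ValueError(f"duplicate pathway_id {net.pathway_id!r}")
            self[net.pathway_id] = net
        self.report = report or LoadReport()


_DIRECTIONS = {"directed", "undirected"}


def load_pathways(path, species: str) -> PathwayCollection:
    """Read a tab-separated edge list into per-pathway networks.

    Expected columns: pathway_id, source_gene, target_gene, direction
    (``directed`` or ``undirected``).  Undirected rows expand to two
    ordered pairs; duplicate rows collapse; self-loop rows are skipped and
    counted in the collection's load report.
    """
    report = LoadReport()
    edges: dict[str, set] = {}
    seen_rows: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:1] == ["pathway_id"]:
                continue  # optional header
            if len(parts) != 4:
                raise PathwayParseError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            pid, src, tgt, direction = (p.strip() for p in parts)
            if not pid or not src or not tgt or direction not in _DIRECTIONS:
                raise PathwayParseError(
                    f"{path}: line {lineno}: malformed row {parts!r}"
                )
            report.n_rows += 1
            if src == tgt:
                report.n_self_loops_skipped += 1
                continue
            row_key = (pid, src, tgt, direction)
            if row_key in seen_rows:
                report.n_duplicates_collapsed += 1
                continue
            seen_rows.add(row_key)
            bucket = edges.setdefault(pid, set())
            bucket.add((src, tgt))
            if direction == "undirected":
                bucket.add((tgt, src))
    networks = []
    for pid in sorted(edges):
        e = frozenset(edges[pid])
        nodes = frozenset(u for pair in e for u in pair)
        networks.append(PathwayNetwork(pid, species, nodes, e))
        report.n_edges += len(e)
    return PathwayCollection(networks, report)


def load_gmt(path) -> dict:
    """Read a GMT file: pathway_id <tab> description <tab> gene...

    Returns mapping pathway_id -> (description, tuple of genes).
    """
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PathwayParseError(
                    f"{path}: line {lineno}: GMT rows need id, description and >=1 gene"
                )
            pid, desc, genes = parts[0], parts[1], tuple(g for g in parts[2:] if g)
            if pid in out:
                raise PathwayParseError(f"{path}: line {lineno}: duplicate set {pid!r}")
            out[pid] = (desc, genes)
    return out


def gmt_to_networks(gmt: Mapping[str, tuple], species: str) -> PathwayCollection:
    """Edge-free fallback: each gene set becomes a network with no edges.

    With no edges every node is a terminus, so node weights are uniform and
    all pairwise distances are infinite (the proximity term degenerates to 1).
    """
    nets = [
        PathwayNetwork(pid, species, frozenset(genes), frozenset())
        for pid, (_desc, genes) in gmt.items()
    ]
    return PathwayCollection(nets)


def node_weights(net: PathwayNetwork, lam: float = 1.0) -> NodeWeighting:
    """Topological node weights increasing toward pathway termini.

    Termini are nodes with out-degree 0.  With d_T(v) the directed
    shortest-path length from v to the nearest terminus and D the largest
    finite d_T, weight(v) = 1 + lam * (1 - d_T(v) / D).  Nodes that cannot
    reach a terminus weigh 1; if there is no terminus all weights are 1;
    if D == 0 termini weigh 1 + lam and all other nodes 1.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    g = net.to_directed()
    termini = [v for v in g if g.out_degree(v) == 0]
    weights = {v: 1.0 for v in g}
    if termini:
        # distance *to* a terminus == distance *from* termini on the reverse graph
        d_t = nx.multi_source_dijkstra_path_length(g.reverse(copy=False), termini)
        finite_max = max(d_t.values())
        if finite_max == 0:
            for v in termini:
                weights[v] = 1.0 + lam
        else:
            for v, d in d_t.items():
                weights[v] = 1.0 + lam * (1.0 - d / finite_max)
    return NodeWeighting(net.pathway_id, weights)


def pairwise_distances(net: PathwayNetwork) -> DistanceTable:
    """Unweighted shortest-path lengths on the underlying undirected graph."""
    g = net.to_undirected()
    dists = {}
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        for v, d in lengths.items():
            if u < v:
                dists[(u, v)] = d
    return DistanceTable(net.pathway_id, dists)


def shared_panel(
    collections: Mapping[str, PathwayCollection],
    orthology: OrthologyMap | None = None,
) -> list:
    """Lexicographically sorted pathway ids present in every species.

    The returned order fixes feature-column order for every downstream
    feature matrix, so train and prediction panels always align.
    """
    if not collections:
        raise ValueError("at least one species collection is required")
    species = list(collections)
    shared = set(collections[species[0]])
    for sp in species[1:]:
        shared &= set(collections[sp])
    if not shared:
        raise EmptyPanelError(
            f"no pathway is shared by all of {species!r}"
        )
    return sorted(shared)


def write_pathways_tsv(collection: PathwayCollection, path) -> None:
    """Write networks back to the edge-list TSV format read by load_pathways.

    All edges are emitted as directed rows (an undirected interaction was
    already expanded to two ordered pairs on load).
    """
    rows = []
    for pid in sorted(collection):
        for u, v in sorted(collection[pid].edges):
            rows.append((pid, u, v, "directed"))
    pd.DataFrame(rows, columns=["pathway_id", "source_gene", "target_gene", "direction"]).to_csv(
        path, sep="\t", index=False
    )
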