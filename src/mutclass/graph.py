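"""Weighted undirected gene-interaction graph.

Edges carry confidence weights in (0, 1], mirroring protein-protein
interaction networks where the weight reflects the evidence for the
interaction.  Internally the graph keeps adjacency in CSR-like arrays so
random walks can sample neighbors cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io


@dataclass
class WeightedGraph:
    nodes: list[str]
    edges: list[tuple[str, str, float]]
    _index: dict[str, int] = field(init=False, repr=False)
    _adj: list[list[int]] = field(init=False, repr=False)
    _adj_w: list[np.ndarray] = field(init=False, repr=False)
    _adj_cum: list[np.ndarray] = field(init=False, repr=False)
    _neighbor_sets: list[set[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        adj: list[list[int]] = [[] for _ in self.nodes]
        wts: list[list[float]] = [[] for _ in self.nodes]
        seen: set[tuple[int, int]] = set()
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge weight {w} outside (0, 1]")
            ia, ib = self._index[a], self._index[b]
            key = (min(ia, ib), max(ia, ib))
            if key in seen:
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            seen.add(key)
            adj[ia].append(ib)
            adj[ib].append(ia)
            wts[ia].append(w)
            wts[ib].append(w)
        self._adj = adj
        self._adj_w = [np.asarray(w, dtype=float) for w in wts]
        self._adj_cum = [np.cumsum(w) for w in self._adj_w]
        self._neighbor_sets = [set(a) for a in adj]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return len(self._adj[self._index[node]])

    def neighbors(self, node: str) -> list[str]:
        return [self.nodes[j] for j in self._adj[self._index[node]]]

    def has_node(self, node: str) -> bool:
        return node in self._index

    def write_tsv(self, path: str | Path) -> None:
        _io.write_edge_list(self.edges, path)

    @staticmethod
    def read_tsv(path: str | Path, nodes: list[str] | None = None) -> "WeightedGraph":
        edges = _io.read_edge_list(path)
        if nodes is None:
            nodes = sorted({g for a, b, _ in edges for g in (a, b)})
        return WeightedGraph(nodes=nodes, edges=edges)

    def to_networkx(self):
        """Export to a networkx Graph (for inspection/plotting)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g
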