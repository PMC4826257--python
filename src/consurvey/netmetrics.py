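"""Node topology metrics of an undirected PPI network.

Four per-node metrics over a simple undirected graph:

* degree k -- number of direct neighbors;
* clustering coefficient CC_v = 2 e_v / (k (k - 1)), with e_v the edge
  count among v's neighbors, and CC_v = 0 for k < 2;
* normalized betweenness B_v = [sum over ordered pairs i != j (both
  != v) of sigma_ivj / sigma_ij] / ((n - 1)(n - 2)), where sigma_ij
  counts i -> j shortest paths and sigma_ivj those through v, computed
  with Brandes' accumulation; unreachable pairs contribute 0; the
  normalization uses the whole-graph n even on disconnected graphs;
* average shortest path length -- mean hop distance from v to every
  node reachable from v; NaN for isolated nodes (excluded downstream).
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genesets import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "NodeTopology",
    "read_edge_list",
    "betweenness",
    "clustering_coefficient",
    "avg_shortest_path",
    "degree",
    "topology_table",
]


class InteractionNetwork:
    """Simple undirected graph of protein/gene identifiers."""

    def __init__(self, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()):
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        n_loops = n_dups = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                continue
            if u in adj and v in adj[u]:
                n_dups += 1
                continue
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        if n_loops:
            logger.warning("dropped %d self-loops", n_loops)
        if n_dups:
            logger.warning("collapsed %d duplicate edges", n_dups)
        self._adj = adj

    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    @property
    def n(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def neighbors(self, node: str) -> set[str]:
        return self._adj[node]

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (u, v) for u, nbrs in self._adj.items() for v in nbrs if u < v
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v in self.edges():
                fh.write(f"{u}\t{v}\n")


@dataclass(frozen=True)
class NodeTopology:
    node: str
    degree: int
    clustering_coefficient: float
    betweenness: float
    avg_shortest_path: float  # NaN when the node is isolated


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a two-column TSV edge list; ``#`` lines skipped."""
    path = Path(path)
    edges = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        u, v = (f.strip() for f in fields)
        if not u or not v:
            raise ValueError(f"{path}:{lineno}: empty node identifier")
        edges.append((u, v))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return InteractionNetwork(edges)


def degree(net: InteractionNetwork) -> dict[str, int]:
    return {v: len(net.neighbors(v)) for v in net.nodes}


def clustering_coefficient(net: InteractionNetwork) -> dict[str, float]:
    out = {}
    for v in net.nodes:
        nbrs = net.neighbors(v)
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        e_v = sum(len(net.neighbors(u) & nbrs) for u in nbrs) // 2
        out[v] = 2.0 * e_v / (k * (k - 1))
    return out


def betweenness(net: InteractionNetwork) -> dict[str, float]:
    """Normalized betweenness by Brandes' algorithm (unweighted BFS).

    Summing dependencies over every source counts each ordered pair
    (i, j) exactly once, so dividing by (n-1)(n-2) yields the
    ordered-pair normalization.
    """
    n = net.n
    if n < 3:
        raise ValueError("betweenness normalization requires at least 3 nodes")
    cb = {v: 0.0 for v in net.nodes}
    for s in net.nodes:
        # single-source shortest-path counts
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in net._adj}
        sigma = {v: 0.0 for v in net._adj}
        dist = {v: -1 for v in net._adj}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in net.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in net._adj}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
    scale = 1.0 / ((n - 1) * (n - 2))
    return {v: cb[v] * scale for v in cb}


def avg_shortest_path(net: InteractionNetwork) -> dict[str, float]:
    """Mean BFS hop distance from each node to its reachable nodes."""
    out = {}
    for s in net.nodes:
        dist = {s: 0}
        queue = deque([s])
        total = count = 0
        while queue:
            v = queue.popleft()
            for w in net.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    total += dist[w]
                    count += 1
                    queue.append(w)
        out[s] = total / count if count else math.nan
    return out


def topology_table(net: InteractionNetwork, genes: GeneSet) -> list[NodeTopology]:
    """All four metrics for each gene present as a network node."""
    present = sorted(g for g in genes.genes if g in net)
    n_absent = len(genes) - len(present)
    if n_absent:
        logger.warning(
            "topology_table(%s): %d genes absent from the network", genes.label, n_absent
        )
    if not present:
        return []
    deg = degree(net)
    cc = clustering_coefficient(net)
    btw = betweenness(net)
    aspl = avg_shortest_path(net)
    return [
        NodeTopology(
            node=g,
            degree=deg[g],
            clustering_coefficient=cc[g],
            betweenness=btw[g],
            avg_shortest_path=aspl[g],
        )
        for g in present
    ]
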