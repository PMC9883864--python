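"""Sequence-similarity graph construction and ego-graph extraction.

Nodes are sequences; an undirected edge joins i and j whenever the cosine
similarity of their similarity features reaches the threshold tau (ties at
exactly tau create an edge).  Node features used downstream by the classifier
may differ from the features used for similarity; by default they are the
same matrix.  Isolated nodes are permitted — they are how unseen sequences
with no close relative enter the graph.

Each node's local (ego) graph is the per-sample unit fed to the classifier:
in 1-layer mode it is the center, its direct neighbors, and only the center's
incident edges (a star); 2-layer mode additionally pulls in the neighbors'
neighbors and the edges that connect the first layer outward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

__all__ = [
    "GraphError",
    "SimilarityGraph",
    "LocalGraph",
    "GraphStats",
    "cosine_similarity",
    "build_similarity_graph",
    "graph_stats",
    "extract_local_graphs",
    "write_edge_list",
    "write_graph_stats",
]


class GraphError(ValueError):
    pass


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (|a||b|); undefined (error) for a zero vector."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GraphError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise GraphError("cosine similarity is undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclass
class SimilarityGraph:
    """G = (V, E, X) with labels Y and the threshold tau that built E.

    ``edges`` is an (m, 2) int array with i < j per row; ``edge_similarities``
    carries the cosine similarity of each edge's endpoints.
    """

    node_ids: list[str]
    features: np.ndarray  # |V| x d node features (classifier input)
    labels: np.ndarray  # |V| array of compartment names (object dtype)
    edges: np.ndarray  # m x 2, each row (i, j) with i < j
    edge_similarities: np.ndarray  # m
    tau: float
    provenance: np.ndarray | None = None  # |V| array of "real"/"synthetic"
    _adjacency: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency[i]

    @property
    def adjacency(self) -> list[np.ndarray]:
        if self._adjacency is None:
            lists: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, j in self.edges:
                lists[int(i)].append(int(j))
                lists[int(j)].append(int(i))
            self._adjacency = [np.array(sorted(l), dtype=int) for l in lists]
        return self._adjacency


@dataclass
class LocalGraph:
    """Ego graph around one node; the unit sample for meta-learning episodes.

    ``members`` are global node indices with the center first; ``edges`` are
    pairs of *local* member positions.  Features are views into the parent
    graph's matrix, so holding all |V| local graphs costs no feature copies.
    """

    center: int  # global node index
    members: np.ndarray  # global node indices, members[0] == center
    edges: np.ndarray  # (m, 2) local positions into members
    graph: SimilarityGraph = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.members)

    @property
    def X(self) -> np.ndarray:
        return self.graph.features[self.members]

    @property
    def label(self) -> str:
        return str(self.graph.labels[self.center])

    @property
    def provenance(self) -> str:
        if self.graph.provenance is None:
            return "real"
        return str(self.graph.provenance[self.center])


@dataclass(frozen=True)
class GraphStats:
    """Connectivity summary: isolated nodes, edges, same-label edge fraction.

    ``key_edge_fraction`` — the share of edges whose endpoints carry the same
    compartment label — is None for an edgeless graph.
    """

    isolated_count: int
    edge_count: int
    key_edge_fraction: float | None


def build_similarity_graph(
    features: np.ndarray,
    labels: Sequence[str],
    tau: float,
    similarity_features: np.ndarray | None = None,
    node_ids: Sequence[str] | None = None,
    provenance: Sequence[str] | None = None,
) -> SimilarityGraph:
    """Threshold graph: edge (i, j) iff cos(l_i, l_j) >= tau.

    Similarity is computed on ``similarity_features`` (defaults to
    ``features``); node features stored on the graph are ``features``.
    """
    if not -1.0 <= tau <= 1.0:
        raise GraphError(f"tau must lie in [-1, 1], got {tau}")
    features = np.asarray(features, dtype=float)
    sim_feats = (
        features if similarity_features is None
        else np.asarray(similarity_features, dtype=float)
    )
    if sim_feats.shape[0] != features.shape[0]:
        raise GraphError("similarity_features must align with features")
    if len(labels) != features.shape[0]:
        raise GraphError("labels must align with features")
    norms = np.linalg.norm(sim_feats, axis=1)
    if np.any(norms == 0):
        bad = int(np.argmax(norms == 0))
        raise GraphError(f"node {bad} has a zero similarity-feature vector")

    sims = _sk_cosine(sim_feats)
    iu, ju = np.triu_indices(len(sims), k=1)
    keep = sims[iu, ju] >= tau
    edges = np.stack([iu[keep], ju[keep]], axis=1).astype(int)
    edge_sims = sims[iu[keep], ju[keep]]

    ids = list(node_ids) if node_ids is not None else [str(i) for i in range(len(labels))]
    prov = np.array(list(provenance), dtype=object) if provenance is not None else None
    return SimilarityGraph(
        node_ids=ids,
        features=features,
        labels=np.array(list(labels), dtype=object),
        edges=edges,
        edge_similarities=np.asarray(edge_sims, dtype=float),
        tau=float(tau),
        provenance=prov,
    )


def graph_stats(g: SimilarityGraph) -> GraphStats:
    degree = np.zeros(g.n_nodes, dtype=int)
    for i, j in g.edges:
        degree[i] += 1
        degree[j] += 1
    isolated = int(np.sum(degree == 0))
    if g.n_edges == 0:
        return GraphStats(isolated, 0, None)
    same = sum(1 for i, j in g.edges if g.labels[i] == g.labels[j])
    return GraphStats(isolated, g.n_edges, same / g.n_edges)


def extract_local_graphs(g: SimilarityGraph, layers: int = 1) -> list[LocalGraph]:
    """One ego graph per node, in node order.

    layers=1: center + direct neighbors, only the center's incident edges.
    layers=2: additionally the neighbors' neighbors, plus every edge linking
    the center/first layer to a member.
    """
    if layers not in (1, 2):
        raise GraphError("layers must be 1 or 2")
    adj = g.adjacency
    out: list[LocalGraph] = []
    for c in range(g.n_nodes):
        first = adj[c]
        if layers == 1:
            members = np.concatenate([[c], first]).astype(int)
            local_edges = np.array(
                [[0, p] for p in range(1, len(members))], dtype=int
            ).reshape(-1, 2)
        else:
            second: set[int] = set()
            for nb in first:
                second.update(int(x) for x in adj[nb])
            member_set = {int(c), *map(int, first), *second}
            rest = sorted(member_set - {int(c)})
            members = np.array([c] + rest, dtype=int)
            pos = {int(m): p for p, m in enumerate(members)}
            inner = {int(c), *map(int, first)}
            seen: set[tuple[int, int]] = set()
            pairs: list[list[int]] = []
            for u in sorted(inner):
                for v in adj[u]:
                    v = int(v)
                    if v not in pos:
                        continue
                    key = (min(u, v), max(u, v))
                    if key in seen:
                        continue
                    seen.add(key)
                    pairs.append([pos[key[0]], pos[key[1]]])
            local_edges = np.array(pairs, dtype=int).reshape(-1, 2)
        out.append(LocalGraph(center=int(c), members=members, edges=local_edges, graph=g))
    return out


def write_edge_list(g: SimilarityGraph, path: str | Path) -> None:
    """Edge list TSV: node_i, node_j, similarity."""
    with open(path, "w") as handle:
        handle.write("node_i\tnode_j\tsimilarity\n")
        for (i, j), s in zip(g.edges, g.edge_similarities):
            handle.write(f"{g.node_ids[int(i)]}\t{g.node_ids[int(j)]}\t{s:.6f}\n")


def write_graph_stats(stats: GraphStats, path: str | Path) -> None:
    payload = {
        "isolated_count": stats.isolated_count,
        "edge_count": stats.edge_count,
        "key_edge_fraction": stats.key_edge_fraction,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
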