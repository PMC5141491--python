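"""Minimum spanning tree reconstruction and topology descriptors.

Connectivity matrices are turned into trees by running Kruskal's
algorithm on the complete graph with link weight ``1 - PLI``, so the
tree keeps the strongest phase-coupled links while avoiding any
connectivity threshold. Four descriptors summarize where a tree sits on
the star-to-path axis:

* **leaf fraction** L/N — fraction of degree-1 nodes (high for a star);
* **diameter** — longest shortest path in links, normalized by N-1;
* **kappa** (degree divergence) <k^2>/<k> — broadness of the degree
  distribution;
* **tree hierarchy** Th = L / (2 (N-1) B_max) — balance between short
  paths and hub overload, with B_max the maximum betweenness centrality
  normalized by (N-1)(N-2)/2 so a star scores exactly 0.5.

A tree's distance to a reference topology (the MST of the control-group
average matrix) is the **dissimilarity** 1 - |shared edges| / (N-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "SpanningTree",
    "MSTMetrics",
    "build_mst",
    "leaf_fraction",
    "diameter",
    "kappa",
    "tree_hierarchy",
    "compute_metrics",
    "reference_tree",
    "mst_dissimilarity",
    "subject_mst_summary",
]

Edge = tuple[int, int]


@dataclass(frozen=True)
class SpanningTree:
    """An acyclic connected edge set over ``n_nodes`` labelled nodes."""

    n_nodes: int
    edges: frozenset[Edge]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        norm = frozenset((min(u, v), max(u, v)) for u, v in self.edges)
        object.__setattr__(self, "edges", norm)
        if len(norm) != self.n_nodes - 1:
            raise ValueError(
                f"spanning tree on {self.n_nodes} nodes needs {self.n_nodes - 1} edges, "
                f"got {len(norm)}"
            )
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("label count does not match n_nodes")
        # connectivity (and hence acyclicity, given the edge count)
        adj = self._adjacency()
        seen = [False] * self.n_nodes
        stack = [0]
        seen[0] = True
        count = 1
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    count += 1
                    stack.append(v)
        if count != self.n_nodes:
            raise ValueError("edge set is not connected")

    def _adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class MSTMetrics:
    """The four tree topology descriptors (plus optional dissimilarity)."""

    leaf_fraction: float
    diameter: float
    kappa: float
    hierarchy: float
    dissimilarity: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "leaf_fraction": self.leaf_fraction,
            "diameter": self.diameter,
            "kappa": self.kappa,
            "hierarchy": self.hierarchy,
        }
        if self.dissimilarity is not None:
            d["dissimilarity"] = self.dissimilarity
        return d


def build_mst(matrix: ConnectivityMatrix) -> SpanningTree:
    """Kruskal MST of the complete graph with weight 1 - PLI.

    Edges are inserted in lexicographic (i, j) order; Kruskal's stable
    sort then breaks weight ties deterministically on (smaller label,
    larger label).
    """
    w = matrix.weights
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=1.0 - w[i, j])
    t = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return SpanningTree(
        n_nodes=n,
        edges=frozenset((min(u, v), max(u, v)) for u, v in t.edges),
        labels=matrix.labels,
    )


def leaf_fraction(tree: SpanningTree) -> float:
    """Number of degree-1 nodes divided by the total number of nodes."""
    deg = tree.degrees()
    return float(np.sum(deg == 1) / tree.n_nodes)


def _bfs_depths(adj: list[list[int]], start: int) -> list[int]:
    depth = [-1] * len(adj)
    depth[start] = 0
    queue = [start]
    head = 0
    while head < len(queue):
        u = queue[head]
        head += 1
        for v in adj[u]:
            if depth[v] < 0:
                depth[v] = depth[u] + 1
                queue.append(v)
    return depth


def diameter(tree: SpanningTree, normalize: bool = True) -> float:
    """Longest shortest path in link count; divided by N-1 when normalized.

    On a tree the double-sweep BFS is exact: the farthest node from any
    start is an endpoint of a diametral path.
    """
    adj = tree._adjacency()
    d0 = _bfs_depths(adj, 0)
    far = int(np.argmax(d0))
    d1 = _bfs_depths(adj, far)
    diam = max(d1)
    return diam / (tree.n_nodes - 1) if normalize else float(diam)


def kappa(tree: SpanningTree) -> float:
    """Degree divergence <k^2>/<k>: N/2 for a star, -> 2 for a long path."""
    deg = tree.degrees()
    # <k^2>/<k> as a ratio of integer sums (the 1/N factors cancel), so
    # integer-valued cases (e.g. a star) are exact in floating point.
    return float(int(np.sum(deg**2)) / int(np.sum(deg)))


def _max_betweenness(tree: SpanningTree) -> float:
    """Maximum betweenness centrality, normalized by (N-1)(N-2)/2.

    On a tree every pair is joined by a unique path, so the betweenness
    of node v is the number of node pairs lying in different components
    of tree - v: ((N-1)^2 - sum_c s_c^2) / 2 with s_c the component
    sizes. Computed for all nodes in O(N) from rooted subtree sizes.
    """
    n = tree.n_nodes
    adj = tree._adjacency()
    parent = [-1] * n
    order: list[int] = []
    stack = [0]
    seen = [False] * n
    seen[0] = True
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    size = [1] * n
    for u in reversed(order):
        if parent[u] >= 0:
            size[parent[u]] += size[u]
    best = 0.0
    for v in range(n):
        comp_sq = 0
        child_total = 0
        for u in adj[v]:
            s = size[u] if parent[u] == v else n - size[v]
            comp_sq += s * s
            child_total += s
        assert child_total == n - 1
        pairs_through = ((n - 1) ** 2 - comp_sq) / 2
        best = max(best, pairs_through)
    return best / ((n - 1) * (n - 2) / 2)


def tree_hierarchy(tree: SpanningTree) -> float:
    """Th = L / (2 M B_max) with L leaves, M = N-1 edges, B_max in [0, 1].

    Exactly 0.5 for a star of any size (hub betweenness 1); decreases
    toward 0 along increasingly path-like trees.
    """
    if tree.n_nodes < 3:
        raise ValueError("tree hierarchy is undefined for fewer than 3 nodes")
    leaves = int(np.sum(tree.degrees() == 1))
    m = tree.n_nodes - 1
    b_max = _max_betweenness(tree)
    return leaves / (2 * m * b_max)


def compute_metrics(
    tree: SpanningTree,
    reference: SpanningTree | None = None,
    normalize_diameter: bool = True,
) -> MSTMetrics:
    """All four descriptors of one tree, plus dissimilarity if a reference is given."""
    return MSTMetrics(
        leaf_fraction=leaf_fraction(tree),
        diameter=diameter(tree, normalize=normalize_diameter),
        kappa=kappa(tree),
        hierarchy=tree_hierarchy(tree),
        dissimilarity=None if reference is None else mst_dissimilarity(tree, reference),
    )


def reference_tree(control_matrices: list[ConnectivityMatrix]) -> SpanningTree:
    """MST of the element-wise mean of the control matrices (subjects x epochs)."""
    if not control_matrices:
        raise ValueError("need at least one control matrix")
    dims = {m.n_channels for m in control_matrices}
    if len(dims) > 1:
        raise ValueError(f"control matrices differ in dimension: {sorted(dims)}")
    mean_w = np.mean([m.weights for m in control_matrices], axis=0)
    mean_mat = ConnectivityMatrix(
        weights=mean_w,
        labels=control_matrices[0].labels,
        band=control_matrices[0].band,
    )
    return build_mst(mean_mat)


def mst_dissimilarity(tree: SpanningTree, reference: SpanningTree) -> float:
    """1 - |shared edges| / (N-1): 0 for identical trees, 1 for edge-disjoint."""
    if tree.n_nodes != reference.n_nodes:
        raise ValueError("trees are defined over different node sets")
    if (
        tree.labels is not None
        and reference.labels is not None
        and tree.labels != reference.labels
    ):
        raise ValueError("trees are defined over different channel labels")
    shared = len(tree.edges & reference.edges)
    return 1.0 - shared / (tree.n_nodes - 1)


def subject_mst_summary(
    matrices: list[ConnectivityMatrix],
    reference: SpanningTree | None = None,
    normalize_diameter: bool = True,
    aggregation: str = "epoch_metrics",
) -> tuple[list[MSTMetrics], MSTMetrics]:
    """Per-epoch tree metrics and their subject-level aggregate.

    ``aggregation="epoch_metrics"`` (default) averages the per-epoch
    metric values; ``"mean_matrix"`` instead computes the metrics of the
    MST of the epoch-averaged matrix.
    """
    if not matrices:
        raise ValueError("need at least one epoch matrix")
    per_epoch = [
        compute_metrics(build_mst(m), reference, normalize_diameter) for m in matrices
    ]
    if aggregation == "epoch_metrics":
        def agg(name: str) -> float:
            return float(np.mean([getattr(m, name) for m in per_epoch]))

        subject = MSTMetrics(
            leaf_fraction=agg("leaf_fraction"),
            diameter=agg("diameter"),
            kappa=agg("kappa"),
            hierarchy=agg("hierarchy"),
            dissimilarity=(
                float(np.mean([m.dissimilarity for m in per_epoch]))
                if reference is not None
                else None
            ),
        )
    elif aggregation == "mean_matrix":
        subject = compute_metrics(
            build_mst(
                ConnectivityMatrix(
                    weights=np.mean([m.weights for m in matrices], axis=0),
                    labels=matrices[0].labels,
                    band=matrices[0].band,
                )
            ),
            reference,
            normalize_diameter,
        )
    else:
        raise ValueError(f"unknown aggregation mode {aggregation!r}")
    return per_epoch, subject
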