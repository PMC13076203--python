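"""The directed "can-represent" graph and its clustering algorithms.

A directed edge A→B means sequence A can represent sequence B under the
clustering criterion.  Greedy vertex cover repeatedly selects the live node
with the highest live outdegree as a representative and absorbs its
depth-bounded out-neighborhood as a cluster; infinite depth corresponds to
(weakly) connected components.
"""

from __future__ import annotations

import heapq
from typing import Iterable, Mapping, Optional, Union

import networkx as nx

from .errors import IntegrityError, ParameterError
from .pairwise import AlignmentHit, ClusterCriterion, edge_directions
from .seqio import Clustering, SequenceDB


class AlignGraph:
    """Directed graph over sequence ids with per-node lengths.

    Self-loops are never stored (every node can trivially represent itself);
    lengths participate in the deterministic tie-break when selecting
    representatives.
    """

    def __init__(
        self,
        nodes: Union[Mapping[str, int], Iterable[str]],
        edges: Iterable[tuple[str, str]] = (),
    ):
        if isinstance(nodes, Mapping):
            self._length = dict(nodes)
        else:
            self._length = {n: 0 for n in nodes}
        self._out: dict[str, set[str]] = {n: set() for n in self._length}
        self._in: dict[str, set[str]] = {n: set() for n in self._length}
        for a, b in edges:
            self.add_edge(a, b)

    def add_edge(self, a: str, b: str) -> None:
        if a not in self._length or b not in self._length:
            raise IntegrityError(f"edge ({a!r}, {b!r}) references unknown node")
        if a == b:
            return
        self._out[a].add(b)
        self._in[b].add(a)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._length)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((a, b) for a, outs in self._out.items() for b in outs)

    def n_edges(self) -> int:
        return sum(len(v) for v in self._out.values())

    def out_degree(self, node: str) -> int:
        return len(self._out[node])

    def out_neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self._out[node])

    def length_of(self, node: str) -> int:
        return self._length[node]


def build_graph(
    db: Union[SequenceDB, Mapping[str, int], Iterable[str]],
    hits: Iterable[AlignmentHit],
    criterion: ClusterCriterion,
) -> AlignGraph:
    """Encode accepted alignments as directed can-represent edges.

    In bi-directional mode a passing alignment yields both directions; in
    uni-directional mode A→B requires coverage of B only.  Isolated nodes
    are kept so the clustering covers every input id.
    """
    if isinstance(db, SequenceDB):
        nodes: Mapping[str, int] = {rec.id: rec.length for rec in db}
    elif isinstance(db, Mapping):
        nodes = db
    else:
        nodes = {n: 0 for n in db}
    graph = AlignGraph(nodes)
    for hit in hits:
        for rep, member in edge_directions(hit, criterion):
            graph.add_edge(rep, member)
    return graph


def greedy_vertex_cover(
    graph: AlignGraph,
    depth: int = 1,
    return_paths: bool = False,
):
    """Cluster by repeatedly absorbing the highest-outdegree neighborhood.

    Each iteration selects the live node with maximal live outdegree (ties:
    longer sequence, then lexicographically smaller id), forms a cluster
    from the nodes reachable within ``depth`` directed hops over live nodes,
    and removes them.  Outdegrees are maintained over live nodes only.

    With ``return_paths`` the directed path (representative ... member)
    recorded at extraction time is returned for every member.
    """
    if depth < 1:
        raise ParameterError("search depth must be >= 1")
    live = set(graph.nodes)
    outdeg = {n: graph.out_degree(n) for n in live}
    heap = [(-outdeg[n], -graph.length_of(n), n) for n in live]
    heapq.heapify(heap)
    assignment: dict[str, str] = {}
    paths: dict[str, list[str]] = {}
    while heap:
        negdeg, _, rep = heapq.heappop(heap)
        if rep not in live or -negdeg != outdeg[rep]:
            continue  # stale heap entry
        # breadth-first expansion over live nodes up to `depth` hops
        cluster = {rep}
        parent = {rep: None}
        frontier = [rep]
        for _ in range(depth):
            nxt = []
            for u in frontier:
                for v in graph.out_neighbors(u):
                    if v in live and v not in cluster:
                        cluster.add(v)
                        parent[v] = u
                        nxt.append(v)
            if not nxt:
                break
            frontier = nxt
        for member in cluster:
            assignment[member] = rep
            if return_paths:
                path = [member]
                while parent[path[-1]] is not None:
                    path.append(parent[path[-1]])
                paths[member] = path[::-1]
        live -= cluster
        touched = set()
        for member in cluster:
            for u in graph._in[member]:
                if u in live:
                    outdeg[u] -= 1
                    touched.add(u)
        for u in touched:
            heapq.heappush(heap, (-outdeg[u], -graph.length_of(u), u))
    clustering = Clustering(assignment)
    if return_paths:
        return clustering, paths
    return clustering


def connected_components(graph: AlignGraph) -> Clustering:
    """Weakly connected components (infinite search depth).

    The representative of a component is its longest member, ties broken by
    the lexicographically smaller id.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    assignment: dict[str, str] = {}
    for comp in nx.connected_components(g):
        rep = min(comp, key=lambda n: (-graph.length_of(n), n))
        for member in comp:
            assignment[member] = rep
    return Clustering(assignment)


def compose(outer: Clustering, inner: Clustering) -> Clustering:
    """Chain two clustering levels: member → inner rep → outer rep.

    ``outer`` must be a clustering of exactly the representatives of
    ``inner``.
    """
    if set(outer.assignment) != set(inner.representatives):
        raise IntegrityError(
            "outer clustering must cover exactly the inner representatives"
        )
    return Clustering(
        {member: outer.assignment[rep] for member, rep in inner.assignment.items()}
    )
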