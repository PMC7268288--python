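"""MCODE (Molecular Complex Detection) dense-cluster search on PPI graphs.

Stage 1 weights every vertex by ``k * density`` of the highest k-core of its
closed neighborhood (the k-core is the maximal subgraph of minimum degree k,
found by iterative minimum-degree peeling).  Stage 2 grows complexes outward
from the highest-weight unseen seed, admitting neighbors whose weight is
within a fraction ``vwp`` (vertex weight percentage) of the seed weight.
Stage 3 discards complexes lacking a 2-core, optionally shaves degree-1
members (haircut) and optionally adds back dense neighbors (fluff).  Each
complex is scored ``density * n_nodes`` — equivalently ``2E/(n-1)`` on a
simple graph — and complexes are reported in descending score order.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .netmodel import PPINetwork


@dataclass(frozen=True)
class MCODEParams:
    vwp: float = 0.2
    degree_cutoff: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.vwp < 1.0):
            raise ValueError("vwp must be in [0,1)")
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not (0.0 <= self.fluff_density <= 1.0):
            raise ValueError("fluff_density must be in [0,1]")


@dataclass
class Cluster:
    members: set[str]
    n_nodes: int
    n_edges: int
    score: float
    seed: str
    seed_weight: float
    rank: int = 0
    fluff_members: set[str] = field(default_factory=set)


def cluster_score(n_nodes: int, n_edges: int) -> float:
    """Complex score = density * size = 2E / (n - 1); zero for trivial complexes."""
    if n_nodes <= 1:
        return 0.0
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges exceed simple-graph maximum {max_edges} for {n_nodes} nodes")
    return 2.0 * n_edges / (n_nodes - 1)


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest nonempty k-core of g via core numbers (iterative peeling)."""
    if g.number_of_nodes() == 0:
        return 0, g
    core = nx.core_number(g)
    k_max = max(core.values())
    sub = g.subgraph([v for v, c in core.items() if c >= k_max])
    return k_max, sub


def vertex_weight(net: PPINetwork, v: str, degree_cutoff: int = 1) -> float:
    """MCODE stage-1 weight: k_max x density of the densest core around v."""
    g = net.graph
    if v not in g:
        raise KeyError(f"node {v!r} not in network")
    if g.degree(v) < degree_cutoff or g.degree(v) == 0:
        return 0.0
    closed = g.subgraph([v, *g.neighbors(v)])
    k, core = _highest_kcore(closed)
    n = core.number_of_nodes()
    if n < 2:
        return 0.0
    density = 2.0 * core.number_of_edges() / (n * (n - 1))
    return k * density


def _grow_complex(
    g: nx.Graph,
    weights: dict[str, float],
    seed: str,
    visited: set[str],
    params: MCODEParams,
) -> set[str]:
    threshold = weights[seed] * (1.0 - params.vwp)
    members = {seed}
    queue: deque[tuple[str, int]] = deque([(seed, 0)])
    while queue:
        node, depth = queue.popleft()
        if depth >= params.max_depth:
            continue
        for nb in g.neighbors(node):
            if nb in members or nb in visited:
                continue
            if weights[nb] >= threshold:
                members.add(nb)
                queue.append((nb, depth + 1))
    return members


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively drop members with induced degree < 2 (the induced 2-core)."""
    sub = g.subgraph(members)
    core = nx.core_number(sub) if sub.number_of_nodes() else {}
    return {v for v, c in core.items() if c >= 2}


def _fluff(g: nx.Graph, members: set[str], fluff_density: float) -> set[str]:
    extra = set()
    for v in members:
        for nb in g.neighbors(v):
            if nb in members or nb in extra:
                continue
            closed = g.subgraph([nb, *g.neighbors(nb)])
            n = closed.number_of_nodes()
            dens = 2.0 * closed.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
            if dens > fluff_density:
                extra.add(nb)
    return extra


def mcode_clusters(net: PPINetwork, params: MCODEParams | None = None) -> list[Cluster]:
    """Run the full three-stage MCODE search; deterministic given an id-ordering tiebreak."""
    params = params or MCODEParams()
    g = net.graph
    if g.number_of_nodes() == 0:
        return []
    weights = {v: vertex_weight(net, v, degree_cutoff=params.degree_cutoff) for v in g}

    # seeds in descending weight, lexicographic id on ties
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set[str] = set()
    clusters: list[Cluster] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = _grow_complex(g, weights, seed, visited, params)
        visited |= members
        sub = g.subgraph(members)
        # discard complexes lacking a 2-core
        if not members or not any(c >= 2 for c in nx.core_number(sub).values()):
            continue
        if params.haircut:
            members = _haircut(g, members)
            if not members:
                continue
        fluff_members: set[str] = set()
        if params.fluff:
            fluff_members = _fluff(g, members, params.fluff_density)
        reported = members | fluff_members
        sub = g.subgraph(reported)
        n, m = sub.number_of_nodes(), sub.number_of_edges()
        clusters.append(
            Cluster(
                members=set(reported),
                n_nodes=n,
                n_edges=m,
                score=cluster_score(n, m),
                seed=seed,
                seed_weight=weights[seed],
                fluff_members=fluff_members,
            )
        )
    clusters.sort(key=lambda c: (-c.score, str(c.seed)))
    for i, c in enumerate(clusters, start=1):
        c.rank = i
    return clusters
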