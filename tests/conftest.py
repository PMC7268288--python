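import networkx as nx
import numpy as np
import pytest

import regnet as rn


@pytest.fixture
def minimal_regnet():
    """Three-node TF -> miRNA -> target chain."""
    nodes = [
        rn.RegulatoryNode("A", "TF"),
        rn.RegulatoryNode("m", "miRNA"),
        rn.RegulatoryNode("G", "target_gene"),
    ]
    edges = [
        rn.RegulatoryEdge("A", "m", "tf_mirna", "activation"),
        rn.RegulatoryEdge("m", "G", "mirna_target", "repression"),
    ]
    return rn.assemble_network(nodes, edges)


@pytest.fixture
def star5():
    """Star with center c and 4 leaves."""
    return rn.PPINetwork.from_pairs([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def triangle():
    return rn.PPINetwork.from_pairs([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def loop_fixture():
    """The packaged narrated loop network + miRNA attribute table."""
    return rn.rpl_fixture()


@pytest.fixture(scope="session")
def informative_pwm():
    """8-position PWM, strongly informative positions 2..6 (core there)."""
    counts = np.array(
        [[5, 5, 5, 5],
         [4, 4, 4, 8],
         [40, 0, 0, 0],
         [0, 40, 0, 0],
         [0, 0, 40, 0],
         [0, 0, 0, 40],
         [40, 0, 0, 0],
         [8, 4, 4, 4]]
    )
    return rn.build_pwm(counts, pseudocount=0.01, pwm_id="M1")


def random_regulatory_network(rng, n_tf=6, n_mirna=6, n_target=6, p=0.2):
    """Small random signed layered network for brute-force motif checks."""
    tfs = [f"T{i}" for i in range(n_tf)]
    mirs = [f"m{i}" for i in range(n_mirna)]
    genes = [f"g{i}" for i in range(n_target)]
    nodes = (
        [rn.RegulatoryNode(t, "TF") for t in tfs]
        + [rn.RegulatoryNode(m, "miRNA") for m in mirs]
        + [rn.RegulatoryNode(g, "target_gene") for g in genes]
    )
    signs = ["activation", "repression", "unknown"]
    edges = []
    for t in tfs:
        for m in mirs:
            if rng.random() < p:
                edges.append(rn.RegulatoryEdge(t, m, "tf_mirna", rng.choice(signs)))
    for m in mirs:
        for g in tfs + genes:
            if rng.random() < p:
                edges.append(rn.RegulatoryEdge(m, g, "mirna_target", rng.choice(signs)))
    for t in tfs:
        for g in [x for x in tfs + genes if x != t]:
            if rng.random() < p / 2:
                edges.append(rn.RegulatoryEdge(t, g, "tf_gene", rng.choice(signs)))
    return rn.assemble_network(nodes, edges)


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Independent betweenness oracle: BFS distances + path-count DP.

    sigma_st(v) = sigma(s,v) * sigma(v,t) when d(s,v) + d(v,t) == d(s,t).
    Sums over ordered pairs for directed graphs, unordered for undirected.
    """
    nodes = list(g.nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in (g.successors(u) if g.is_directed() else g.neighbors(u)):
                    if w not in d:
                        d[w] = d[u] + 1
                        sig[w] = 0
                        nxt.append(w)
                    if d[w] == d[u] + 1:
                        sig[w] += sig[u]
            frontier = nxt
        dist[s] = d
        sigma[s] = sig
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            if not g.is_directed() and nodes.index(t) < i:
                continue
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bc


def brute_force_motifs(net):
    """Enumerate motifs straight from the edge dictionary over all node tuples."""
    ids = sorted(net.nodes)
    E = net.edges
    feedback, ffl, co_tf, co_mir = set(), set(), set(), set()
    for a in ids:
        for b in ids:
            if a == b:
                continue
            if (a, b, "tf_mirna") in E and (b, a, "mirna_target") in E:
                feedback.add((a, b))
            for c in ids:
                if c in (a, b):
                    continue
                if (
                    (a, b, "tf_mirna") in E
                    and (b, c, "mirna_target") in E
                    and ((a, c, "tf_gene") in E or (a, c, "tf_mirna") in E)
                ):
                    ffl.add((a, b, c))
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            for c in ids:
                if c in (a, b):
                    continue
                if (a, c, "tf_mirna") in E and (b, c, "tf_mirna") in E:
                    co_tf.add((a, b, c))
                if (a, c, "mirna_target") in E and (b, c, "mirna_target") in E:
                    co_mir.add((a, b, c))
    return feedback, ffl, co_tf, co_mir
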