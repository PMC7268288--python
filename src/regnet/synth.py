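"""Synthetic inputs with recorded ground truth for every pipeline stage.

Every generator is a pure function of its parameters plus a seed, and returns
a :class:`GroundTruth` sufficient to score recovery (planted motifs, planted
dense modules, the planted enriched term, planted binding sites) without
re-deriving anything from the generated artifact.

The default regulatory-network spec mirrors the composition of the curated
RPL network this pipeline was built around: 44 TFs, 37 miRNAs, 36 target
genes plus a small host-gene layer, with layer edge probabilities chosen to
land near its ~200-edge scale.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .motifs import MotifInstance
from .netmodel import (
    PPINetwork,
    RegulatoryEdge,
    RegulatoryNode,
    RegulatoryNetwork,
    assemble_network,
)
from .enrichment import GeneSetCollection
from .tfbs import PWM, reverse_complement


@dataclass(frozen=True)
class SynthNetworkSpec:
    n_tf: int = 44
    n_mirna: int = 37
    n_target: int = 36
    n_host: int = 10
    p_tf_mirna: float = 0.06
    p_mirna_target: float = 0.03
    p_mirna_host: float = 0.3
    n_planted_feedback: int = 3
    n_planted_ffl: int = 1
    frac_repression: float = 0.5
    seed: int = 0


@dataclass
class GroundTruth:
    planted_motifs: list[MotifInstance] = field(default_factory=list)
    planted_clusters: list[set[str]] = field(default_factory=list)
    planted_term: str | None = None
    planted_sites: list[tuple[str, int, str]] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def _sign(rng: random.Random, frac_repression: float) -> str:
    return "repression" if rng.random() < frac_repression else "activation"


def gen_regulatory_network(spec: SynthNetworkSpec) -> tuple[RegulatoryNetwork, GroundTruth]:
    """Layered random regulatory network with planted signed motifs.

    Background edges are drawn independently per layer; planted feedback
    loops are inserted as repression/repression pairs (double-negative
    switches) and planted feedforward loops as activation/repression/
    activation triples (incoherent), overwriting any background edge on the
    same (source, target, type) triple.
    """
    if spec.n_planted_feedback > min(spec.n_tf, spec.n_mirna):
        raise ValueError("not enough TF/miRNA nodes for planted feedback loops")
    if spec.n_planted_ffl > min(spec.n_tf, spec.n_mirna, spec.n_target):
        raise ValueError("not enough nodes for planted feedforward loops")
    rng = random.Random(spec.seed)
    tfs = [f"TF{i:03d}" for i in range(spec.n_tf)]
    mirnas = [f"miR{i:03d}" for i in range(spec.n_mirna)]
    targets = [f"G{i:03d}" for i in range(spec.n_target)]
    hosts = [f"H{i:03d}" for i in range(spec.n_host)]

    nodes = (
        [RegulatoryNode(i, "TF", rng.choice(("up", "down"))) for i in tfs]
        + [RegulatoryNode(i, "miRNA", rng.choice(("up", "down"))) for i in mirnas]
        + [RegulatoryNode(i, "target_gene", rng.choice(("up", "down"))) for i in targets]
        + [RegulatoryNode(i, "host_gene", "unchanged") for i in hosts]
    )

    edges: dict[tuple[str, str, str], RegulatoryEdge] = {}

    def put(e: RegulatoryEdge) -> None:
        edges[e.key] = e

    for t in tfs:
        for m in mirnas:
            if rng.random() < spec.p_tf_mirna:
                put(RegulatoryEdge(t, m, "tf_mirna", _sign(rng, spec.frac_repression), "background"))
    for m in mirnas:
        for g in tfs + targets:
            if rng.random() < spec.p_mirna_target:
                put(RegulatoryEdge(m, g, "mirna_target", "repression", "background"))
    for m in mirnas:
        if hosts and rng.random() < spec.p_mirna_host:
            put(RegulatoryEdge(m, rng.choice(hosts), "mirna_host", "unknown", "background"))

    truth = GroundTruth()
    # planted double-negative feedback loops on disjoint TF/miRNA pairs
    fb_tfs = rng.sample(tfs, spec.n_planted_feedback)
    fb_mirs = rng.sample(mirnas, spec.n_planted_feedback)
    for t, m in zip(fb_tfs, fb_mirs):
        put(RegulatoryEdge(t, m, "tf_mirna", "repression", "planted"))
        put(RegulatoryEdge(m, t, "mirna_target", "repression", "planted"))
        truth.planted_motifs.append(
            MotifInstance("feedback_2", (t, m), ("repression", "repression"), "double_negative")
        )
    # planted incoherent feedforward loops on disjoint triples
    ffl_tfs = rng.sample([t for t in tfs if t not in fb_tfs], spec.n_planted_ffl)
    ffl_mirs = rng.sample([m for m in mirnas if m not in fb_mirs], spec.n_planted_ffl)
    ffl_genes = rng.sample(targets, spec.n_planted_ffl)
    for t, m, g in zip(ffl_tfs, ffl_mirs, ffl_genes):
        put(RegulatoryEdge(t, m, "tf_mirna", "activation", "planted"))
        put(RegulatoryEdge(m, g, "mirna_target", "repression", "planted"))
        put(RegulatoryEdge(t, g, "tf_gene", "activation", "planted"))
        truth.planted_motifs.append(
            MotifInstance(
                "feedforward_3", (t, m, g),
                ("activation", "repression", "activation"), "incoherent",
            )
        )

    net = assemble_network(nodes, list(edges.values()), prune=False)
    truth.extras["edge_list"] = [(e.source, e.target, e.interaction_type) for e in net.edges.values()]
    truth.extras["class_counts"] = {
        "TF": spec.n_tf, "miRNA": spec.n_mirna,
        "target_gene": spec.n_target, "host_gene": spec.n_host,
    }
    return net, truth


def gen_ppi_planted(
    n_background: int = 100,
    p_background: float = 0.05,
    clique_sizes: list[int] | None = None,
    internal_density: float = 0.9,
    seed: int = 42,
) -> tuple[PPINetwork, GroundTruth]:
    """Erdős–Rényi background plus planted dense modules.

    Each planted module of size s is wired internally at ``internal_density``
    and attached to the background (when present) by a single bridge edge.
    """
    if not (0.0 <= p_background <= 1.0 and 0.0 <= internal_density <= 1.0):
        raise ValueError("densities must lie in [0,1]")
    clique_sizes = [12] if clique_sizes is None else clique_sizes
    rng = random.Random(seed)
    g = nx.gnp_random_graph(n_background, p_background, seed=rng.randrange(2**31))
    g = nx.relabel_nodes(g, {i: f"P{i:04d}" for i in range(n_background)})
    g.add_nodes_from(f"P{i:04d}" for i in range(n_background))

    truth = GroundTruth()
    for ci, size in enumerate(clique_sizes):
        members = [f"C{ci}_{j:02d}" for j in range(size)]
        g.add_nodes_from(members)
        for i in range(size):
            for j in range(i + 1, size):
                if internal_density >= 1.0 or rng.random() < internal_density:
                    g.add_edge(members[i], members[j])
        if n_background > 0:
            anchor = f"P{rng.randrange(n_background):04d}"
            g.add_edge(members[0], anchor)
        truth.planted_clusters.append(set(members))
    return PPINetwork(graph=g), truth


def gen_annotations(
    n_genes: int = 2000,
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (50, 300),
    planted_fold: float = 1.0,
    query_size: int = 50,
    seed: int = 0,
) -> tuple[GeneSetCollection, set[str], GroundTruth]:
    """Random flat gene-set collection plus a query over-sampling one planted term.

    With ``planted_fold == 1`` the query is a uniform draw (null design); at
    fold f > 1 members of the planted term enter the query f times as often
    as background genes.
    """
    if planted_fold < 1:
        raise ValueError("planted_fold must be >= 1")
    lo, hi = term_size_range
    if not (0 < lo <= hi <= n_genes) or query_size > n_genes:
        raise ValueError("infeasible annotation design")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    sets = {}
    for ti in range(n_terms):
        # the planted term (T000) is the designed treatment: a fixed-size,
        # well-powered positive control at the top of the size range
        size = hi if ti == 0 else int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        sets[f"T{ti:03d}"] = frozenset(genes[i] for i in members)
    collection = GeneSetCollection.from_sets(sets, universe=genes)

    planted_term = "T000"
    planted_members = sorted(sets[planted_term])
    if planted_fold == 1.0:
        query = {genes[i] for i in rng.choice(n_genes, size=query_size, replace=False)}
    else:
        # each query slot is planted_fold times as likely to hold a member of
        # the planted term as a background gene
        K = len(planted_members)
        p_slot = planted_fold * K / (planted_fold * K + (n_genes - K))
        m = int(rng.binomial(query_size, p_slot))
        m = min(m, K, query_size)
        background = sorted(set(genes) - set(planted_members))
        query = set(rng.choice(planted_members, size=m, replace=False))
        query |= set(rng.choice(background, size=query_size - m, replace=False))

    truth = GroundTruth(planted_term=planted_term if planted_fold > 1 else None)
    truth.extras["planted_term_members"] = set(planted_members)
    return collection, query, truth


def gen_promoters(
    pwm: PWM,
    n_seq: int = 10,
    seq_len: int = 1000,
    sites_per_seq: int = 2,
    seed: int = 0,
    consensus_sites: bool = True,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Uniform-background promoter sequences with planted PWM sites.

    Sites are planted at recorded non-overlapping offsets on random strands;
    the planted sequence is the PWM consensus (default) or a per-position
    frequency sample.  Returns (id, sequence) pairs, promoter-window length
    1000 nt by default.
    """
    L = pwm.length
    if seq_len < L:
        raise ValueError("seq_len must be >= matrix length")
    if sites_per_seq * (2 * L) > seq_len:
        raise ValueError("overcrowded planting: sites do not fit with spacing")
    rng = np.random.default_rng(seed)
    records = []
    truth = GroundTruth()
    for si in range(n_seq):
        seq_id = f"prom{si:03d}"
        seq = list("ACGT"[i] for i in rng.integers(0, 4, size=seq_len))
        placed: list[int] = []
        attempts = 0
        while len(placed) < sites_per_seq:
            attempts += 1
            if attempts > 1000:
                raise ValueError("overcrowded planting: failed to place sites")
            off = int(rng.integers(0, seq_len - L + 1))
            if any(abs(off - p) < L for p in placed):
                continue
            placed.append(off)
            strand = "+" if rng.random() < 0.5 else "-"
            if consensus_sites:
                site = pwm.consensus
            else:
                site = "".join(
                    "ACGT"[rng.choice(4, p=pwm.frequencies[i])] for i in range(L)
                )
            if strand == "-":
                site = reverse_complement(site)
            seq[off : off + L] = list(site)
            truth.planted_sites.append((seq_id, off, strand))
        records.append((seq_id, "".join(seq)))
    truth.planted_sites.sort()
    return records, truth


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
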