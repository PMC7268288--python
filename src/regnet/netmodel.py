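"""Data model and I/O for heterogeneous TF-miRNA regulatory networks and PPI graphs.

The regulatory network is a directed, signed, layered graph over four node
classes (transcription factors, miRNAs, differentially expressed target genes,
and miRNA host genes).  Edges live in typed layers:

* ``tf_mirna``     TF -> miRNA transcriptional regulation (activation/repression)
* ``mirna_target`` miRNA -> gene (TF or target gene) post-transcriptional targeting
* ``mirna_host``   miRNA -> host gene locus membership
* ``tf_gene``      TF -> gene direct transcriptional regulation (needed to close
  feedforward loops in which a TF controls a gene both directly and via a miRNA)

The protein-protein interaction (PPI) network is a plain undirected simple graph.
All tabular I/O is UTF-8 TSV with a mandatory header; lines starting with ``#``
are comments.  Node ids are case-sensitive verbatim strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_CLASSES = ("TF", "miRNA", "target_gene", "host_gene")
EXPRESSION_STATES = ("up", "down", "unchanged", "unknown")
INTERACTION_TYPES = ("tf_mirna", "mirna_target", "mirna_host", "tf_gene")
SIGNS = ("activation", "repression", "unknown")

#: allowed (source class, target classes) per edge layer
_EDGE_RULES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "tf_mirna": (("TF",), ("miRNA",)),
    "mirna_target": (("miRNA",), ("TF", "target_gene")),
    "mirna_host": (("miRNA",), ("host_gene",)),
    "tf_gene": (("TF",), ("TF", "target_gene")),
}


class NetworkError(ValueError):
    """Raised on structurally invalid networks or malformed input tables."""


@dataclass(frozen=True)
class RegulatoryNode:
    id: str
    node_class: str
    expression_state: str = "unknown"
    fold_change: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("node id must be nonempty")
        if self.node_class not in NODE_CLASSES:
            raise NetworkError(f"unknown node class {self.node_class!r} for node {self.id!r}")
        if self.expression_state not in EXPRESSION_STATES:
            raise NetworkError(
                f"unknown expression state {self.expression_state!r} for node {self.id!r}"
            )
        if self.fold_change is not None and self.fold_change < 0:
            raise NetworkError(f"negative fold_change for node {self.id!r}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise NetworkError(f"p_value outside [0,1] for node {self.id!r}")


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    target: str
    interaction_type: str
    sign: str = "unknown"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise NetworkError(
                f"unknown interaction_type {self.interaction_type!r} "
                f"on edge {self.source!r}->{self.target!r}"
            )
        if self.sign not in SIGNS:
            raise NetworkError(
                f"unknown sign {self.sign!r} on edge {self.source!r}->{self.target!r}"
            )
        if self.source == self.target:
            raise NetworkError(f"self-edge on {self.source!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.interaction_type)


@dataclass
class RegulatoryNetwork:
    """Heterogeneous directed signed network.

    ``edges`` is keyed by ``(source, target, interaction_type)`` so at most one
    edge exists per triple; two layers may both connect the same node pair.
    """

    nodes: dict[str, RegulatoryNode] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], RegulatoryEdge] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_class(self, node_id: str) -> str:
        return self.nodes[node_id].node_class

    def nodes_of_class(self, node_class: str) -> list[str]:
        return [n.id for n in self.nodes.values() if n.node_class == node_class]

    def edges_of_type(self, interaction_type: str) -> list[RegulatoryEdge]:
        return [e for e in self.edges.values() if e.interaction_type == interaction_type]

    def out_edges(self, node_id: str) -> list[RegulatoryEdge]:
        return [e for e in self.edges.values() if e.source == node_id]

    def to_multidigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n in self.nodes.values():
            g.add_node(
                n.id,
                node_class=n.node_class,
                expression_state=n.expression_state,
            )
        for e in self.edges.values():
            g.add_edge(
                e.source, e.target, key=e.interaction_type,
                interaction_type=e.interaction_type, sign=e.sign, evidence=e.evidence,
            )
        return g

    def to_digraph(self) -> nx.DiGraph:
        """Simple-digraph view (parallel typed edges collapsed); for path-based metrics."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges.values())
        return g


@dataclass
class PPINetwork:
    """Undirected simple protein graph (no self-loops, no duplicate pairs)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        n_dropped = 0
        for a, b in pairs:
            if a == b:
                n_dropped += 1
                continue
            if g.has_edge(a, b):
                n_dropped += 1
                continue
            g.add_edge(a, b)
        if n_dropped:
            logger.warning("dropped %d self-loop/duplicate PPI pairs", n_dropped)
        return cls(graph=g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def node_ids(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_pairs(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    counts_by_class: dict[str, int]
    counts_by_state: dict[str, int]


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("source", "target", "interaction_type")


def _as_dataframe(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    if isinstance(rows, (str, Path)):
        return pd.read_csv(rows, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return pd.DataFrame(list(rows))


def read_edge_table(rows) -> list[RegulatoryEdge]:
    """Parse a TSV path / DataFrame / record iterable into regulatory edges.

    Required columns: source, target, interaction_type.  Optional: sign
    (empty -> unknown) and evidence.  Unknown interaction types are hard
    errors naming the offending row.
    """
    df = _as_dataframe(rows)
    for col in _EDGE_COLUMNS:
        if col not in df.columns:
            raise NetworkError(f"edge table missing required column {col!r}")
    edges: list[RegulatoryEdge] = []
    for i, row in enumerate(df.itertuples(index=False)):
        itype = getattr(row, "interaction_type")
        if itype not in INTERACTION_TYPES:
            raise NetworkError(f"row {i}: unknown interaction_type {itype!r}")
        sign = getattr(row, "sign", "") or "unknown"
        evidence = getattr(row, "evidence", "") or ""
        edges.append(
            RegulatoryEdge(
                source=getattr(row, "source"),
                target=getattr(row, "target"),
                interaction_type=itype,
                sign=sign,
                evidence=evidence,
            )
        )
    return edges


def write_edge_table(edges: Sequence[RegulatoryEdge], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "interaction_type": e.interaction_type,
                "sign": e.sign,
                "evidence": e.evidence,
            }
            for e in edges
        ],
        columns=["source", "target", "interaction_type", "sign", "evidence"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_node_table(rows) -> list[RegulatoryNode]:
    """Node attribute TSV: id, node_class, optional expression_state/fold_change/p_value."""
    df = _as_dataframe(rows)
    for col in ("id", "node_class"):
        if col not in df.columns:
            raise NetworkError(f"node table missing required column {col!r}")
    nodes = []
    for row in df.itertuples(index=False):
        fc = getattr(row, "fold_change", "")
        pv = getattr(row, "p_value", "")
        nodes.append(
            RegulatoryNode(
                id=getattr(row, "id"),
                node_class=getattr(row, "node_class"),
                expression_state=getattr(row, "expression_state", "") or "unknown",
                fold_change=float(fc) if fc not in ("", None) else None,
                p_value=float(pv) if pv not in ("", None) else None,
            )
        )
    return nodes


def assemble_network(
    nodes: Sequence[RegulatoryNode],
    edges: Sequence[RegulatoryEdge],
    prune: bool = False,
) -> RegulatoryNetwork:
    """Validate and assemble a regulatory network.

    Enforces class/type consistency of every edge against the declared node
    classes; collapses duplicate ``(source, target, interaction_type)`` edges
    keeping the first sign (logged); with ``prune=True`` removes nodes of
    degree zero (the convention for discarding factors lacking any regulatory
    miRNA association).
    """
    node_map: dict[str, RegulatoryNode] = {}
    for n in nodes:
        if n.id in node_map:
            raise NetworkError(f"duplicate node id {n.id!r}")
        node_map[n.id] = n

    edge_map: dict[tuple[str, str, str], RegulatoryEdge] = {}
    n_dup = 0
    for e in edges:
        for endpoint in (e.source, e.target):
            if endpoint not in node_map:
                raise NetworkError(f"edge {e.source!r}->{e.target!r} references undeclared node {endpoint!r}")
        src_ok, tgt_ok = _EDGE_RULES[e.interaction_type]
        src_class = node_map[e.source].node_class
        tgt_class = node_map[e.target].node_class
        if src_class not in src_ok or tgt_class not in tgt_ok:
            raise NetworkError(
                f"class-inconsistent edge {e.source!r}({src_class})->"
                f"{e.target!r}({tgt_class}) of type {e.interaction_type!r}"
            )
        if e.key in edge_map:
            n_dup += 1
            continue  # keep first sign
        edge_map[e.key] = e
    if n_dup:
        logger.warning("collapsed %d duplicate (source,target,type) edges, keeping first sign", n_dup)

    if prune:
        touched = {e.source for e in edge_map.values()} | {e.target for e in edge_map.values()}
        node_map = {i: n for i, n in node_map.items() if i in touched}

    return RegulatoryNetwork(nodes=node_map, edges=edge_map)


def summarize(net: RegulatoryNetwork) -> NetworkSummary:
    """Exact node/edge counts broken down by node class and expression state."""
    by_class: dict[str, int] = {}
    by_state: dict[str, int] = {}
    for n in net.nodes.values():
        by_class[n.node_class] = by_class.get(n.node_class, 0) + 1
        by_state[n.expression_state] = by_state.get(n.expression_state, 0) + 1
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        counts_by_class=by_class,
        counts_by_state=by_state,
    )


# ---------------------------------------------------------------------------
# PPI I/O and graph serialization
# ---------------------------------------------------------------------------

def read_ppi(rows) -> PPINetwork:
    """Read an undirected PPI edge list (columns: protein_a, protein_b).

    Self-loops and duplicate pairs are dropped with a logged count.
    """
    df = _as_dataframe(rows)
    if df.shape[1] < 2:
        if df.shape[0] == 0:
            return PPINetwork()
        raise NetworkError("PPI table needs two id columns")
    a_col, b_col = df.columns[:2]
    pairs = list(zip(df[a_col].astype(str), df[b_col].astype(str)))
    for a, b in pairs:
        if not a or not b or a == "nan" or b == "nan":
            raise NetworkError("malformed PPI pair row with empty id")
    return PPINetwork.from_pairs(pairs)


def write_ppi(net: PPINetwork, path: str | Path) -> None:
    pd.DataFrame(sorted((min(a, b), max(a, b)) for a, b in net.graph.edges),
                 columns=["protein_a", "protein_b"]).to_csv(path, sep="\t", index=False)


def write_graph(net: RegulatoryNetwork | PPINetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Serialize a network as GraphML, SIF, or TSV."""
    fmt = fmt.lower()
    if fmt not in ("graphml", "sif", "tsv"):
        raise NetworkError(f"unsupported format {fmt!r}")
    path = Path(path)
    if isinstance(net, PPINetwork):
        if fmt == "graphml":
            nx.write_graphml(net.graph, path)
        elif fmt == "sif":
            with open(path, "w") as fh:
                for a, b in sorted(net.graph.edges):
                    fh.write(f"{a}\tpp\t{b}\n")
        else:
            write_ppi(net, path)
        return
    if fmt == "graphml":
        nx.write_graphml(net.to_multidigraph(), path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in net.edges.values():
                fh.write(f"{e.source}\t{e.interaction_type}\t{e.target}\n")
    else:
        write_edge_table(list(net.edges.values()), path)


def read_graphml_regulatory(path: str | Path) -> RegulatoryNetwork:
    g = nx.read_graphml(path, force_multigraph=True)
    nodes = [
        RegulatoryNode(
            id=str(i),
            node_class=d.get("node_class", "target_gene"),
            expression_state=d.get("expression_state", "unknown"),
        )
        for i, d in g.nodes(data=True)
    ]
    edges = [
        RegulatoryEdge(
            source=str(u), target=str(v),
            interaction_type=d.get("interaction_type", "tf_gene"),
            sign=d.get("sign", "unknown"), evidence=d.get("evidence", ""),
        )
        for u, v, d in g.edges(data=True)
    ]
    return assemble_network(nodes, edges)


def read_graphml_ppi(path: str | Path) -> PPINetwork:
    g = nx.read_graphml(path)
    return PPINetwork.from_pairs((str(a), str(b)) for a, b in g.edges)
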