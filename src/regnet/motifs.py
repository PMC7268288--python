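"""Signed TF-miRNA motif census: feedback loops, feedforward loops, co-regulation.

Sign algebra: activation = +1, repression = -1.  A miRNA->gene targeting edge
with no annotated sign defaults to repression (silencing is the miRNA default
mode of action); a TF edge with no annotated sign stays unknown and makes the
containing motif ``unsigned``.

Motif types
-----------
* ``feedback_2``      TF -> miRNA (transcriptional) and miRNA -> TF (targeting).
  Both edges repressive -> ``double_negative`` (bistable switch); both
  activating -> ``double_positive``; otherwise ``mixed`` (oscillator-like).
* ``feedforward_3``   TF -> miRNA -> gene plus the direct TF -> gene edge;
  ``coherent`` when the direct sign equals the product of the indirect signs.
* ``co_reg_tf``       two TFs transcriptionally regulating the same miRNA.
* ``co_target_mirna`` two miRNAs targeting the same gene.

Significance is assessed against a degree-preserving rewiring null that
shuffles each interaction-type layer independently with double-edge swaps.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass

from .netmodel import RegulatoryEdge, RegulatoryNetwork

logger = logging.getLogger(__name__)

MOTIF_TYPES = ("feedback_2", "feedforward_3", "co_reg_tf", "co_target_mirna")

_SIGN_VALUE = {"activation": +1, "repression": -1}


@dataclass(frozen=True)
class MotifInstance:
    motif_type: str
    members: tuple[str, ...]
    signs: tuple[str, ...]
    classification: str


@dataclass
class MotifCensus:
    instances: list[MotifInstance]
    counts: dict[str, int]
    null_mean: dict[str, float] | None = None
    null_sd: dict[str, float] | None = None
    z_score: dict[str, float] | None = None


def effective_sign(edge: RegulatoryEdge) -> str:
    """Edge sign with the miRNA-silencing default applied to unsigned targeting edges."""
    if edge.sign == "unknown" and edge.interaction_type == "mirna_target":
        return "repression"
    return edge.sign


def _classify_pair(s1: str, s2: str) -> str:
    if "unknown" in (s1, s2):
        return "unsigned"
    if s1 == s2 == "repression":
        return "double_negative"
    if s1 == s2 == "activation":
        return "double_positive"
    return "mixed"


def find_feedback_loops(net: RegulatoryNetwork) -> list[MotifInstance]:
    """Two-node loops: a TF transcriptionally regulates a miRNA that targets it back."""
    out = []
    for e in net.edges_of_type("tf_mirna"):
        back = net.edges.get((e.target, e.source, "mirna_target"))
        if back is None:
            continue
        s1, s2 = effective_sign(e), effective_sign(back)
        out.append(
            MotifInstance(
                motif_type="feedback_2",
                members=(e.source, e.target),
                signs=(s1, s2),
                classification=_classify_pair(s1, s2),
            )
        )
    out.sort(key=lambda m: m.members)
    return out


def _direct_tf_edge(net: RegulatoryNetwork, tf: str, gene: str) -> RegulatoryEdge | None:
    """Direct TF regulation of ``gene``: a tf_gene edge, or tf_mirna when the gene is a miRNA."""
    e = net.edges.get((tf, gene, "tf_gene"))
    if e is not None:
        return e
    return net.edges.get((tf, gene, "tf_mirna"))


def find_feedforward_loops(net: RegulatoryNetwork) -> list[MotifInstance]:
    """Three-node loops TF -> miRNA -> gene closed by a direct TF -> gene edge."""
    out = []
    targets_of = {}
    for e in net.edges_of_type("mirna_target"):
        targets_of.setdefault(e.source, []).append(e)
    for e1 in net.edges_of_type("tf_mirna"):
        tf, mirna = e1.source, e1.target
        for e2 in targets_of.get(mirna, ()):
            gene = e2.target
            if gene == tf:
                continue  # that is a feedback pair, not a feedforward triple
            e3 = _direct_tf_edge(net, tf, gene)
            if e3 is None:
                continue
            signs = (effective_sign(e1), effective_sign(e2), effective_sign(e3))
            if "unknown" in signs:
                cls = "unsigned"
            else:
                indirect = _SIGN_VALUE[signs[0]] * _SIGN_VALUE[signs[1]]
                cls = "coherent" if _SIGN_VALUE[signs[2]] == indirect else "incoherent"
            out.append(
                MotifInstance(
                    motif_type="feedforward_3",
                    members=(tf, mirna, gene),
                    signs=signs,
                    classification=cls,
                )
            )
    out.sort(key=lambda m: m.members)
    return out


def find_co_regulation(net: RegulatoryNetwork) -> list[MotifInstance]:
    """Shared-neighbor pairs: TFs co-regulating a miRNA; miRNAs co-targeting a gene.

    One instance per (unordered pair, shared node); the shared node is the
    third member.
    """
    out = []
    by_target: dict[str, list[RegulatoryEdge]] = {}
    for e in net.edges_of_type("tf_mirna"):
        by_target.setdefault(e.target, []).append(e)
    for mirna, es in by_target.items():
        es = sorted(es, key=lambda e: e.source)
        for i in range(len(es)):
            for j in range(i + 1, len(es)):
                s1, s2 = effective_sign(es[i]), effective_sign(es[j])
                out.append(
                    MotifInstance(
                        motif_type="co_reg_tf",
                        members=(es[i].source, es[j].source, mirna),
                        signs=(s1, s2),
                        classification=_classify_pair(s1, s2),
                    )
                )
    by_gene: dict[str, list[RegulatoryEdge]] = {}
    for e in net.edges_of_type("mirna_target"):
        by_gene.setdefault(e.target, []).append(e)
    for gene, es in by_gene.items():
        es = sorted(es, key=lambda e: e.source)
        for i in range(len(es)):
            for j in range(i + 1, len(es)):
                s1, s2 = effective_sign(es[i]), effective_sign(es[j])
                out.append(
                    MotifInstance(
                        motif_type="co_target_mirna",
                        members=(es[i].source, es[j].source, gene),
                        signs=(s1, s2),
                        classification=_classify_pair(s1, s2),
                    )
                )
    out.sort(key=lambda m: (m.motif_type, m.members))
    return out


def motif_census(net: RegulatoryNetwork) -> MotifCensus:
    instances = find_feedback_loops(net) + find_feedforward_loops(net) + find_co_regulation(net)
    counts = {t: 0 for t in MOTIF_TYPES}
    for m in instances:
        counts[m.motif_type] += 1
    return MotifCensus(instances=instances, counts=counts)


# ---------------------------------------------------------------------------
# rewiring null model
# ---------------------------------------------------------------------------

def _rewire_layer(edges: list[RegulatoryEdge], n_swaps: int, rng: random.Random,
                  warn: bool = True) -> list[RegulatoryEdge]:
    """Degree-preserving double-edge swaps within one interaction-type layer.

    Swapping targets of two edges preserves every node's per-layer in/out
    degree and, because all sources (resp. targets) of a layer share a node
    class, also class consistency.  Signs travel with the source edge.
    """
    if len(edges) < 2:
        if warn:
            logger.warning("layer with <2 edges left intact by rewiring")
        return list(edges)
    current = list(edges)
    present = {(e.source, e.target) for e in current}
    for _ in range(n_swaps):
        i, j = rng.randrange(len(current)), rng.randrange(len(current))
        if i == j:
            continue
        a, b = current[i], current[j]
        if a.source == b.target or b.source == a.target:
            continue
        na = (a.source, b.target)
        nb = (b.source, a.target)
        if na in present or nb in present:
            continue
        present -= {(a.source, a.target), (b.source, b.target)}
        present |= {na, nb}
        current[i] = RegulatoryEdge(a.source, b.target, a.interaction_type, a.sign, a.evidence)
        current[j] = RegulatoryEdge(b.source, a.target, b.interaction_type, b.sign, b.evidence)
    return current


def rewire_network(net: RegulatoryNetwork, n_rewires: int, rng: random.Random,
                   warn: bool = True) -> RegulatoryNetwork:
    """One null-model sample: each layer independently double-edge-swapped."""
    new_edges: dict[tuple[str, str, str], RegulatoryEdge] = {}
    for itype in ("tf_mirna", "mirna_target", "mirna_host", "tf_gene"):
        layer = net.edges_of_type(itype)
        if not layer:
            continue
        for e in _rewire_layer(layer, n_rewires, rng, warn=warn):
            new_edges[e.key] = e
    return RegulatoryNetwork(nodes=dict(net.nodes), edges=new_edges)


def motif_null(
    net: RegulatoryNetwork,
    census: MotifCensus | None = None,
    n_rewires: int = 100,
    n_samples: int = 100,
    seed: int = 0,
) -> MotifCensus:
    """Attach rewiring-null mean/sd and z-scores to a motif census."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    census = census or motif_census(net)
    rng = random.Random(seed)
    samples: dict[str, list[int]] = {t: [] for t in MOTIF_TYPES}
    for i in range(n_samples):
        null_net = rewire_network(net, n_rewires, rng, warn=(i == 0))
        counts = motif_census(null_net).counts
        for t in MOTIF_TYPES:
            samples[t].append(counts[t])
    null_mean = {t: sum(v) / len(v) for t, v in samples.items()}
    null_sd = {
        t: math.sqrt(sum((x - null_mean[t]) ** 2 for x in v) / len(v))
        for t, v in samples.items()
    }
    z = {
        t: (census.counts[t] - null_mean[t]) / null_sd[t]
        for t in MOTIF_TYPES
        if null_sd[t] > 0
    }
    return MotifCensus(
        instances=census.instances,
        counts=census.counts,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
    )
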