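"""Centrality, hub/bottleneck selection, hub-miRNA ranking, and power-law fits.

Hubs are nodes in the upper tail of the degree distribution, bottlenecks in the
upper tail of shortest-path betweenness; hub-bottlenecks are the intersection.
Selection uses an inclusive empirical-quantile threshold: the cut value is the
``ceil(q*n)``-th largest statistic and every node at or above it is kept, so
ties never split and the set is monotone in ``q``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .netmodel import PPINetwork, RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass
class CentralityReport:
    degree: dict[str, int]
    betweenness: dict[str, float]
    hub_set: set[str]
    bottleneck_set: set[str]
    hub_bottleneck_set: set[str]
    quantile: float


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def _as_graph(net) -> nx.Graph | nx.MultiDiGraph:
    if isinstance(net, PPINetwork):
        return net.graph
    if isinstance(net, RegulatoryNetwork):
        return net.to_multidigraph()
    return net


def degree_centrality(net, mode: str = "total") -> dict[str, int]:
    """Integer node degrees; ``mode`` in {total, in, out} (forced total on PPI)."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("degree_centrality on empty network")
    if not g.is_directed():
        mode = "total"
    if mode == "total":
        deg = g.degree()
    elif mode == "in":
        deg = g.in_degree()
    elif mode == "out":
        deg = g.out_degree()
    else:
        raise ValueError(f"unknown degree mode {mode!r}")
    return {n: int(d) for n, d in deg}


def betweenness(net, directed: bool | None = None) -> dict[str, float]:
    """Unnormalized shortest-path (pair-dependency) betweenness.

    Directed on regulatory networks, undirected on PPI graphs by default.
    Disconnected pairs contribute nothing.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("betweenness on empty network")
    if g.is_multigraph():
        g = nx.DiGraph(g) if g.is_directed() else nx.Graph(g)
    if directed is not None and directed != g.is_directed():
        g = g.to_directed() if directed else g.to_undirected()
    return dict(nx.betweenness_centrality(g, normalized=False))


def _upper_tail(values: dict[str, float], quantile: float) -> set[str]:
    n = len(values)
    k = max(1, math.ceil(quantile * n))
    cut = sorted(values.values(), reverse=True)[k - 1]
    return {v for v, x in values.items() if x >= cut}


def hub_bottleneck(net, quantile: float = 0.2) -> CentralityReport:
    """Select hub, bottleneck, and hub-bottleneck nodes at an upper-tail quantile."""
    if not (0.0 < quantile < 1.0):
        raise ValueError(f"quantile must be in (0,1), got {quantile}")
    deg = degree_centrality(net)
    btw = betweenness(net)
    hubs = _upper_tail({k: float(v) for k, v in deg.items()}, quantile)
    bots = _upper_tail(btw, quantile)
    return CentralityReport(
        degree=deg,
        betweenness=btw,
        hub_set=hubs,
        bottleneck_set=bots,
        hub_bottleneck_set=hubs & bots,
        quantile=quantile,
    )


def rank_hub_mirnas(net: RegulatoryNetwork, clusters, k: int = 10) -> list[str]:
    """Rank miRNA nodes by (total degree, intramodular degree, id) and return top k.

    Intramodular degree counts neighbors sharing the node's module, where
    modules are given as node-id sets (or objects with a ``members`` set, e.g.
    MCODE clusters).  Connectivity plus module membership is the working
    definition of a hub miRNA.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mirnas = net.nodes_of_class("miRNA")
    if not mirnas:
        logger.warning("rank_hub_mirnas: network has no miRNA nodes")
        return []
    member_sets = [set(getattr(c, "members", c)) for c in clusters]
    g = net.to_multidigraph().to_undirected()
    deg = {m: g.degree(m) for m in mirnas}

    def intramodular(m: str) -> int:
        for members in member_sets:
            if m in members:
                return sum(1 for nb in set(g.neighbors(m)) if nb in members)
        return 0

    ranked = sorted(mirnas, key=lambda m: (-deg[m], -intramodular(m), m))
    return ranked[:k]


def fit_power_law(degrees: dict[str, int], method: str = "ols") -> PowerLawFit:
    """Fit the degree distribution in log-log space.

    ``ols`` (default) regresses log10 frequency on log10 degree over degrees
    >= 1 with nonzero frequency — the straight red-line convention of
    scale-free-network figures.  ``mle`` instead returns the discrete maximum
    likelihood exponent (Clauset-style with x_min = 1) as a negative slope;
    intercept/r² are not defined for it and are reported as nan.
    """
    vals = [d for d in degrees.values() if d >= 1]
    freq: dict[int, int] = {}
    for d in vals:
        freq[d] = freq.get(d, 0) + 1
    if len(freq) < 2:
        raise ValueError("need at least 2 distinct nonzero degrees to fit")
    if method == "mle":
        x = np.array(vals, dtype=float)
        alpha = 1.0 + len(x) / np.sum(np.log(x / 0.5))
        return PowerLawFit(slope=-alpha, intercept=float("nan"),
                           r_squared=float("nan"), n_points=len(freq))
    if method != "ols":
        raise ValueError(f"unknown power-law fit method {method!r}")
    ds = np.array(sorted(freq), dtype=float)
    fs = np.array([freq[int(d)] for d in ds], dtype=float)
    res = stats.linregress(np.log10(ds), np.log10(fs))
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(ds),
    )
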