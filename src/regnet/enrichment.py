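"""Gene-set over-representation: hypergeometric tests, BH FDR, Fisher combination.

Implements the multi-miRNA pathway logic of union-style web tools: each
miRNA's filtered target list is tested per pathway with a one-sided
hypergeometric test, and per-pathway evidence across miRNAs is pooled either
by Fisher's method (default) or by a single test on the pooled target union.
GO terms are treated as flat gene sets (no ontology DAG propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class GeneSetCollection:
    universe: set[str]
    sets: dict[str, tuple[str, frozenset[str]]]  # term id -> (name, members)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set {term!r}")
            if not members <= self.universe:
                raise ValueError(f"gene set {term!r} not contained in universe")

    @classmethod
    def from_sets(cls, sets: Mapping[str, Iterable[str]],
                  universe: Iterable[str] | None = None,
                  names: Mapping[str, str] | None = None) -> "GeneSetCollection":
        frozen = {t: ((names or {}).get(t, t), frozenset(g)) for t, g in sets.items()}
        if universe is None:
            universe = set().union(*(g for _, g in frozen.values())) if frozen else set()
        return cls(universe=set(universe), sets=frozen)


@dataclass
class EnrichmentResult:
    term: str
    name: str
    k: int           # overlap
    K: int           # term size
    n: int           # query size
    N: int           # universe size
    p_raw: float
    p_adjusted: float = 1.0
    n_mirnas: int = 0
    combined_p: float | None = None


@dataclass(frozen=True)
class MirPathConfig:
    target_score_cutoff: float = 0.8
    max_targets_per_mirna: int = 350
    alpha: float = 0.05
    combine_method: str = "fisher"

    def __post_init__(self) -> None:
        if self.combine_method not in ("fisher", "union"):
            raise ValueError(f"unknown combine_method {self.combine_method!r}")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read gene sets from GMT (term <tab> description <tab> gene...)."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[term] = frozenset(genes)
            names[term] = desc
    return GeneSetCollection.from_sets(sets, universe=universe, names=names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            name, members = collection.sets[term]
            fh.write("\t".join([term, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n); 1.0 when k == 0."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, _P_FLOOR), 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    ps = list(p_values)
    if not ps:
        return []
    arr = np.asarray(ps, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def fisher_combine(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: X² = -2 Σ ln p ~ χ²(2m); returns (X², df, combined p)."""
    ps = list(p_values)
    if not ps:
        raise ValueError("fisher_combine needs at least one p-value")
    if any(p <= 0 or p > 1 for p in ps):
        if any(p > 1 or p < 0 for p in ps):
            raise ValueError("p-values must lie in (0,1]")
        logger.warning("clamping %d nonpositive p-values at %g", sum(p <= 0 for p in ps), _P_FLOOR)
    clamped = [max(p, _P_FLOOR) for p in ps]
    x2 = -2.0 * float(np.sum(np.log(clamped)))
    df = 2 * len(clamped)
    return x2, df, float(stats.chi2.sf(x2, df))


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def _filter_targets(
    scored: Mapping[str, float] | Iterable[tuple[str, float]],
    universe: set[str],
    config: MirPathConfig,
) -> list[str]:
    items = list(scored.items()) if isinstance(scored, Mapping) else list(scored)
    known = [(g, s) for g, s in items if g in universe]
    dropped = len(items) - len(known)
    if dropped:
        logger.warning("dropped %d target genes absent from the universe", dropped)
    kept = [(g, s) for g, s in known if s >= config.target_score_cutoff]
    kept.sort(key=lambda gs: (-gs[1], gs[0]))
    return [g for g, _ in kept[: config.max_targets_per_mirna]]


def mirpath_analyze(
    targets: Mapping[str, Mapping[str, float]],
    pathways: GeneSetCollection,
    config: MirPathConfig | None = None,
) -> list[EnrichmentResult]:
    """Multi-miRNA pathway enrichment over scored target predictions.

    Per miRNA, targets are filtered by score cutoff and truncated to the
    per-miRNA cap, then tested per pathway; per-pathway p-values across
    miRNAs are combined by Fisher's method, or a single hypergeometric test
    is run on the pooled target union (``combine_method='union'``).  Reported
    overlap ``k`` is between the pooled union and the pathway; ``n_mirnas``
    counts miRNAs with at least one filtered target in the pathway.  BH
    adjustment is applied across pathways.
    """
    if not targets:
        raise ValueError("need at least one miRNA")
    config = config or MirPathConfig()
    N = len(pathways.universe)
    filtered = {m: _filter_targets(t, pathways.universe, config) for m, t in targets.items()}
    union: set[str] = set().union(*filtered.values()) if filtered else set()

    results: list[EnrichmentResult] = []
    for term in sorted(pathways.sets):
        name, members = pathways.sets[term]
        k_union = len(union & members)
        n_mirnas = sum(1 for t in filtered.values() if set(t) & members)
        if config.combine_method == "fisher":
            per_mirna = [
                hypergeom_upper(len(set(t) & members), len(members), len(t), N)
                for t in filtered.values()
                if t
            ]
            if per_mirna:
                _, _, p = fisher_combine(per_mirna)
            else:
                p = 1.0
            combined: float | None = p
        else:
            p = hypergeom_upper(k_union, len(members), len(union), N)
            combined = None
        results.append(
            EnrichmentResult(
                term=term, name=name, k=k_union, K=len(members),
                n=len(union), N=N, p_raw=p, n_mirnas=n_mirnas, combined_p=combined,
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = float(q)
    results.sort(key=lambda r: (r.p_raw, r.term))
    return results


def go_annotate(query: Iterable[str], goterms: GeneSetCollection) -> list[EnrichmentResult]:
    """Flat-set GO over-representation of one query set, BH-corrected across terms."""
    qset = set(query)
    known = qset & goterms.universe
    if len(known) < len(qset):
        logger.warning("dropped %d query genes absent from the universe", len(qset) - len(known))
    N = len(goterms.universe)
    results = []
    for term in sorted(goterms.sets):
        name, members = goterms.sets[term]
        k = len(known & members)
        results.append(
            EnrichmentResult(
                term=term, name=name, k=k, K=len(members), n=len(known), N=N,
                p_raw=hypergeom_upper(k, len(members), len(known), N),
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = float(q)
    results.sort(key=lambda r: (r.p_raw, r.term))
    return results
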