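"""Tandem gene cluster identification from all-vs-all protein similarity.

The pipeline: repair zero E-values in a blastp-style hit table, build a
weighted similarity graph, partition it by Markov clustering (MCL,
inflation 2.0), call tandem gene pairs (two co-clustered genes on one
scaffold separated by at most one intervening non-TE gene), and take
connected components of the pair graph as tandem gene clusters.

MCL is implemented here directly: a column-stochastic random-walk matrix
with self-loops, alternating expansion (matrix power) and inflation
(entrywise power plus column renormalization) to convergence, clusters read
off the attractor rows.  Edge weights default to -log10(E-value), which
preserves the hit ordering; a raw-score mode is available.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GeneRecord",
    "SimilarityEdge",
    "ClusterParams",
    "TandemCluster",
    "build_similarity_graph",
    "mcl_cluster",
    "call_tandem_pairs",
    "tandem_clusters",
    "cluster_size_histogram",
]


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene: position on a scaffold plus a transposable-element
    flag (TE genes never join pairs and never count as intervening)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    is_te: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass(frozen=True)
class SimilarityEdge:
    a: str
    b: str
    evalue: float
    weight: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-edges are not allowed")
        if not math.isfinite(self.weight):
            raise ValueError("edge weight must be finite")


@dataclass(frozen=True)
class ClusterParams:
    """Markov-clustering and tandem-pair parameters.

    inflation (> 1) controls cluster granularity; expansion is the matrix
    power per iteration; max_intervening is the maximum number of non-TE
    genes allowed between the members of a tandem pair.
    """

    inflation: float = 2.0
    expansion: int = 2
    max_iter: int = 100
    convergence_tol: float = 1e-6
    max_intervening: int = 1
    prune_below: float = 1e-9

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass(frozen=True)
class TandemCluster:
    member_ids: frozenset[str]
    scaffolds: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


def build_similarity_graph(
    hits: Iterable[tuple[str, str, float]], use_log_weight: bool = True
) -> list[SimilarityEdge]:
    """Turn raw (query, subject, E-value) hits into a merged edge list.

    Zero E-values are replaced by the lowest non-zero E-value in the input
    (raising if every E-value is zero), self-hits are dropped, and
    reciprocal hits are merged keeping the better (lower) E-value.  The
    default weight is -log10(E-value); ``use_log_weight=False`` keeps
    1/E-value instead.
    """
    hits = list(hits)
    nonzero = [e for _, _, e in hits if e > 0]
    has_zero = any(e == 0 for _, _, e in hits)
    if has_zero and not nonzero:
        raise ValueError(
            "all E-values are zero: replacement value is undefined"
        )
    floor = min(nonzero) if nonzero else None

    best: dict[tuple[str, str], float] = {}
    for a, b, e in hits:
        if e < 0:
            raise ValueError(f"negative E-value for ({a},{b})")
        if a == b:
            continue
        if e == 0:
            e = floor
        key = (a, b) if a <= b else (b, a)
        if key not in best or e < best[key]:
            best[key] = e

    edges = []
    for (a, b), e in sorted(best.items()):
        weight = -math.log10(e) if use_log_weight else 1.0 / e
        edges.append(SimilarityEdge(a, b, e, weight))
    return edges


def mcl_cluster(
    edges: Sequence[SimilarityEdge], params: ClusterParams | None = None
) -> list[frozenset[str]]:
    """Markov clustering of the similarity graph.

    Returns a partition of all node ids (singletons allowed), deterministic
    for a given input: nodes are ordered by id, and a node attracted by
    several attractor systems joins the lexicographically smallest cluster.
    Non-convergence within ``max_iter`` iterations emits a warning and the
    current matrix is interpreted as-is.
    """
    params = params or ClusterParams()
    nodes = sorted({n for e in edges for n in (e.a, e.b)})
    if not nodes:
        return []
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    M = np.zeros((n, n))
    for e in edges:
        i, j = index[e.a], index[e.b]
        w = max(e.weight, 0.0)
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    # Self-loops at the column maximum (1.0 for isolated nodes) damp
    # oscillation, as in canonical MCL.
    col_max = M.max(axis=0)
    np.fill_diagonal(M, np.where(col_max > 0, col_max, 1.0))
    M = M / M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(params.max_iter):
        prev = M
        M = np.linalg.matrix_power(M, params.expansion)
        M = M**params.inflation
        M[M < params.prune_below] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - prev)) < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iter} iterations; "
            "interpreting the current matrix",
            stacklevel=2,
        )

    tol = params.convergence_tol
    clusters: list[set[str]] = []
    assigned: dict[str, int] = {}
    for i in range(n):
        if M[i, i] <= tol:
            continue  # not an attractor row
        members = {nodes[j] for j in np.nonzero(M[i] > tol)[0]}
        members.add(nodes[i])
        overlapping = sorted({assigned[m] for m in members if m in assigned})
        if overlapping:
            # A node reachable from two attractor systems joins the
            # cluster containing the smallest id (deterministic choice).
            target = overlapping[0]
            clusters[target] |= members
            for ci in overlapping[1:]:
                clusters[target] |= clusters[ci]
                clusters[ci] = set()
            members = clusters[target]
            idx = target
        else:
            clusters.append(members)
            idx = len(clusters) - 1
        for m in members:
            assigned[m] = idx
    for node in nodes:
        if node not in assigned:
            clusters.append({node})
            assigned[node] = len(clusters) - 1
    return sorted(
        (frozenset(c) for c in clusters if c), key=lambda c: min(c)
    )


def call_tandem_pairs(
    genes: Sequence[GeneRecord],
    clusters: Iterable[frozenset[str]],
    params: ClusterParams | None = None,
) -> list[tuple[str, str]]:
    """Call tandem gene pairs from a cluster partition.

    A pair (g1, g2) is called iff the two genes share a cluster and a
    scaffold and the number of non-TE genes strictly between them in start
    order is at most ``max_intervening``.  TE genes neither join pairs nor
    count as intervening.  Pairs are returned with the earlier-starting
    gene first, sorted by position.
    """
    params = params or ClusterParams()
    cluster_of: dict[str, int] = {}
    for ci, cluster in enumerate(clusters):
        for g in cluster:
            cluster_of[g] = ci

    by_scaffold: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)

    pairs: list[tuple[str, str]] = []
    for scaffold in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.end))
        starts = [g.start for g in ordered]
        if len(set(starts)) != len(starts):
            raise ValueError(
                f"duplicate gene start positions on scaffold {scaffold}"
            )
        non_te = [g for g in ordered if not g.is_te]
        for i, g1 in enumerate(non_te):
            if g1.gene_id not in cluster_of:
                continue
            for j in range(i + 1, len(non_te)):
                g2 = non_te[j]
                if j - i - 1 > params.max_intervening:
                    break  # intervening count only grows with j
                if cluster_of.get(g2.gene_id) == cluster_of[g1.gene_id]:
                    pairs.append((g1.gene_id, g2.gene_id))
    return pairs


def tandem_clusters(pairs: Iterable[tuple[str, str]]) -> list[TandemCluster]:
    """Connected components of the tandem-pair graph (size >= 2 each)."""
    graph = nx.Graph()
    graph.add_edges_from(pairs)
    return sorted(
        (
            TandemCluster(member_ids=frozenset(comp), scaffolds=frozenset())
            for comp in nx.connected_components(graph)
        ),
        key=lambda c: min(c.member_ids),
    )


def annotate_cluster_scaffolds(
    clusters: Iterable[TandemCluster], genes: Sequence[GeneRecord]
) -> list[TandemCluster]:
    scaffold_of = {g.gene_id: g.scaffold for g in genes}
    return [
        TandemCluster(
            member_ids=c.member_ids,
            scaffolds=frozenset(
                scaffold_of[g] for g in c.member_ids if g in scaffold_of
            ),
        )
        for c in clusters
    ]


def cluster_size_histogram(clusters: Iterable[TandemCluster]) -> dict[int, int]:
    """Map cluster size -> number of clusters of that size."""
    return dict(sorted(Counter(c.size for c in clusters).items()))
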