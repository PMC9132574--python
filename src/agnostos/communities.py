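"""Aggregation of gene clusters into communities.

Profile-homology graph construction, a Markov clustering implementation with
inflation-grid optimization over five partition-quality metrics, and
three-pass orphan rescue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .functional import annotation_entropy
from .model import ProfileHit

logger = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    assignment: Dict[str, int]
    inflation: float = 0.0
    metrics: Dict[str, Optional[float]] = field(default_factory=dict)
    composite: float = 0.0

    @property
    def communities(self) -> Dict[int, Set[str]]:
        out: Dict[int, Set[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


def build_gcc_graph(
    hits: Iterable[ProfileHit],
    min_probability: float = 0.5,
    min_coverage: float = 0.6,
) -> nx.Graph:
    """Homology graph over clusters from profile-vs-profile hits.

    Edges require probability >= ``min_probability`` and bidirectional
    coverage > ``min_coverage``; the weight is bitscore / aligned columns.
    Self-hits are dropped and reciprocal hits merged keeping the max weight.
    """
    graph = nx.Graph()
    for hit in hits:
        if hit.query_gc == hit.target_gc:
            continue
        if hit.probability < min_probability:
            continue
        if hit.query_cov <= min_coverage or hit.target_cov <= min_coverage:
            continue
        w = hit.weight
        if w <= 0:
            continue
        u, v = hit.query_gc, hit.target_gc
        if graph.has_edge(u, v):
            graph[u][v]["weight"] = max(graph[u][v]["weight"], w)
        else:
            graph.add_edge(u, v, weight=w)
    return graph


# ---------------------------------------------------------------------------
# Markov clustering


def _mcl_matrix(
    adj: np.ndarray,
    inflation: float,
    prune: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    n = adj.shape[0]
    m = adj.astype(float).copy()
    # self loops: weight = max incident edge weight (1 for isolated nodes)
    for i in range(n):
        incident = m[i].max()
        m[i, i] = incident if incident > 0 else 1.0

    def normalize(mat: np.ndarray) -> np.ndarray:
        sums = mat.sum(axis=0)
        sums[sums == 0] = 1.0
        return mat / sums

    m = normalize(m)
    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        m = np.power(m, inflation)     # inflation
        m[m < prune] = 0.0
        m = normalize(m)
        if np.abs(m - prev).max() < tol:
            break
    else:
        logger.warning("MCL did not converge in %d iterations", max_iter)
    return m


def _interpret(matrix: np.ndarray, nodes: Sequence[str]) -> Dict[str, int]:
    """Communities = connected components of the limit matrix's support."""
    n = len(nodes)
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(matrix > 1e-6)
    for i, j in zip(rows, cols):
        if i != j:
            support.add_edge(int(i), int(j))
    assignment: Dict[str, int] = {}
    for cid, component in enumerate(
        sorted(nx.connected_components(support), key=lambda c: sorted(c)[0])
    ):
        for idx in component:
            assignment[nodes[idx]] = cid
    return assignment


def mcl(
    graph: nx.Graph,
    inflation: float,
    prune: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> CommunityPartition:
    """Markov clustering of a weighted graph.

    Builds a column-stochastic matrix with self-loops, alternates expansion
    (matrix squaring) and inflation (entrywise power + renormalization) with
    pruning, and reads communities off the limit matrix's support. Isolated
    nodes become singleton communities.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return CommunityPartition(assignment={}, inflation=inflation)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    limit = _mcl_matrix(adj, inflation, prune=prune, tol=tol, max_iter=max_iter)
    return CommunityPartition(
        assignment=_interpret(limit, nodes), inflation=inflation
    )


# ---------------------------------------------------------------------------
# partition-quality metrics


def community_metrics(
    partition: CommunityPartition,
    graph: nx.Graph,
    consensus_das: Optional[Mapping[str, Tuple[str, ...]]] = None,
    clan_map: Optional[Mapping[str, str]] = None,
    n_nonredundant_das: Optional[int] = None,
) -> Dict[str, Optional[float]]:
    """Five partition-quality metrics, each in [0, 1].

    m1: fraction of communities whose members share a single consensus
    architecture; m2: fraction of communities with more than one cluster;
    m3: fraction of communities with zero clan entropy; m4: mean
    intra-community edge weight over the global maximum weight; m5:
    agreement between the community count and the non-redundant architecture
    count. m1/m3 are ``None`` when no architectures are supplied.
    """
    communities = partition.communities
    n_comm = len(communities)
    metrics: Dict[str, Optional[float]] = {
        "m1": None, "m2": None, "m3": None, "m4": None, "m5": None,
    }
    if n_comm == 0:
        return metrics
    clan_map = clan_map or {}
    if consensus_das:
        single_da = 0
        zero_entropy = 0
        for members in communities.values():
            das = {consensus_das[m] for m in members if m in consensus_das}
            if len(das) == 1:
                single_da += 1
            clans = [
                clan_map.get(d, d)
                for m in members if m in consensus_das
                for d in consensus_das[m]
            ]
            if clans and annotation_entropy(clans) == 0.0:
                zero_entropy += 1
        metrics["m1"] = single_da / n_comm
        metrics["m3"] = zero_entropy / n_comm
    metrics["m2"] = sum(1 for c in communities.values() if len(c) > 1) / n_comm
    weights = [d["weight"] for _, _, d in graph.edges(data=True)]
    if weights:
        max_w = max(weights)
        intra = [
            d["weight"]
            for u, v, d in graph.edges(data=True)
            if partition.assignment.get(u) == partition.assignment.get(v)
        ]
        metrics["m4"] = (float(np.mean(intra)) / max_w) if intra else 0.0
    if n_nonredundant_das is not None and n_nonredundant_das > 0:
        c, d = n_comm, n_nonredundant_das
        metrics["m5"] = 1.0 - abs(c - d) / max(c, d)
    return metrics


def composite_score(metrics: Mapping[str, Optional[float]]) -> float:
    available = [v for v in metrics.values() if v is not None]
    return float(np.mean(available)) if available else 0.0


DEFAULT_GRID = tuple(round(1.2 + 0.1 * i, 1) for i in range(19))


def select_inflation(
    graph: nx.Graph,
    consensus_das: Optional[Mapping[str, Tuple[str, ...]]] = None,
    clan_map: Optional[Mapping[str, str]] = None,
    n_nonredundant_das: Optional[int] = None,
    grid: Sequence[float] = DEFAULT_GRID,
    **mcl_kwargs,
) -> Tuple[float, CommunityPartition, List[Dict[str, float]]]:
    """Scan the inflation grid and keep the partition maximizing the
    composite (unweighted mean of available metrics); ties prefer the
    smaller inflation. Returns (inflation, partition, scan report)."""
    if not grid:
        raise ValueError("inflation grid is empty")
    best: Optional[CommunityPartition] = None
    report: List[Dict[str, float]] = []
    for inflation in grid:
        part = mcl(graph, inflation, **mcl_kwargs)
        part.metrics = community_metrics(
            part, graph, consensus_das, clan_map, n_nonredundant_das
        )
        part.composite = composite_score(part.metrics)
        report.append(
            {"inflation": inflation, "composite": part.composite,
             "n_communities": part.n_communities,
             **{k: (v if v is not None else float("nan"))
                for k, v in part.metrics.items()}}
        )
        if best is None or part.composite > best.composite + 1e-12:
            best = part
    assert best is not None
    return best.inflation, best, report


# ---------------------------------------------------------------------------
# orphan rescue


def assign_orphans(
    partition: CommunityPartition,
    all_nodes: Iterable[str],
    hits: Iterable[ProfileHit],
    min_probability: float = 0.5,
    min_coverage: float = 0.4,
) -> CommunityPartition:
    """Attach graph orphans to existing communities in three passes.

    Pass 1 joins each orphan to the community of its best qualifying hit
    (probability >= 0.5, both coverages >= 0.4; best = max probability, then
    max weight); pass 2 repeats once against the updated assignment; pass 3
    turns the remainder into singleton communities. Assigned nodes are never
    reassigned.
    """
    assignment = dict(partition.assignment)
    orphans = [n for n in sorted(set(all_nodes)) if n not in assignment]
    qualifying: Dict[str, List[ProfileHit]] = {}
    for hit in hits:
        if hit.query_gc == hit.target_gc:
            continue
        if hit.probability < min_probability:
            continue
        if hit.query_cov < min_coverage or hit.target_cov < min_coverage:
            continue
        qualifying.setdefault(hit.query_gc, []).append(hit)
        # hits qualify in both directions
        qualifying.setdefault(hit.target_gc, []).append(
            ProfileHit(
                query_gc=hit.target_gc, target_gc=hit.query_gc,
                probability=hit.probability, score=hit.score,
                aligned_cols=hit.aligned_cols,
                query_cov=hit.target_cov, target_cov=hit.query_cov,
            )
        )
    for _ in range(2):  # passes 1 and 2
        remaining = []
        for orphan in orphans:
            candidates = [
                h for h in qualifying.get(orphan, ())
                if h.target_gc in assignment
            ]
            if candidates:
                best = max(candidates, key=lambda h: (h.probability, h.weight))
                assignment[orphan] = assignment[best.target_gc]
            else:
                remaining.append(orphan)
        orphans = remaining
    next_id = max(assignment.values(), default=-1) + 1
    for orphan in orphans:  # pass 3
        assignment[orphan] = next_id
        next_id += 1
    return CommunityPartition(
        assignment=assignment,
        inflation=partition.inflation,
        metrics=dict(partition.metrics),
        composite=partition.composite,
    )


def infer_communities(
    hits_by_category: Mapping[str, Sequence[ProfileHit]],
    clusters_by_category: Mapping[str, Sequence[str]],
    consensus_das: Optional[Mapping[str, Tuple[str, ...]]] = None,
    clan_map: Optional[Mapping[str, str]] = None,
    n_nonredundant_das: Optional[int] = None,
    grid: Sequence[float] = DEFAULT_GRID,
    min_probability: float = 0.5,
    min_coverage: float = 0.6,
    rescue_min_probability: float = 0.5,
    rescue_min_coverage: float = 0.4,
) -> Tuple[Dict[str, CommunityPartition], List[Dict[str, float]]]:
    """Community inference per category.

    The inflation grid is optimized on the K graph (architectures available
    as constraints); the optimal value is reused for KWP/GU/EU. Every
    category gets the three-pass orphan rescue so all of its clusters end up
    in exactly one community.
    """
    partitions: Dict[str, CommunityPartition] = {}

    def category_hits(category: str) -> List[ProfileHit]:
        allowed = set(clusters_by_category.get(category, ()))
        return [
            h for h in hits_by_category.get(category, ())
            if h.query_gc in allowed and h.target_gc in allowed
        ]

    k_hits = category_hits("K")
    k_graph = build_gcc_graph(k_hits, min_probability, min_coverage)
    inflation, k_part, scan = select_inflation(
        k_graph, consensus_das, clan_map, n_nonredundant_das, grid
    )
    partitions["K"] = assign_orphans(
        k_part, clusters_by_category.get("K", ()), k_hits,
        rescue_min_probability, rescue_min_coverage,
    )
    for category in ("KWP", "GU", "EU"):
        cat_hits = category_hits(category)
        graph = build_gcc_graph(cat_hits, min_probability, min_coverage)
        part = mcl(graph, inflation)
        part.metrics = community_metrics(part, graph)
        part.composite = composite_score(part.metrics)
        partitions[category] = assign_orphans(
            part, clusters_by_category.get(category, ()), cat_hits,
            rescue_min_probability, rescue_min_coverage,
        )
    return partitions, scan
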