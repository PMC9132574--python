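"""Intra-cluster compositional validation.

Size flagging, per-cluster sequence similarity network (SSN) trimming,
eigenvector-centrality representative selection, MSA outlier screening,
broken-stick thresholds, shadow-gene detection and the keep/discard call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import Gene, GeneCluster

logger = logging.getLogger(__name__)


@dataclass
class ClusterValidationReport:
    cluster_id: str
    new_representative: str
    outlier_genes: Set[str] = field(default_factory=set)
    outlier_fraction: float = 0.0
    shadow_fraction: float = 0.0
    decision: str = "keep"  # keep | discard


# ---------------------------------------------------------------------------
# broken-stick threshold


def broken_stick_threshold(
    values: Sequence[float],
    method: str = "closed_form",
    n_iter: int = 100,
    seed: int = 0,
) -> float:
    """Adaptive threshold from the broken-stick null model.

    Value shares (descending) are compared to the broken-stick expectations
    ``E_k = (1/N) * sum_{i=k..N} 1/i``; the threshold is the smallest value
    whose share still exceeds its expectation (0 when no share does).

    ``method="resample"`` averages the closed form over random subsets,
    emulating the stochastic variant; it must agree with the closed form
    within one rank on well-separated inputs.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("broken-stick threshold needs at least 2 values")
    if (vals < 0).any():
        raise ValueError("broken-stick values must be non-negative")
    total = vals.sum()
    if total == 0:
        raise ValueError("broken-stick threshold undefined for all-zero input")
    if method == "resample":
        rng = np.random.default_rng(seed)
        estimates = []
        for _ in range(n_iter):
            idx = rng.choice(vals.size, size=vals.size, replace=True)
            sub = vals[idx]
            if sub.sum() == 0 or sub.size < 2:
                continue
            estimates.append(_broken_stick_closed_form(sub))
        if not estimates:
            return _broken_stick_closed_form(vals)
        return float(np.mean(estimates))
    if method != "closed_form":
        raise ValueError(f"unknown broken-stick method {method!r}")
    return _broken_stick_closed_form(vals)


def _broken_stick_closed_form(vals: np.ndarray) -> float:
    n = vals.size
    order = np.sort(vals)[::-1]
    shares = order / order.sum()
    # E_k = (1/N) * sum_{i=k..N} 1/i, computed as a reversed cumulative sum
    inv = 1.0 / np.arange(1, n + 1)
    expectations = np.cumsum(inv[::-1])[::-1] / n
    threshold = 0.0
    for k in range(n):
        if shares[k] > expectations[k]:
            threshold = float(order[k])
        else:
            break
    return threshold


# ---------------------------------------------------------------------------
# size flagging


def flag_small_clusters(
    clusters: Iterable[GeneCluster], min_size: int = 10
) -> List[GeneCluster]:
    """Mark clusters smaller than ``min_size`` as FLAGGED (they bypass
    validation, lacking enough sequences for a reliable screen)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out = []
    for cluster in clusters:
        if cluster.size < min_size:
            cluster.category = "FLAGGED"
        out.append(cluster)
    return out


# ---------------------------------------------------------------------------
# SSN construction / trimming / representative


def make_default_scorer() -> Callable[[str, str], float]:
    """Semi-global BLOSUM62 aligner returning a normalized similarity in (0,1].

    The raw semi-global score is normalized by the geometric mean of the two
    self-scores so edge weights are positive and comparable across lengths.
    """
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # free end gaps = semi-global
    try:
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    except AttributeError:  # older Biopython
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    cache: Dict[str, float] = {}

    def self_score(seq: str) -> float:
        if seq not in cache:
            cache[seq] = aligner.score(seq, seq)
        return cache[seq]

    def scorer(a: str, b: str) -> float:
        denom = np.sqrt(self_score(a) * self_score(b))
        if denom <= 0:
            return 1e-9
        sim = aligner.score(a, b) / denom
        return max(float(sim), 1e-9)

    return scorer


def build_ssn(
    members: Sequence[Gene],
    scorer: Optional[Callable[[str, str], float]] = None,
) -> nx.Graph:
    """Complete weighted graph over cluster members.

    Edge weight is the (symmetric) pairwise similarity from ``scorer``.
    """
    if len(members) < 2:
        raise ValueError("SSN needs at least 2 members")
    if scorer is None:
        scorer = make_default_scorer()
    graph = nx.Graph()
    for gene in members:
        graph.add_node(gene.id)
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            try:
                weight = scorer(a.sequence, b.sequence)
            except Exception as exc:
                raise RuntimeError(
                    f"scorer failed on pair ({a.id}, {b.id}): {exc}"
                ) from exc
            graph.add_edge(a.id, b.id, weight=float(weight))
    return graph


def trim_ssn(graph: nx.Graph) -> nx.Graph:
    """Remove low-weight edges while keeping one connected component.

    Keeps every edge with weight >= t*, where t* is the largest threshold
    leaving the graph connected — the bottleneck weight of the maximum
    spanning tree. The result spans all nodes and is connected.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph):
        raise ValueError("trim_ssn requires a connected graph")
    if graph.number_of_edges() == 0:
        return graph.copy()
    mst = nx.maximum_spanning_tree(graph, weight="weight")
    t_star = min(d["weight"] for _, _, d in mst.edges(data=True))
    trimmed = nx.Graph()
    trimmed.add_nodes_from(graph.nodes)
    trimmed.add_edges_from(
        (u, v, d) for u, v, d in graph.edges(data=True) if d["weight"] >= t_star
    )
    assert nx.is_connected(trimmed)
    return trimmed


def select_representative(
    graph: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> str:
    """Most central node by weighted eigenvector centrality (power iteration).

    Ties are broken by lexicographically smallest node id.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    if len(nodes) == 1:
        return nodes[0]
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        adj[index[u], index[v]] = w
        adj[index[v], index[u]] = w
    # diagonal shift keeps the Perron eigenvector but prevents the power
    # iteration oscillating on bipartite structures
    shift = adj.max() if adj.max() > 0 else 1.0
    adj = adj + shift * np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nxt = adj @ x
        norm = np.linalg.norm(nxt)
        if norm == 0:
            raise RuntimeError(
                "eigenvector centrality failed to converge (degenerate weights)"
            )
        nxt /= norm
        if np.abs(nxt - x).max() < tol:
            x = nxt
            break
        x = nxt
    else:
        raise RuntimeError(
            "eigenvector centrality did not converge; weights may be degenerate"
        )
    best = x.max()
    candidates = [nodes[i] for i in range(n) if x[i] >= best - 1e-12]
    return min(candidates)


# ---------------------------------------------------------------------------
# MSA and outlier screen


def naive_msa(sequences: Dict[str, str]) -> Dict[str, str]:
    """Pad-to-longest pseudo-alignment.

    Adequate for near-identical families without indels (the synthetic
    default); any real aligner producing multi-FASTA output can be supplied
    instead via file injection.
    """
    if not sequences:
        return {}
    width = max(len(s) for s in sequences.values())
    return {k: s + "-" * (width - len(s)) for k, s in sequences.items()}


def pairwise_identity_distance(a: str, b: str) -> float:
    """1 - identical fraction over columns where both sequences are non-gap."""
    both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not both:
        return 1.0
    same = sum(1 for x, y in both if x == y)
    return 1.0 - same / len(both)


def detect_msa_outliers(
    alignment: Dict[str, str],
    representative: str,
    hard_floor: float = 0.8,
) -> Set[str]:
    """Sequences non-homologous to the representative in a cluster MSA.

    Outliers have identity distance to the representative above both
    ``Q3 + 1.5*IQR`` of the distance distribution and the hard floor. The
    screen needs >= 4 sequences (IQR is meaningless below that); the
    representative is never an outlier.
    """
    if representative not in alignment:
        raise ValueError(f"representative {representative!r} absent from alignment")
    others = {k: v for k, v in alignment.items() if k != representative}
    if len(alignment) < 4:
        return set()
    rep_seq = alignment[representative]
    dists = {k: pairwise_identity_distance(rep_seq, v) for k, v in others.items()}
    arr = np.array(list(dists.values()))
    q1, q3 = np.percentile(arr, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return {k for k, d in dists.items() if d > fence and d > hard_floor}


# ---------------------------------------------------------------------------
# shadow genes


def flag_shadow_genes(
    genes: Sequence[Gene],
    opposite_strand_bp: int = 60,
    same_strand_frac: float = 0.5,
) -> Set[str]:
    """Shadow-gene screen for genes sharing one contig.

    For each overlapping pair the shorter gene is flagged when the overlap is
    >= ``opposite_strand_bp`` on opposite strands, or covers
    >= ``same_strand_frac`` of the shorter gene on the same strand. Length
    ties are broken against the gene with the larger start coordinate.
    """
    contigs = {g.contig for g in genes}
    if len(contigs) > 1:
        raise ValueError("flag_shadow_genes expects genes from a single contig")
    flagged: Set[str] = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            overlap = min(a.end, b.end) - max(a.start, b.start) + 1
            if overlap <= 0:
                continue
            shorter = min(a.length_nt, b.length_nt)
            hit = False
            if a.strand != b.strand and overlap >= opposite_strand_bp:
                hit = True
            elif a.strand == b.strand and overlap >= same_strand_frac * shorter:
                hit = True
            if hit:
                if a.length_nt != b.length_nt:
                    loser = a if a.length_nt < b.length_nt else b
                else:
                    loser = a if a.start > b.start else b
                flagged.add(loser.id)
    return flagged


# ---------------------------------------------------------------------------
# the full per-cluster screen


@dataclass
class _ClusterScreen:
    report: ClusterValidationReport
    removable: Set[str]


def _screen_cluster(
    cluster: GeneCluster,
    genes: Dict[str, Gene],
    spurious: Set[str],
    scorer: Optional[Callable[[str, str], float]],
    msa: Optional[Dict[str, str]],
    hard_floor: float,
) -> _ClusterScreen:
    members = [genes[m] for m in sorted(cluster.members)]
    if len(members) >= 2:
        ssn = build_ssn(members, scorer=scorer)
        trimmed = trim_ssn(ssn)
        rep = select_representative(trimmed)
    else:
        rep = members[0].id
    if msa is None:
        msa = naive_msa({g.id: g.sequence for g in members})
    outliers = detect_msa_outliers(msa, rep, hard_floor=hard_floor)
    shadow = {g.id for g in members if "shadow" in g.flags}
    spur = {g.id for g in members if g.id in spurious or "spurious" in g.flags}
    report = ClusterValidationReport(
        cluster_id=cluster.id,
        new_representative=rep,
        outlier_genes=outliers,
        outlier_fraction=len(outliers) / cluster.size,
        shadow_fraction=len(shadow) / cluster.size,
    )
    return _ClusterScreen(report=report, removable=outliers | shadow | spur)


def validate_clusters(
    clusters: Sequence[GeneCluster],
    genes: Dict[str, Gene],
    spurious: Optional[Set[str]] = None,
    scorer: Optional[Callable[[str, str], float]] = None,
    alignments: Optional[Dict[str, Dict[str, str]]] = None,
    shadow_discard_fraction: float = 0.30,
    msa_outlier_floor: float = 0.8,
    broken_stick_method: str = "closed_form",
) -> Tuple[List[ClusterValidationReport], List[GeneCluster]]:
    """Run the compositional screen over all non-FLAGGED clusters.

    Per cluster: SSN -> trim -> representative -> MSA outlier screen. A
    cluster is discarded when its outlier fraction exceeds the broken-stick
    threshold over all clusters' outlier fractions, or when its shadow
    fraction reaches ``shadow_discard_fraction``. Kept clusters lose their
    individual outlier/shadow/spurious genes (never the representative).

    Returns the reports and the updated cluster list (discarded clusters stay,
    labelled DISCARDED).
    """
    spurious = spurious or set()
    if scorer is None:
        scorer = make_default_scorer()
    screens: Dict[str, _ClusterScreen] = {}
    todo = [c for c in clusters if c.category != "FLAGGED"]
    for cluster in todo:
        msa = alignments.get(cluster.id) if alignments else None
        screens[cluster.id] = _screen_cluster(
            cluster, genes, spurious, scorer, msa, msa_outlier_floor
        )
    fractions = [s.report.outlier_fraction for s in screens.values()]
    if len(fractions) >= 2 and sum(fractions) > 0:
        threshold = broken_stick_threshold(fractions, method=broken_stick_method)
    else:
        threshold = 0.0
    reports = []
    for cluster in todo:
        screen = screens[cluster.id]
        report = screen.report
        if report.shadow_fraction >= shadow_discard_fraction:
            report.decision = "discard"
        elif threshold > 0 and report.outlier_fraction > threshold:
            report.decision = "discard"
        if report.decision == "discard":
            cluster.category = "DISCARDED"
        else:
            keep = cluster.members - (screen.removable - {report.new_representative})
            cluster.members = keep
            cluster.representative = report.new_representative
        reports.append(report)
    return reports, list(clusters)


def write_validation_reports(
    reports: Sequence[ClusterValidationReport], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tnew_representative\toutlier_fraction\t"
            "shadow_fraction\tn_outliers\tdecision\n"
        )
        for r in reports:
            fh.write(
                f"{r.cluster_id}\t{r.new_representative}\t"
                f"{r.outlier_fraction:.6g}\t{r.shadow_fraction:.6g}\t"
                f"{len(r.outlier_genes)}\t{r.decision}\n"
            )
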