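"""Phylogenomic characterization: lineage specificity via an F1 score over
tree clades, phylogenetic conservation (consenTRAIT-style trait depth) and
the known-vs-unknown conservation comparison."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class LineageCall:
    gc_id: str
    best_node: str
    best_f1: float
    rank: str
    is_lineage_specific: bool
    n_genomes: int = 0
    prevalence: float = 0.0


def _node_id(node: dendropy.Node, idx: int) -> str:
    if node.label:
        return str(node.label)
    return f"node_{idx}"


def lineage_f1(
    tree: dendropy.Tree,
    gc_id: str,
    presence: Set[str],
    f1_threshold: float = 0.95,
    max_prevalence: float = 0.5,
    min_genomes: int = 2,
) -> LineageCall:
    """Best-matching clade for a cluster's genome presence set.

    For each internal node, recall is the presence fraction of the clade's
    tips and precision the fraction of present genomes inside the clade;
    the best node maximizes F1 (ties prefer the deeper node, then the larger
    clade). Lineage-specific calls additionally require presence in >= 2
    genomes and in less than half of all genomes.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if not presence:
        raise ValueError("presence set is empty")
    missing = presence - tips
    if missing:
        raise ValueError(f"presence genomes not in tree: {sorted(missing)[:3]}")
    n_tips = len(tips)
    best: Optional[Tuple[float, int, int, str, dendropy.Node]] = None
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            continue
        clade_tips = {leaf.taxon.label for leaf in node.leaf_iter()}
        inter = len(presence & clade_tips)
        if inter == 0:
            continue
        recall = inter / len(clade_tips)
        precision = inter / len(presence)
        f1 = 2 * precision * recall / (precision + recall)
        depth = node.level()
        key = (f1, depth, len(clade_tips))
        if best is None or key > (best[0], best[1], best[2]):
            best = (f1, depth, len(clade_tips), _node_id(node, idx), node)
    if best is None:  # presence exists but no internal node contains it
        raise RuntimeError("no internal node overlaps the presence set")
    f1, _, _, node_id, node = best
    prevalence = len(presence) / n_tips
    is_ls = (
        f1 > f1_threshold
        and len(presence) >= min_genomes
        and prevalence < max_prevalence
    )
    return LineageCall(
        gc_id=gc_id,
        best_node=node_id,
        best_f1=float(f1),
        rank=_deepest_rank(node),
        is_lineage_specific=is_ls,
        n_genomes=len(presence),
        prevalence=prevalence,
    )


def _deepest_rank(node: dendropy.Node) -> str:
    """Rank of the deepest rank-labelled ancestor (including the node)."""
    current = node
    while current is not None:
        label = (current.label or "").strip().lower()
        for rank in RANKS:
            if label.startswith(rank):
                return rank
        current = current.parent_node
    return ""


def consentrait_tau(
    tree: dendropy.Tree,
    presence: Set[str],
    threshold: float = 0.9,
) -> float:
    """Mean depth of the maximal clades predominantly carrying a trait.

    A clade qualifies when >= ``threshold`` of its tips carry the cluster;
    qualifying clades are maximal (the traversal does not descend into
    them). Clade depth is the mean root-to-tip path length measured from the
    clade root; an isolated positive tip contributes half its terminal
    branch length. The result is the mean depth over all clades found.
    """
    if not presence:
        raise ValueError("presence set is empty")
    depths: List[float] = []

    def tip_stats(node: dendropy.Node) -> Tuple[int, int]:
        leaves = list(node.leaf_iter())
        positives = sum(1 for l in leaves if l.taxon.label in presence)
        return positives, len(leaves)

    def mean_depth(node: dendropy.Node) -> float:
        total, count = 0.0, 0
        stack = [(node, 0.0)]
        while stack:
            current, dist = stack.pop()
            if current.is_leaf():
                total += dist
                count += 1
            else:
                for child in current.child_nodes():
                    stack.append((child, dist + (child.edge.length or 0.0)))
        return total / count if count else 0.0

    def visit(node: dendropy.Node) -> None:
        if node.is_leaf():
            if node.taxon.label in presence:
                depths.append(0.5 * (node.edge.length or 0.0))
            return
        positives, n = tip_stats(node)
        if positives == 0:
            return
        if n >= 2 and positives / n >= threshold:
            depths.append(mean_depth(node))
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.seed_node)
    if not depths:
        raise RuntimeError("no clade or tip carries the trait")
    return float(np.mean(depths))


@dataclass
class ConservationComparison:
    statistic: float
    p_value: float
    median_known: float
    median_unknown: float
    direction: str
    n_pairs: int


def compare_conservation(
    tau: Mapping[str, float],
    is_known: Mapping[str, bool],
    is_lineage_specific: Mapping[str, bool],
) -> ConservationComparison:
    """Paired (signed-rank) comparison of known vs unknown trait depths.

    Within each lineage-specific / non-specific stratum the known and
    unknown depth distributions are rank-matched (sorted values paired up to
    the smaller group size); the pooled pairs feed a Wilcoxon signed-rank
    test. All-tied input returns p = 1 with a warning.
    """
    pairs: List[Tuple[float, float]] = []
    for stratum in (True, False):
        known = sorted(
            tau[g] for g in tau if is_known.get(g) and
            is_lineage_specific.get(g, False) == stratum
        )
        unknown = sorted(
            tau[g] for g in tau if not is_known.get(g, True) and
            is_lineage_specific.get(g, False) == stratum
        )
        n = min(len(known), len(unknown))
        pairs.extend(zip(known[:n], unknown[:n]))
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs")
    known_vals = np.array([p[0] for p in pairs])
    unknown_vals = np.array([p[1] for p in pairs])
    diffs = unknown_vals - known_vals
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p-value set to 1")
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(unknown_vals, known_vals, zero_method="wilcox")
        stat, p = float(res.statistic), float(res.pvalue)
    med_known = float(np.median(known_vals))
    med_unknown = float(np.median(unknown_vals))
    if med_unknown > med_known:
        direction = "unknown > known"
    elif med_unknown < med_known:
        direction = "unknown < known"
    else:
        direction = "unknown == known"
    return ConservationComparison(
        statistic=stat,
        p_value=p,
        median_known=med_known,
        median_unknown=med_unknown,
        direction=direction,
        n_pairs=len(pairs),
    )


def exclude_prophage_presence(
    presence: Mapping[str, Set[str]],
    prophage_by_gc_genome: Mapping[Tuple[str, str], Sequence[bool]],
) -> Dict[str, Set[str]]:
    """Drop a genome from a cluster's presence set when every member gene of
    that cluster in that genome lies in a flagged prophage region."""
    out: Dict[str, Set[str]] = {}
    for gc, genomes in presence.items():
        kept = set()
        for genome in genomes:
            flags = prophage_by_gc_genome.get((gc, genome))
            if flags and all(flags):
                continue
            kept.add(genome)
        out[gc] = kept
    return out
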