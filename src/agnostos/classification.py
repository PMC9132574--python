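"""Cluster categorization: consensus domain architectures, the K / KWP / GU /
EU partition, remote-homology refinement, high-quality selection and the
non-redundant architecture set.

Category semantics: K = at least one Pfam domain of known function; KWP =
homology to characterized proteins but no Pfam; GU = unknown function seen in
genomic databases (or DUF-only annotation); EU = no homolog anywhere.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from math import log10, sqrt
from typing import (
    Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple,
)

import numpy as np

from .config import DEFAULT_UNKNOWN_TERMS
from .functional import DomainArchitecture
from .model import GeneCluster, HomologHit, RefinementHit
from .validation import broken_stick_threshold

_DUF_RE = re.compile(r"^DUF\d+", re.IGNORECASE)


@dataclass
class CategoryDecision:
    cluster_id: str
    category: str  # K, KWP, GU, EU
    evidence: str


def make_duf_predicate(extra_accessions: Iterable[str] = ()) -> Callable[[str], bool]:
    """Predicate for Pfam domains of unknown function: DUF-style names plus a
    configurable accession list."""
    accessions = {a.upper() for a in extra_accessions}
    def predicate(domain: str) -> bool:
        return bool(_DUF_RE.match(domain)) or domain.upper() in accessions
    return predicate


def make_unknown_matcher(
    terms: Sequence[str] = DEFAULT_UNKNOWN_TERMS,
) -> Callable[[str], bool]:
    """Case-insensitive substring matcher for unknown-function annotations."""
    lowered = [t.lower() for t in terms]
    def matcher(annotation: str) -> bool:
        text = annotation.lower()
        return any(t in text for t in lowered)
    return matcher


# ---------------------------------------------------------------------------
# consensus domain architecture


def _collapse_repeats(domains: Sequence[str]) -> Tuple[str, ...]:
    out: List[str] = []
    for d in domains:
        if not out or out[-1] != d:
            out.append(d)
    return tuple(out)


def consensus_da(
    gene_das: Mapping[str, DomainArchitecture],
    completeness: Mapping[str, bool],
    incomplete_weight: float = 0.5,
) -> Tuple[str, ...]:
    """Consensus architecture of a cluster's annotated genes.

    Consecutive repeats of one domain are collapsed per gene; each gene then
    contributes its transition path (virtual source -> domains -> sink) with
    weight 1 for complete genes and ``incomplete_weight`` for incomplete
    ones. The consensus is the candidate path with maximum total edge
    weight; ties prefer the path supported by more complete genes, then the
    lexicographically smallest architecture.
    """
    if not gene_das:
        raise ValueError("consensus_da needs at least one annotated gene")
    edge_weight: Dict[Tuple[str, str], float] = defaultdict(float)
    path_complete: Dict[Tuple[str, ...], int] = defaultdict(int)
    paths: Set[Tuple[str, ...]] = set()
    for gene, da in gene_das.items():
        collapsed = _collapse_repeats(da.domains)
        paths.add(collapsed)
        w = 1.0 if completeness.get(gene, False) else incomplete_weight
        nodes = ("<s>",) + collapsed + ("<t>",)
        for a, b in zip(nodes, nodes[1:]):
            edge_weight[(a, b)] += w
        if completeness.get(gene, False):
            path_complete[collapsed] += 1

    def path_score(path: Tuple[str, ...]) -> float:
        nodes = ("<s>",) + path + ("<t>",)
        return sum(edge_weight[(a, b)] for a, b in zip(nodes, nodes[1:]))

    best_score = max(path_score(p) for p in paths)
    candidates = [p for p in paths if path_score(p) == best_score]
    best_complete = max(path_complete[p] for p in candidates)
    return min(p for p in candidates if path_complete[p] == best_complete)


def classify_annotated(
    consensus: Sequence[str],
    duf_predicate: Optional[Callable[[str], bool]] = None,
) -> str:
    """GU iff every consensus domain is of unknown function, else K."""
    if not consensus:
        raise ValueError("empty consensus architecture")
    duf_predicate = duf_predicate or make_duf_predicate()
    return "GU" if all(duf_predicate(d) for d in consensus) else "K"


# ---------------------------------------------------------------------------
# homolog filtering + voting


def filter_homologs(
    hits: Sequence[HomologHit], log_fraction: float = 0.6
) -> List[HomologHit]:
    """Keep hits within ``log_fraction`` of the log of the best e-value.

    With ``L = |log10(best e-value)|``, a hit is retained when
    ``|log10(e)| >= log_fraction * L``; the best hit is always retained.
    """
    if not hits:
        raise ValueError("filter_homologs needs at least one hit")
    best = min(hits, key=lambda h: h.evalue)
    cutoff = log_fraction * abs(log10(best.evalue))
    kept = [h for h in hits if abs(log10(h.evalue)) >= cutoff]
    if best not in kept:
        kept.append(best)
    return kept


def vote_category(
    hits: Sequence[HomologHit],
    unknown_matcher: Optional[Callable[[str], bool]] = None,
    weight_by_bitscore: bool = False,
) -> str:
    """Quorum majority vote over retained hits: ``unknown`` needs a strict
    majority of unknown-function annotations; ties go to ``known``."""
    if not hits:
        raise ValueError("vote_category needs at least one hit")
    unknown_matcher = unknown_matcher or make_unknown_matcher()
    unknown_mass = 0.0
    total = 0.0
    for h in hits:
        w = h.bitscore if weight_by_bitscore else 1.0
        total += w
        if h.target_is_duf or unknown_matcher(h.target_annotation):
            unknown_mass += w
    return "unknown" if unknown_mass > 0.5 * total else "known"


def classify_unannotated(
    uniref_hits: Sequence[HomologHit],
    nr_hits: Sequence[HomologHit],
    unknown_matcher: Optional[Callable[[str], bool]] = None,
    log_fraction: float = 0.6,
    weight_by_bitscore: bool = False,
) -> str:
    """Nested-search categorization of clusters without a Pfam consensus.

    Stage 1 votes on the filtered UniRef-tier hits (unknown -> GU, known ->
    KWP); stage 2 applies the same vote to the nr-tier hits; clusters with no
    hit anywhere are EU.
    """
    for hits in (uniref_hits, nr_hits):
        if hits:
            vote = vote_category(
                filter_homologs(hits, log_fraction),
                unknown_matcher,
                weight_by_bitscore,
            )
            return "GU" if vote == "unknown" else "KWP"
    return "EU"


# ---------------------------------------------------------------------------
# remote-homology refinement


def _refinement_vote(
    hits: Sequence[RefinementHit],
    unknown_matcher: Callable[[str], bool],
) -> str:
    unknown = sum(
        1 for h in hits if h.target_is_duf or unknown_matcher(h.target_annotation)
    )
    return "unknown" if unknown > 0.5 * len(hits) else "known"


def refine_eu(
    hits: Sequence[RefinementHit],
    unknown_matcher: Optional[Callable[[str], bool]] = None,
    min_probability: float = 0.90,
) -> str:
    """Re-categorize an EU cluster from profile hits against reference
    profiles: qualifying hits (probability >= 90%) are re-voted — known ->
    KWP, unknown -> GU; no qualifying hit leaves the cluster EU."""
    unknown_matcher = unknown_matcher or make_unknown_matcher()
    qualifying = [h for h in hits if h.probability >= min_probability]
    if not qualifying:
        return "EU"
    return "KWP" if _refinement_vote(qualifying, unknown_matcher) == "known" else "GU"


def _resolve_overlaps(hits: List[RefinementHit]) -> List[RefinementHit]:
    """Drop the worse (larger e-value) hit of any pair overlapping > 50% of
    the shorter hit on the query."""
    kept: List[RefinementHit] = []
    for h in sorted(hits, key=lambda x: (x.evalue, x.target)):
        clash = False
        for k in kept:
            if h.q_end < h.q_start or k.q_end < k.q_start:
                continue
            overlap = min(h.q_end, k.q_end) - max(h.q_start, k.q_start) + 1
            shorter = min(h.q_end - h.q_start + 1, k.q_end - k.q_start + 1)
            if shorter > 0 and overlap > 0.5 * shorter:
                clash = True
                break
        if not clash:
            kept.append(h)
    return kept


def refine_kwp(
    hits: Sequence[RefinementHit],
    duf_predicate: Optional[Callable[[str], bool]] = None,
    min_probability: float = 0.90,
    min_target_cov: float = 0.60,
) -> str:
    """Re-categorize a KWP cluster from Pfam-profile hits.

    Qualifying hits need probability >= 90% and target coverage > 60%;
    overlapping hits keep the smaller e-value. Any qualifying hit to a known
    Pfam sends the cluster to K; qualifying DUF-only hits send it to GU;
    otherwise it stays KWP.
    """
    duf_predicate = duf_predicate or make_duf_predicate()
    qualifying = [
        h for h in hits
        if h.probability >= min_probability and h.target_cov > min_target_cov
    ]
    if not qualifying:
        return "KWP"
    resolved = _resolve_overlaps(list(qualifying))
    if any(not duf_predicate(h.target) for h in resolved):
        return "K"
    return "GU"


# ---------------------------------------------------------------------------
# orchestration


def classify_clusters(
    clusters: Sequence[GeneCluster],
    gene_das: Mapping[str, DomainArchitecture],
    completeness: Mapping[str, bool],
    uniref_hits: Mapping[str, Sequence[HomologHit]],
    nr_hits: Mapping[str, Sequence[HomologHit]],
    eu_refinement_hits: Optional[Mapping[str, Sequence[RefinementHit]]] = None,
    kwp_refinement_hits: Optional[Mapping[str, Sequence[RefinementHit]]] = None,
    unknown_matcher: Optional[Callable[[str], bool]] = None,
    duf_predicate: Optional[Callable[[str], bool]] = None,
    log_fraction: float = 0.6,
    weight_by_bitscore: bool = False,
) -> List[CategoryDecision]:
    """Assign exactly one of K/KWP/GU/EU to every validated cluster.

    Clusters with annotated genes go through the consensus architecture
    route; the rest through the nested homology search; EU and KWP calls are
    then refined against profile hits when supplied. Sets ``category`` and
    ``consensus_da`` on the clusters in place.
    """
    unknown_matcher = unknown_matcher or make_unknown_matcher()
    duf_predicate = duf_predicate or make_duf_predicate()
    eu_refinement_hits = eu_refinement_hits or {}
    kwp_refinement_hits = kwp_refinement_hits or {}
    decisions: List[CategoryDecision] = []
    for cluster in clusters:
        if cluster.category in ("FLAGGED", "DISCARDED"):
            continue
        annotated = {
            g: gene_das[g] for g in cluster.members if g in gene_das
        }
        if annotated:
            consensus = consensus_da(annotated, completeness)
            cluster.consensus_da = consensus
            category = classify_annotated(consensus, duf_predicate)
            evidence = f"consensus_da:{'|'.join(consensus)}"
        else:
            u_hits = list(uniref_hits.get(cluster.id, ()))
            n_hits = list(nr_hits.get(cluster.id, ()))
            category = classify_unannotated(
                u_hits, n_hits, unknown_matcher, log_fraction, weight_by_bitscore
            )
            if category == "EU":
                evidence = "no_hits"
            else:
                used = u_hits or n_hits
                retained = filter_homologs(used, log_fraction)
                unknowns = sum(
                    1 for h in retained
                    if h.target_is_duf or unknown_matcher(h.target_annotation)
                )
                evidence = f"vote(n_hits={len(retained)},unknown_fraction={unknowns / len(retained):.3f})"
        if category == "EU" and cluster.id in eu_refinement_hits:
            refined = refine_eu(eu_refinement_hits[cluster.id], unknown_matcher)
            if refined != "EU":
                evidence = "refined_from:EU"
                category = refined
        if category == "KWP" and cluster.id in kwp_refinement_hits:
            refined = refine_kwp(kwp_refinement_hits[cluster.id], duf_predicate)
            if refined != "KWP":
                evidence = "refined_from:KWP"
                category = refined
        cluster.category = category
        decisions.append(
            CategoryDecision(cluster_id=cluster.id, category=category, evidence=evidence)
        )
    return decisions


# ---------------------------------------------------------------------------
# high-quality subset


def select_high_quality(
    clusters: Sequence[GeneCluster],
    completeness: Mapping[str, bool],
    min_fraction: float = 1.0 / 3.0,
) -> Dict[str, bool]:
    """Flag clusters whose representative is complete and whose complete-gene
    fraction clears both the fixed floor and the broken-stick threshold over
    the completeness-fraction distribution."""
    usable = [c for c in clusters if c.category in ("K", "KWP", "GU", "EU")]
    fractions = {
        c.id: sum(1 for m in c.members if completeness.get(m, False)) / c.size
        for c in usable
    }
    values = list(fractions.values())
    if len(values) >= 2 and sum(values) > 0:
        bs = broken_stick_threshold(values)
    else:
        bs = 0.0
    cutoff = max(min_fraction, bs)
    flags: Dict[str, bool] = {}
    for c in usable:
        hq = completeness.get(c.representative, False) and fractions[c.id] > cutoff
        c.is_high_quality = hq
        flags[c.id] = hq
    return flags


# ---------------------------------------------------------------------------
# non-redundant domain architectures


def _qgram_profile(text: str, q: int = 3) -> Counter:
    if len(text) < q:
        return Counter([text])
    return Counter(text[i : i + q] for i in range(len(text) - q + 1))


def qgram_cosine_distance(a: str, b: str, q: int = 3) -> float:
    """Cosine distance between character q-gram profiles of two strings."""
    pa, pb = _qgram_profile(a, q), _qgram_profile(b, q)
    dot = sum(pa[g] * pb.get(g, 0) for g in pa)
    na = sqrt(sum(v * v for v in pa.values()))
    nb = sqrt(sum(v * v for v in pb.values()))
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def _is_contiguous_subarchitecture(
    small: Tuple[str, ...], large: Tuple[str, ...]
) -> bool:
    if len(small) >= len(large):
        return False
    return any(
        large[i : i + len(small)] == small
        for i in range(len(large) - len(small) + 1)
    )


def collapse_fragmented_das(
    das: Sequence[Tuple[Tuple[str, ...], float]],
    max_cosine_distance: float = 0.9,
    complete_fraction_cutoff: float = 0.75,
) -> List[Tuple[str, ...]]:
    """Collapse fragmented architectures into their parent architectures.

    Input: ``(architecture, complete-gene fraction)`` pairs. Candidate pairs
    are those whose 3-gram cosine distance on the joined token string is
    below ``max_cosine_distance``; a fragment that is a contiguous
    sub-architecture of a larger one and comes from a cluster with fewer than
    ``complete_fraction_cutoff`` complete genes is merged into the larger.
    Returns the distinct surviving architectures.
    """
    distinct: Dict[Tuple[str, ...], float] = {}
    for da, frac in das:
        # keep the highest completeness seen for a duplicated architecture
        if da not in distinct or frac > distinct[da]:
            distinct[da] = frac
    merged: Set[Tuple[str, ...]] = set()
    items = sorted(distinct, key=lambda d: (len(d), d))
    for small, large in combinations(items, 2):
        if small in merged:
            continue
        dist = qgram_cosine_distance(" ".join(small), " ".join(large))
        if dist >= max_cosine_distance:
            continue
        if (
            _is_contiguous_subarchitecture(small, large)
            and distinct[small] < complete_fraction_cutoff
        ):
            merged.add(small)
    return [d for d in items if d not in merged]
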