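"""Domain-annotation homogeneity of clusters.

w-shingling of domain architectures, clan-aware Jaccard similarity, the
median-homogeneity keep/discard rule, and annotation-frequency entropy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import DomainHit

#: a token is (domain, clan, terminal_variant); order follows env_start
DAToken = Tuple[str, str, str]


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered list of domain tokens along a gene."""

    tokens: Tuple[DAToken, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def domains(self) -> Tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)


def domain_architecture(hits: Sequence[DomainHit]) -> DomainArchitecture:
    """Build a gene's architecture from its domain hits (ascending env_start)."""
    if not hits:
        raise ValueError("cannot build an architecture without domain hits")
    ordered = sorted(hits, key=lambda h: (h.env_start, h.env_end, h.domain))
    return DomainArchitecture(
        tokens=tuple((h.domain, h.clan, h.terminal_variant) for h in ordered)
    )


def architectures_by_gene(
    hits: Iterable[DomainHit],
) -> Dict[str, DomainArchitecture]:
    by_gene: Dict[str, List[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    return {g: domain_architecture(hs) for g, hs in by_gene.items()}


def shingles(da: DomainArchitecture, k: int = 2) -> FrozenSet[Tuple[DAToken, ...]]:
    """Set of consecutive k-tuples of tokens; a short architecture (< k)
    yields itself as a single shingle."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(da) == 0:
        raise ValueError("empty domain architecture")
    if len(da) < k:
        return frozenset({da.tokens})
    return frozenset(da.tokens[i : i + k] for i in range(len(da) - k + 1))


def _canonical_token(token: DAToken, clan_map: Mapping[str, str]) -> str:
    domain, clan, _variant = token
    # strip explicit N/C/M suffixes so terminal variants of a domain compare equal
    for suffix in ("_N", "_C", "_M"):
        if domain.endswith(suffix):
            domain = domain[: -len(suffix)]
            break
    clan = clan or clan_map.get(domain, "")
    return clan if clan else domain


def clan_jaccard(
    s1: FrozenSet[Tuple[DAToken, ...]],
    s2: FrozenSet[Tuple[DAToken, ...]],
    clan_map: Optional[Mapping[str, str]] = None,
) -> float:
    """Jaccard similarity of shingle sets after clan collapse.

    Each domain is replaced by its clan when it has one, and N/C/M terminal
    variants of one domain compare equal.
    """
    clan_map = clan_map or {}

    def canon(shingle_set):
        return {
            tuple(_canonical_token(t, clan_map) for t in sh) for sh in shingle_set
        }

    c1, c2 = canon(s1), canon(s2)
    if not c1 and not c2:
        return 1.0
    union = c1 | c2
    return len(c1 & c2) / len(union)


def cluster_functional_homogeneity(
    das: Mapping[str, DomainArchitecture],
    clan_map: Optional[Mapping[str, str]] = None,
    k: int = 2,
) -> Tuple[Optional[float], bool]:
    """Median pairwise clan-aware Jaccard over a cluster's annotated genes.

    Returns ``(median, keep)``: keep iff the median equals 1. Clusters with
    fewer than 2 annotated genes pass by default (median ``None``).
    Unannotated genes are excluded from the median.
    """
    annotated = sorted(das)
    if len(annotated) < 2:
        return None, True
    sets = {g: shingles(das[g], k=k) for g in annotated}
    sims = [
        clan_jaccard(sets[a], sets[b], clan_map)
        for a, b in combinations(annotated, 2)
    ]
    median = float(np.median(sims))
    return median, median == 1.0


def annotation_entropy(labels: Sequence[str]) -> float:
    """Shannon entropy (natural log) of annotation label frequencies."""
    if not labels:
        raise ValueError("annotation_entropy needs a non-empty label list")
    counts = np.array(list(Counter(labels).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())
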