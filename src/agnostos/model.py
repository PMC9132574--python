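"""Domain types shared by every pipeline stage.

All coordinates are 1-based inclusive (Pfam/hmmsearch convention). Strand is
stored but never used to flip residue coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

#: smallest value an e-value of exactly 0 is clamped to, so log10 is defined
EVALUE_FLOOR = 1e-308

GENE_FLAGS = frozenset({"spurious", "shadow", "in_prophage"})
CATEGORIES = ("K", "KWP", "GU", "EU")


@dataclass
class Gene:
    """A predicted protein-coding gene.

    ``is_complete`` is True only when both gene ends were predicted intact
    (Prodigal ``partial=00``).
    """

    id: str
    sequence: str
    is_complete: bool = False
    origin: str = ""
    contig: str = ""
    start: int = 1
    end: int = 1
    strand: str = "+"
    flags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if not self.sequence:
            raise ValueError(f"gene {self.id}: empty sequence")
        bad = set(self.flags) - GENE_FLAGS
        if bad:
            raise ValueError(f"gene {self.id}: unknown flags {sorted(bad)}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainHit:
    """A single Pfam-style domain annotation on a gene."""

    gene_id: str
    domain: str
    clan: str = ""
    env_start: int = 1
    env_end: int = 1
    i_evalue: float = 1.0
    coverage: float = 1.0
    terminal_variant: str = "none"  # one of N, C, M, none

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValueError(
                f"domain hit {self.gene_id}/{self.domain}: env_start > env_end"
            )
        if self.i_evalue < 0:
            raise ValueError(f"domain hit {self.gene_id}/{self.domain}: negative e-value")
        if self.terminal_variant not in ("N", "C", "M", "none"):
            raise ValueError(
                f"domain hit {self.gene_id}/{self.domain}: bad terminal variant "
                f"{self.terminal_variant!r}"
            )


@dataclass
class GeneCluster:
    """A set of homologous genes with one representative."""

    id: str
    representative: str
    members: Set[str]
    category: str = ""  # K, KWP, GU, EU, DISCARDED, FLAGGED or "" (unset)
    consensus_da: Tuple[str, ...] = ()
    is_high_quality: bool = False

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if self.representative not in self.members:
            raise ValueError(
                f"cluster {self.id}: representative {self.representative} not a member"
            )
        if len(self.members) < 1:
            raise ValueError(f"cluster {self.id}: empty membership")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HomologHit:
    """A sequence-level homology hit (MMseqs2/BLAST outfmt6 style)."""

    query: str
    target: str
    evalue: float
    bitscore: float = 0.0
    query_cov: float = 0.0
    target_cov: float = 0.0
    target_annotation: str = ""
    target_is_duf: bool = False

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            # reported zeros are clamped so log transforms stay defined
            self.evalue = EVALUE_FLOOR


@dataclass
class ProfileHit:
    """A profile-vs-profile (HMM/HMM) hit between two clusters."""

    query_gc: str
    target_gc: str
    probability: float
    score: float = 0.0
    aligned_cols: int = 1
    query_cov: float = 0.0
    target_cov: float = 0.0

    def __post_init__(self) -> None:
        if self.probability > 1.0:
            # percent convention auto-detected on ingest
            self.probability = self.probability / 100.0
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"profile hit {self.query_gc}->{self.target_gc}: probability "
                f"{self.probability} outside [0,1]"
            )
        if self.aligned_cols < 1:
            raise ValueError(
                f"profile hit {self.query_gc}->{self.target_gc}: aligned_cols < 1"
            )

    @property
    def weight(self) -> float:
        """Edge weight used for community graphs: score over aligned columns."""
        return self.score / self.aligned_cols


@dataclass
class RefinementHit:
    """A profile hit against a reference profile database, with annotation.

    Used for the EU (vs a clustered-protein database) and KWP (vs Pfam
    profiles) remote-homology refinement screens.
    """

    query_gc: str
    target: str
    probability: float
    target_cov: float = 0.0
    target_annotation: str = ""
    target_is_duf: bool = False
    evalue: float = 1.0
    q_start: int = 0
    q_end: int = 0

    def __post_init__(self) -> None:
        if self.probability > 1.0:
            self.probability = self.probability / 100.0
        if self.evalue <= 0:
            self.evalue = EVALUE_FLOOR


class AbundanceMatrix:
    """Non-negative cluster-by-sample abundance matrix.

    Thin wrapper over a pandas DataFrame enforcing the non-negativity and
    unique-label invariants.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValueError("abundance matrix labels must be unique")
        values = data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("abundance matrix has negative entries")
        self.data = data.astype(float)

    @property
    def gc_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def tss(self) -> "AbundanceMatrix":
        """Total-sum-scale each sample column to proportions (empty stay 0)."""
        values = self.data.to_numpy(dtype=float)
        sums = values.sum(axis=0)
        scaled = np.divide(values, sums, out=np.zeros_like(values), where=sums > 0)
        return AbundanceMatrix(
            pd.DataFrame(scaled, index=self.data.index, columns=self.data.columns)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return self.data.equals(other.data)
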