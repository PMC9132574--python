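"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython; TSV dialects via pandas; Newick via dendropy.
"""

from __future__ import annotations

import logging
import re
from typing import Dict, List, Sequence, Set, Tuple, Union

import dendropy
import pandas as pd
from Bio import SeqIO

from .model import (
    DomainHit,
    Gene,
    GeneCluster,
    HomologHit,
    ProfileHit,
    RefinementHit,
)

logger = logging.getLogger(__name__)

_PARTIAL_RE = re.compile(r"partial=(\d{2})")
_PRODIGAL_RE = re.compile(
    r"#\s*(\d+)\s*#\s*(\d+)\s*#\s*(-?1)\s*#"  # start, end, strand
)


def read_genes(path: str) -> List[Gene]:
    """Read predicted genes from FASTA with Prodigal-style headers.

    Completeness comes from the ``partial=XX`` token: ``partial=00`` means
    both ends intact. A missing token yields ``is_complete=False`` with a
    warning. Prodigal coordinate fields (``# start # end # strand #``) are
    parsed when present.
    """
    genes: List[Gene] = []
    seen: Set[str] = set()
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except (ValueError, Exception) as exc:  # Biopython raises ValueError
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    for rec in records:
        if not rec.id:
            raise ValueError(f"malformed FASTA {path}: record with empty id")
        if rec.id in seen:
            raise ValueError(f"duplicate gene id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        m = _PARTIAL_RE.search(desc)
        if m is None:
            logger.warning("gene %s: no partial= token, assuming incomplete", rec.id)
            is_complete = False
        else:
            is_complete = m.group(1) == "00"
        start, end, strand = 1, max(1, 3 * len(rec.seq)), "+"
        pm = _PRODIGAL_RE.search(desc)
        if pm:
            start, end = int(pm.group(1)), int(pm.group(2))
            strand = "+" if pm.group(3) == "1" else "-"
        contig = rec.id.rsplit("_", 1)[0]
        genes.append(
            Gene(
                id=rec.id,
                sequence=str(rec.seq),
                is_complete=is_complete,
                contig=contig,
                start=start,
                end=end,
                strand=strand,
            )
        )
    return genes


def write_genes(genes: Sequence[Gene], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            partial = "00" if g.is_complete else "10"
            strand = "1" if g.strand == "+" else "-1"
            fh.write(
                f">{g.id} # {g.start} # {g.end} # {strand} # partial={partial}\n"
            )
            seq = g.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_cluster_membership(path: str) -> List[GeneCluster]:
    """Read an MMseqs2-style cluster TSV: ``representative<TAB>member``.

    One cluster per distinct representative. A member mapped to two
    different representatives is a consistency error.
    """
    member_rep: Dict[str, str] = {}
    order: List[str] = []
    members: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            rep, member = parts
            if member in member_rep and member_rep[member] != rep:
                raise ValueError(
                    f"{path}:{lineno}: member {member!r} mapped to both "
                    f"{member_rep[member]!r} and {rep!r}"
                )
            member_rep[member] = rep
            if rep not in members:
                members[rep] = set()
                order.append(rep)
            members[rep].add(member)
    clusters = []
    for rep in order:
        mset = members[rep]
        mset.add(rep)
        clusters.append(GeneCluster(id=rep, representative=rep, members=mset))
    return clusters


def write_cluster_membership(clusters: Sequence[GeneCluster], path: str) -> None:
    """Write rep->member pairs. The cluster id (its original representative)
    keys the first column so cluster identity is stable across stages even
    when validation elects a new representative."""
    with open(path, "w") as fh:
        for c in clusters:
            key = c.id if c.id in c.members else c.representative
            for member in sorted(c.members):
                fh.write(f"{key}\t{member}\n")


_HIT_SCHEMAS = {
    "domain": (
        ["gene_id", "domain", "clan", "env_start", "env_end", "i_evalue",
         "coverage", "terminal_variant"],
        DomainHit,
    ),
    "homolog": (
        ["query", "target", "evalue", "bitscore", "query_cov", "target_cov",
         "target_annotation", "target_is_duf"],
        HomologHit,
    ),
    "profile": (
        ["query_gc", "target_gc", "probability", "score", "aligned_cols",
         "query_cov", "target_cov"],
        ProfileHit,
    ),
    "refinement": (
        ["query_gc", "target", "probability", "target_cov", "target_annotation",
         "target_is_duf", "evalue", "q_start", "q_end"],
        RefinementHit,
    ),
}

HitType = Union[DomainHit, HomologHit, ProfileHit, RefinementHit]


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "t", "yes")


def read_hits(path: str, kind: str) -> List[HitType]:
    """Read a typed hit table; rows violating invariants are dropped and logged.

    ``kind`` is one of ``domain``, ``homolog``, ``profile``, ``refinement``.
    A wrong column count is a format error reported with its line number.
    """
    if kind not in _HIT_SCHEMAS:
        raise ValueError(f"unknown hit kind {kind!r}")
    columns, cls = _HIT_SCHEMAS[kind]
    hits: List[HitType] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(columns):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(columns)} columns for "
                    f"kind {kind!r}, got {len(parts)}"
                )
            kwargs = dict(zip(columns, parts))
            try:
                for key in kwargs:
                    if key in ("env_start", "env_end", "aligned_cols",
                               "q_start", "q_end"):
                        kwargs[key] = int(kwargs[key])
                    elif key in ("i_evalue", "coverage", "evalue", "bitscore",
                                 "query_cov", "target_cov", "probability",
                                 "score"):
                        kwargs[key] = float(kwargs[key])
                    elif key == "target_is_duf":
                        kwargs[key] = _parse_bool(kwargs[key])
                hits.append(cls(**kwargs))
            except (ValueError, TypeError) as exc:
                dropped += 1
                logger.info("%s:%d: dropped invalid %s row (%s)", path, lineno,
                            kind, exc)
    if dropped:
        logger.warning("%s: dropped %d invalid %s rows", path, dropped, kind)
    return hits


def write_hits(hits: Sequence[HitType], path: str, kind: str) -> None:
    columns, _ = _HIT_SCHEMAS[kind]
    with open(path, "w") as fh:
        for hit in hits:
            fh.write("\t".join(str(getattr(hit, c)) for c in columns) + "\n")


def read_flags(path: str) -> Dict[str, Set[str]]:
    """Read gene flags TSV (``gene_id<TAB>flag``) into a map."""
    flags: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            flags.setdefault(parts[0], set()).add(parts[1])
    return flags


def read_tree(path: str) -> dendropy.Tree:
    """Read a rooted Newick tree with optional rank-labelled internal nodes."""
    tree = dendropy.Tree.get(
        path=path, schema="newick", suppress_internal_node_taxa=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("tree has a negative branch length")
    return tree


def read_presence(path: str) -> Dict[str, Set[str]]:
    """Read GC-presence TSV (``gc_id<TAB>genome_id``) into a presence map."""
    presence: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            presence.setdefault(parts[0], set()).add(parts[1])
    return presence


def write_presence(presence: Dict[str, Set[str]], path: str) -> None:
    with open(path, "w") as fh:
        for gc in sorted(presence):
            for genome in sorted(presence[gc]):
                fh.write(f"{gc}\t{genome}\n")


def read_coverage(path: str) -> pd.DataFrame:
    """Read per-gene coverage TSV: ``gene_id<TAB>sample_id<TAB>coverage``."""
    df = pd.read_csv(
        path, sep="\t", names=["gene_id", "sample_id", "coverage"], header=None,
        dtype={"gene_id": str, "sample_id": str, "coverage": float},
    )
    if (df["coverage"] < 0).any():
        raise ValueError(f"{path}: negative coverage values")
    return df
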