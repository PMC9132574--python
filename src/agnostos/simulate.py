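"""Seeded generator of every input the pipeline consumes, with planted
ground truth.

All outputs are plain text (FASTA / TSV / Newick / JSON) and fully
determined by the seed. The planted truth is sufficient to score category
recovery, community recovery, distribution calls and lineage-specificity
calls without any external data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .model import DomainHit, Gene, HomologHit, ProfileHit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

KNOWN_ANNOTATIONS = (
    "ABC transporter ATP-binding protein",
    "serine/threonine protein kinase",
    "DNA polymerase III subunit",
    "50S ribosomal protein L3",
    "glycosyltransferase family 2",
)
UNKNOWN_ANNOTATIONS = (
    "hypothetical protein",
    "uncharacterized protein",
    "protein of unknown function",
)

PRESETS = {
    "small": dict(n_families=200, genes_per_family=20, mutation_rate=0.05,
                  intruder_rate=0.02, n_samples=16, n_groups=4, n_genomes=100),
    "medium": dict(n_families=500, genes_per_family=30, mutation_rate=0.05,
                   intruder_rate=0.02, n_samples=32, n_groups=4, n_genomes=200),
}


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every generated dataset."""

    seed: int = 0
    gene_family: Dict[str, str] = field(default_factory=dict)
    family_category: Dict[str, str] = field(default_factory=dict)
    family_community: Dict[str, str] = field(default_factory=dict)
    family_genes: Dict[str, List[str]] = field(default_factory=dict)
    intruders: Dict[str, List[str]] = field(default_factory=dict)
    gene_complete: Dict[str, bool] = field(default_factory=dict)
    gene_length: Dict[str, int] = field(default_factory=dict)
    gu_evidence_mode: Dict[str, str] = field(default_factory=dict)
    distribution_class: Dict[str, str] = field(default_factory=dict)
    lineage_node: Dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        truth = cls()
        truth.__dict__.update(data)
        return truth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    return "".join(out)


# ---------------------------------------------------------------------------
# families


def simulate_families(
    n_families: int,
    genes_per_family: int,
    mutation_rate: float = 0.05,
    intruder_rate: float = 0.0,
    seed: int = 0,
    complete_fraction: float = 0.7,
    min_length: int = 80,
    max_length: int = 400,
) -> Tuple[List[Gene], Dict[str, List[str]], SyntheticTruth]:
    """Gene families as point-mutated copies of random root proteins.

    Returns (genes, membership map rep -> members, truth). Intruders are
    unrelated random sequences of the family's root length, inserted at
    ``intruder_rate`` per member slot. Category assignment cycles through
    K / KWP / GU / EU at a 2:1:1:1 ratio; families of one category are
    grouped into planted communities of 1-4 families.
    """
    for rate in (mutation_rate, intruder_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0,1]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    genes: List[Gene] = []
    membership: Dict[str, List[str]] = {}
    category_cycle = ("K", "K", "KWP", "GU", "EU")
    for f in range(n_families):
        fam = f"fam{f:04d}"
        truth.family_category[fam] = category_cycle[f % len(category_cycle)]
        length = int(rng.integers(min_length, max_length + 1))
        root = _random_protein(rng, length)
        members: List[str] = []
        for g in range(genes_per_family):
            gid = f"{fam}_g{g:03d}"
            seq = root if mutation_rate == 0 else _mutate(rng, root, mutation_rate)
            complete = bool(rng.random() < complete_fraction)
            genes.append(_make_gene(gid, seq, complete))
            members.append(gid)
            truth.gene_family[gid] = fam
            truth.gene_complete[gid] = complete
            truth.gene_length[gid] = len(seq)
        n_intruders = int(rng.binomial(genes_per_family, intruder_rate))
        intruders = []
        for i in range(n_intruders):
            gid = f"{fam}_i{i:03d}"
            seq = _random_protein(rng, length)
            genes.append(_make_gene(gid, seq, False))
            members.append(gid)
            intruders.append(gid)
            truth.gene_family[gid] = fam
            truth.gene_complete[gid] = False
            truth.gene_length[gid] = len(seq)
        truth.intruders[fam] = intruders
        truth.family_genes[fam] = members
        membership[members[0]] = members
    _plant_communities(truth, rng)
    return genes, membership, truth


def _make_gene(gid: str, seq: str, complete: bool) -> Gene:
    return Gene(
        id=gid, sequence=seq, is_complete=complete,
        contig=gid.rsplit("_", 1)[0], start=1, end=3 * len(seq), strand="+",
    )


def _plant_communities(truth: SyntheticTruth, rng: np.random.Generator) -> None:
    for category in ("K", "KWP", "GU", "EU"):
        fams = sorted(
            f for f, c in truth.family_category.items() if c == category
        )
        i = 0
        c = 0
        while i < len(fams):
            size = int(rng.integers(1, 5))
            for fam in fams[i : i + size]:
                truth.family_community[fam] = f"{category}_comm{c:03d}"
            i += size
            c += 1


# ---------------------------------------------------------------------------
# evidence tables


def simulate_evidence(
    truth: SyntheticTruth,
    noise: float = 0.0,
    seed: int = 0,
    hits_per_cluster: int = 8,
) -> Tuple[
    List[DomainHit],
    Dict[str, List[HomologHit]],
    Dict[str, List[HomologHit]],
    Dict[str, List[ProfileHit]],
    Dict[str, str],
]:
    """Domain, homolog and profile-hit evidence consistent with the truth.

    K families carry known-domain architectures shared within their planted
    community; GU families are split between DUF-only annotation and
    unknown-term homologs (one third of the homolog-mode families appear only
    in the nr tier); KWP families have functional homologs and no domains;
    EU families have no hits at all. Planted communities of >= 2 families
    get qualifying profile hits between all pairs. ``noise`` corrupts each
    evidence record independently (and gives an EU family a spurious homolog
    hit with the same probability).

    Returns (domain hits, uniref hits by rep, nr hits by rep, profile hits
    by category, clan map).
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0,1]")
    rng = np.random.default_rng(seed)
    known_pool = [f"PF{i:05d}" for i in range(1, 61)]
    duf_pool = [f"DUF{1000 + i}" for i in range(60)]
    clan_map = {d: f"CL{(i % 20):04d}" for i, d in enumerate(known_pool)}

    # one architecture per planted community so DA-based metrics can reward
    # the planted partition
    comm_da: Dict[str, Tuple[str, ...]] = {}
    for fam, comm in sorted(truth.family_community.items()):
        if comm in comm_da:
            continue
        category = truth.family_category[fam]
        n_dom = int(rng.integers(1, 4))
        pool = known_pool if category == "K" else duf_pool
        comm_da[comm] = tuple(
            pool[int(rng.integers(0, len(pool)))] for _ in range(n_dom)
        )

    gu_fams = sorted(
        f for f, c in truth.family_category.items() if c == "GU"
    )
    for i, fam in enumerate(gu_fams):
        truth.gu_evidence_mode[fam] = "duf" if i % 2 == 0 else "homolog"

    domain_hits: List[DomainHit] = []
    uniref: Dict[str, List[HomologHit]] = {}
    nr: Dict[str, List[HomologHit]] = {}
    for fam in sorted(truth.family_genes):
        category = truth.family_category[fam]
        rep = truth.family_genes[fam][0]
        members = [
            g for g in truth.family_genes[fam]
            if g not in set(truth.intruders.get(fam, []))
        ]
        if category == "K" or (
            category == "GU" and truth.gu_evidence_mode.get(fam) == "duf"
        ):
            da = comm_da[truth.family_community[fam]]
            wrong_pool = duf_pool if category == "K" else known_pool
            for gene in members:
                pos = 1
                for domain in da:
                    name = domain
                    if noise > 0 and rng.random() < noise:
                        name = wrong_pool[int(rng.integers(0, len(wrong_pool)))]
                    width = max(20, truth.gene_length[gene] // (len(da) + 1))
                    domain_hits.append(
                        DomainHit(
                            gene_id=gene, domain=name,
                            clan=clan_map.get(name, ""),
                            env_start=pos, env_end=pos + width - 1,
                            i_evalue=1e-10, coverage=0.9,
                        )
                    )
                    pos += width
        elif category == "KWP" or (
            category == "GU" and truth.gu_evidence_mode.get(fam) == "homolog"
        ):
            unknown = category == "GU"
            pool = UNKNOWN_ANNOTATIONS if unknown else KNOWN_ANNOTATIONS
            flip_pool = KNOWN_ANNOTATIONS if unknown else UNKNOWN_ANNOTATIONS
            hits = []
            for h in range(hits_per_cluster):
                annotation = pool[int(rng.integers(0, len(pool)))]
                if noise > 0 and rng.random() < noise:
                    annotation = flip_pool[int(rng.integers(0, len(flip_pool)))]
                hits.append(
                    HomologHit(
                        query=rep, target=f"{fam}_t{h:02d}",
                        evalue=float(10.0 ** -rng.uniform(40, 50)),
                        bitscore=float(rng.uniform(100, 300)),
                        query_cov=0.9, target_cov=0.9,
                        target_annotation=annotation,
                    )
                )
            # a third of homolog-mode GU families only show up in the nr tier
            if unknown and int(fam[3:]) % 3 == 0:
                nr[rep] = hits
            else:
                uniref[rep] = hits
        else:  # EU: no evidence, unless noise plants a spurious hit
            if noise > 0 and rng.random() < noise:
                uniref[rep] = [
                    HomologHit(
                        query=rep, target=f"{fam}_spur",
                        evalue=1e-42, bitscore=150.0,
                        query_cov=0.9, target_cov=0.9,
                        target_annotation=KNOWN_ANNOTATIONS[0],
                    )
                ]

    profile_hits: Dict[str, List[ProfileHit]] = {c: [] for c in ("K", "KWP", "GU", "EU")}
    by_comm: Dict[str, List[str]] = {}
    for fam, comm in sorted(truth.family_community.items()):
        by_comm.setdefault(comm, []).append(fam)
    rep_of = {fam: truth.family_genes[fam][0] for fam in truth.family_genes}
    for comm, fams in sorted(by_comm.items()):
        category = truth.family_category[fams[0]]
        for i, a in enumerate(fams):
            for b in fams[i + 1 :]:
                score = float(rng.uniform(100, 200))
                profile_hits[category].append(
                    ProfileHit(
                        query_gc=rep_of[a], target_gc=rep_of[b],
                        probability=0.95, score=score,
                        aligned_cols=100, query_cov=0.85, target_cov=0.85,
                    )
                )
    # sub-threshold decoy edges between different communities
    comms = sorted(by_comm)
    for i in range(0, len(comms) - 1, 2):
        a_f, b_f = by_comm[comms[i]][0], by_comm[comms[i + 1]][0]
        ca = truth.family_category[a_f]
        if ca != truth.family_category[b_f]:
            continue
        profile_hits[ca].append(
            ProfileHit(
                query_gc=rep_of[a_f], target_gc=rep_of[b_f],
                probability=0.30, score=40.0, aligned_cols=100,
                query_cov=0.5, target_cov=0.5,
            )
        )
    return domain_hits, uniref, nr, profile_hits, clan_map


# ---------------------------------------------------------------------------
# ecology


def simulate_ecology(
    truth: SyntheticTruth,
    n_samples: int = 16,
    n_groups: int = 4,
    seed: int = 0,
    broad_mass: float = 0.5,
) -> Tuple[List[Tuple[str, str, float]], Dict[str, float], Dict[str, int]]:
    """Per-gene coverage with planted narrow/broad environmental structure.

    Samples are assigned to groups round-robin. Broad clusters receive the
    same abundance in every sample; narrow clusters receive abundance only
    within their home group (Dirichlet split per sample). Every sample
    column of the implied cluster-by-sample matrix sums to exactly 1, so
    total-sum scaling leaves the planted structure intact.

    Returns (coverage rows (gene, sample, coverage), per-sample gene counts,
    sample group map).
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if n_samples % n_groups:
        raise ValueError("n_samples must be divisible by n_groups")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    groups = {s: i % n_groups for i, s in enumerate(samples)}
    fams = sorted(truth.family_genes)
    narrow = [f for i, f in enumerate(fams) if i % 2 == 0]
    broad = [f for i, f in enumerate(fams) if i % 2 == 1]
    for f in narrow:
        truth.distribution_class[f] = "narrow"
    for f in broad:
        truth.distribution_class[f] = "broad"
    home = {f: i % n_groups for i, f in enumerate(narrow)}
    per_broad = broad_mass / len(broad) if broad else 0.0
    narrow_mass = 1.0 - broad_mass if broad else 1.0
    abundance: Dict[str, Dict[str, float]] = {f: {} for f in fams}
    for s in samples:
        g = groups[s]
        homed = [f for f in narrow if home[f] == g]
        if homed:
            split = rng.dirichlet(np.full(len(homed), 2.0)) * narrow_mass
            for f, v in zip(homed, split):
                abundance[f][s] = float(v)
        for f in broad:
            abundance[f][s] = per_broad
    coverage: List[Tuple[str, str, float]] = []
    for fam in fams:
        members = [
            g for g in truth.family_genes[fam]
            if g not in set(truth.intruders.get(fam, []))
        ]
        for s, value in sorted(abundance[fam].items()):
            if value <= 0:
                continue
            for gene in members:
                coverage.append(
                    (gene, s, value * truth.gene_length[gene] / len(members))
                )
    gene_counts = {
        s: float(len(truth.gene_family)) * (0.5 + rng.random()) for s in samples
    }
    return coverage, gene_counts, groups


# ---------------------------------------------------------------------------
# tree + presence


def simulate_tree_presence(
    truth: SyntheticTruth,
    n_genomes: int = 100,
    seed: int = 0,
    lineage_fraction: float = 0.3,
) -> Tuple[str, Dict[str, Set[str]]]:
    """Random rank-labelled genome tree plus a planted GC presence map.

    A coalescent-style random bifurcating tree is built over ``n_genomes``
    tips. ``lineage_fraction`` of families are planted lineage-specific:
    present in exactly the tips of one internal clade (2 <= tips < half);
    the rest are cosmopolitan, present in >= 60% of genomes. Returns the
    Newick string and the presence map keyed by family representative.
    """
    if n_genomes < 4:
        raise ValueError("need at least 4 genomes")
    rng = np.random.default_rng(seed)
    tips = [f"G{i:04d}" for i in range(n_genomes)]

    class _N:
        __slots__ = ("name", "children", "length", "tipset")
        def __init__(self, name, children=(), length=0.0):
            self.name = name
            self.children = list(children)
            self.length = length
            self.tipset = (
                {name} if not children
                else set().union(*(c.tipset for c in children))
            )

    nodes = [_N(t, length=float(rng.exponential(0.1)) + 0.01) for t in tips]
    internal: List[_N] = []
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = _N(f"tmp{counter}", children=[a, b],
                    length=float(rng.exponential(0.1)) + 0.01)
        counter += 1
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
        internal.append(parent)
    root = nodes[0]
    root.length = 0.0

    # rank labels by level from the root; label prefixes match known ranks
    level_rank = {1: "phylum", 2: "class", 3: "order", 4: "family", 5: "genus"}
    idx = [0]
    def label(node: _N, level: int) -> None:
        if node.children:
            rank = level_rank.get(level, "species") if level > 0 else "root"
            node.name = f"{rank}n{idx[0]}"
            idx[0] += 1
            for c in node.children:
                label(c, level + 1)
    label(root, 0)

    def newick(node: _N) -> str:
        if not node.children:
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}){node.name}:{node.length:.6f}"

    newick_str = newick(root) + ";"

    candidates = [
        n for n in internal
        if 2 <= len(n.tipset) < n_genomes / 2 and n is not root
    ]
    fams = sorted(truth.family_genes)
    n_lineage = int(round(lineage_fraction * len(fams)))
    presence: Dict[str, Set[str]] = {}
    for i, fam in enumerate(fams):
        rep = truth.family_genes[fam][0]
        if i < n_lineage and candidates:
            clade = candidates[int(rng.integers(0, len(candidates)))]
            presence[rep] = set(clade.tipset)
            truth.lineage_node[fam] = clade.name
        else:
            size = int(np.ceil(0.6 * n_genomes) + rng.integers(0, n_genomes // 5))
            size = min(size, n_genomes)
            chosen = rng.choice(n_genomes, size=size, replace=False)
            presence[rep] = {tips[k] for k in chosen}
            truth.lineage_node[fam] = ""
    return newick_str, presence


# ---------------------------------------------------------------------------
# full bundle


def simulate_bundle(
    out_dir: str, preset: str = "small", seed: int = 0, noise: float = 0.0
) -> SyntheticTruth:
    """Emit the full input bundle (FASTA, TSVs, Newick, truth JSON)."""
    from . import io as agio

    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    p = PRESETS[preset]
    os.makedirs(out_dir, exist_ok=True)
    genes, membership, truth = simulate_families(
        p["n_families"], p["genes_per_family"], p["mutation_rate"],
        p["intruder_rate"], seed=seed,
    )
    agio.write_genes(genes, os.path.join(out_dir, "genes.fasta"))
    with open(os.path.join(out_dir, "membership.tsv"), "w") as fh:
        for rep, members in membership.items():
            for m in members:
                fh.write(f"{rep}\t{m}\n")
    domain_hits, uniref, nr, profile_hits, clan_map = simulate_evidence(
        truth, noise=noise, seed=seed + 1
    )
    agio.write_hits(domain_hits, os.path.join(out_dir, "domains.tsv"), "domain")
    for name, table in (("uniref", uniref), ("nr", nr)):
        flat = [h for hits in table.values() for h in hits]
        agio.write_hits(flat, os.path.join(out_dir, f"{name}_hits.tsv"), "homolog")
    for category, hits in profile_hits.items():
        agio.write_hits(
            hits, os.path.join(out_dir, f"profile_{category}.tsv"), "profile"
        )
    with open(os.path.join(out_dir, "clans.tsv"), "w") as fh:
        for domain, clan in sorted(clan_map.items()):
            fh.write(f"{domain}\t{clan}\n")
    coverage, gene_counts, groups = simulate_ecology(
        truth, p["n_samples"], p["n_groups"], seed=seed + 2
    )
    with open(os.path.join(out_dir, "coverage.tsv"), "w") as fh:
        for gene, sample, value in coverage:
            fh.write(f"{gene}\t{sample}\t{value:.10g}\n")
    with open(os.path.join(out_dir, "gene_counts.tsv"), "w") as fh:
        for sample, count in sorted(gene_counts.items()):
            fh.write(f"{sample}\t{count:.6g}\n")
    newick_str, presence = simulate_tree_presence(
        truth, p["n_genomes"], seed=seed + 3
    )
    with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
        fh.write(newick_str + "\n")
    agio.write_presence(presence, os.path.join(out_dir, "presence.tsv"))
    truth.to_json(os.path.join(out_dir, "truth.json"))
    return truth
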