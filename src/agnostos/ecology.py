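"""Environmental characterization of gene clusters.

Abundance profiles, sample selection, accumulation curves, sample grouping,
quasiswap null models and Levins niche-breadth distribution calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .model import AbundanceMatrix, GeneCluster

logger = logging.getLogger(__name__)


@dataclass
class DistributionCall:
    gc_id: str
    observed_B: float
    call: str  # Narrow | Broad | Nonsignificant
    votes: List[str] = field(default_factory=list)


def select_samples(gene_counts: Mapping[str, float]) -> List[str]:
    """Retain samples whose gene count reaches the first quartile
    (linear-interpolation quantile)."""
    if len(gene_counts) < 4:
        raise ValueError("sample selection needs at least 4 samples")
    counts = np.array(list(gene_counts.values()), dtype=float)
    q1 = float(np.quantile(counts, 0.25))
    return [s for s, c in gene_counts.items() if c >= q1]


def cluster_abundance(
    coverage: pd.DataFrame,
    gene_lengths: Mapping[str, int],
    clusters: Sequence[GeneCluster],
) -> AbundanceMatrix:
    """Cluster-by-sample abundance matrix, total-sum-scaled per sample.

    Gene abundance is summed per-base coverage divided by gene length; a
    cluster's abundance is the sum over its members; each sample column is
    then normalized to proportions.
    """
    for gene, length in gene_lengths.items():
        if length <= 0:
            raise ValueError(f"gene {gene} has non-positive length")
    gene_to_gc: Dict[str, str] = {}
    for c in clusters:
        for m in c.members:
            gene_to_gc[m] = c.id
    df = coverage.copy()
    df = df[df["gene_id"].isin(gene_to_gc)]
    df["gc"] = df["gene_id"].map(gene_to_gc)
    lengths = df["gene_id"].map(gene_lengths)
    if lengths.isna().any():
        missing = df.loc[lengths.isna(), "gene_id"].iloc[0]
        raise ValueError(f"no length for gene {missing}")
    df["abundance"] = df["coverage"] / lengths
    matrix = (
        df.pivot_table(
            index="gc", columns="sample_id", values="abundance", aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(sorted(c.id for c in clusters), fill_value=0.0)
        .sort_index()
    )
    matrix.index.name = None
    matrix.columns.name = None
    return AbundanceMatrix(matrix).tss()


def accumulation_curve(
    presence: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    singleton_abundance: Optional[Mapping[str, float]] = None,
    singleton_cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Mean +/- sd of distinct clusters recovered vs number of samples.

    ``presence`` is a boolean/0-1 cluster-by-sample frame. Random sample
    orderings are drawn ``n_perm`` times. The optional singleton filter
    removes single-sample clusters whose abundance is below the supplied
    cutoff before the curve is computed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mat = presence.to_numpy(dtype=bool)
    gcs = list(presence.index)
    if singleton_cutoff is not None and singleton_abundance is not None:
        occupancy = mat.sum(axis=1)
        keep = [
            i for i, gc in enumerate(gcs)
            if not (
                occupancy[i] == 1
                and singleton_abundance.get(gc, np.inf) < singleton_cutoff
            )
        ]
        mat = mat[keep]
    n_samples = mat.shape[1]
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_perm, n_samples))
    for p in range(n_perm):
        order = rng.permutation(n_samples)
        seen = np.zeros(mat.shape[0], dtype=bool)
        for k, s in enumerate(order):
            seen |= mat[:, s]
            curves[p, k] = seen.sum()
    return pd.DataFrame(
        {
            "n_samples": np.arange(1, n_samples + 1),
            "mean_gcs": curves.mean(axis=0),
            "sd_gcs": curves.std(axis=0),
        }
    )


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    unique = np.unique(labels)
    if len(unique) < 2 or len(unique) >= n:
        return -1.0
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        a = dist[i, own].mean() if own.any() else 0.0
        b = min(
            dist[i, labels == other].mean()
            for other in unique if other != labels[i]
        )
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def group_samples(
    matrix: AbundanceMatrix, min_group_size: int = 3
) -> Dict[str, int]:
    """Group similar samples by cluster content.

    Bray-Curtis distances on TSS columns, average-linkage hierarchical
    clustering, a flat cut at the height maximizing the mean silhouette, and
    a final merge of groups smaller than ``min_group_size`` into their
    nearest group.
    """
    samples = matrix.sample_ids
    if len(samples) < 2:
        raise ValueError("group_samples needs at least 2 samples")
    cols = matrix.tss().to_numpy().T  # samples x clusters
    condensed = pdist(cols, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)
    if condensed.max() < 1e-12:
        return {s: 0 for s in samples}
    dist = squareform(condensed)
    link = linkage(condensed, method="average")
    heights = sorted(set(link[:, 2]))
    candidates = [
        (heights[i] + heights[i + 1]) / 2 for i in range(len(heights) - 1)
    ] + [heights[0] / 2]
    best_labels = np.zeros(len(samples), dtype=int)
    best_score = -np.inf
    for height in candidates:
        labels = fcluster(link, t=height, criterion="distance")
        score = _mean_silhouette(dist, labels)
        if score > best_score + 1e-12:
            best_score = score
            best_labels = labels
    if best_score <= -1.0:
        return {s: 0 for s in samples}
    labels = best_labels.copy()
    # merge undersized groups into the nearest (mean-distance) group
    while True:
        sizes = {g: int((labels == g).sum()) for g in np.unique(labels)}
        small = [g for g, n in sizes.items() if n < min_group_size]
        if not small or len(sizes) == 1:
            break
        g = min(small, key=lambda x: sizes[x])
        members = labels == g
        others = [o for o in sizes if o != g]
        nearest = min(
            others, key=lambda o: dist[np.ix_(members, labels == o)].mean()
        )
        labels[members] = nearest
    remap = {g: i for i, g in enumerate(sorted(set(labels)))}
    return {s: remap[g] for s, g in zip(samples, labels)}


# ---------------------------------------------------------------------------
# quasiswap null model


def _random_margin_fill(
    row_sums: np.ndarray, col_sums: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random non-negative integer matrix with the given margins
    (sequential multivariate-hypergeometric fill, r2dtable-style)."""
    remaining = col_sums.copy()
    out = np.zeros((len(row_sums), len(col_sums)), dtype=np.int64)
    for i, r in enumerate(row_sums):
        if remaining.sum() == 0:
            break
        draw = rng.multivariate_hypergeometric(remaining, int(r))
        out[i] = draw
        remaining = remaining - draw
    return out


def _quasiswap_moves(
    matrix: np.ndarray, n_moves: int, rng: np.random.Generator
) -> None:
    """In-place 2x2 diagonal swaps preserving both margin vectors."""
    n_rows, n_cols = matrix.shape
    if n_rows < 2 or n_cols < 2:
        return
    rows = rng.integers(0, n_rows, size=(n_moves, 2))
    cols = rng.integers(0, n_cols, size=(n_moves, 2))
    direction = rng.integers(0, 2, size=n_moves)
    for (i, j), (k, l), d in zip(rows, cols, direction):
        if i == j or k == l:
            continue
        a, b = matrix[i, k], matrix[i, l]
        c, e = matrix[j, k], matrix[j, l]
        if d == 0:
            if a > 0 and e > 0:
                matrix[i, k] -= 1; matrix[j, l] -= 1
                matrix[i, l] += 1; matrix[j, k] += 1
        else:
            if b > 0 and c > 0:
                matrix[i, l] -= 1; matrix[j, k] -= 1
                matrix[i, k] += 1; matrix[j, l] += 1


def quasiswap_null(
    matrix: np.ndarray, n_null: int = 100, seed: int = 0
) -> List[np.ndarray]:
    """Null count matrices preserving every row and column sum exactly.

    Each null starts from an independent random margin-preserving fill and
    is then shuffled with 2x2 quasiswap moves (at least 10x the matrix fill).
    Input must be a non-negative integer matrix.
    """
    arr = np.asarray(matrix)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("quasiswap_null requires an integer matrix")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("quasiswap_null requires non-negative counts")
    arr = arr.astype(np.int64)
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    fill = max(int((arr > 0).sum()), 1)
    n_moves = 10 * fill
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(n_null):
        null = _random_margin_fill(row_sums, col_sums, rng)
        _quasiswap_moves(null, n_moves, rng)
        assert (null.sum(axis=1) == row_sums).all()
        assert (null.sum(axis=0) == col_sums).all()
        nulls.append(null)
    return nulls


# ---------------------------------------------------------------------------
# niche breadth


def niche_breadth(p: Sequence[float]) -> float:
    """Levins niche breadth ``B = 1 / sum(p_i^2)`` on proportions of ``p``.

    B ranges from 1 (single-sample occupancy) to the number of samples
    (perfectly even spread) and is invariant to rescaling of ``p``.
    """
    arr = np.asarray(p, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("niche breadth undefined for an all-zero row")
    q = arr / total
    return float(1.0 / np.square(q).sum())


def classify_distribution(
    gc_id: str,
    observed_bs: Sequence[float],
    null_bs_per_dataset: Sequence[Sequence[float]],
) -> DistributionCall:
    """Consensus distribution call over random datasets.

    Per dataset: Narrow when the observed B falls below the 2.5% null
    quantile, Broad above the 97.5% quantile, otherwise Nonsignificant. The
    consensus is the plurality vote; ties resolve to Nonsignificant.
    """
    if not null_bs_per_dataset:
        raise ValueError("need at least one dataset of null values")
    votes = []
    for observed, nulls in zip(observed_bs, null_bs_per_dataset):
        nulls = np.asarray(nulls, dtype=float)
        lo, hi = np.quantile(nulls, [0.025, 0.975])
        if observed < lo:
            votes.append("Narrow")
        elif observed > hi:
            votes.append("Broad")
        else:
            votes.append("Nonsignificant")
    counts = {c: votes.count(c) for c in ("Narrow", "Broad", "Nonsignificant")}
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    call = winners[0] if len(winners) == 1 else "Nonsignificant"
    return DistributionCall(
        gc_id=gc_id,
        observed_B=float(np.mean(observed_bs)),
        call=call,
        votes=votes,
    )


def distribution_calls(
    matrix: AbundanceMatrix,
    groups: Mapping[str, int],
    n_datasets: int = 10,
    n_null: int = 100,
    seed: int = 0,
    min_mean_abundance: float = 1e-5,
    count_scale: int = 1_000_000,
) -> List[DistributionCall]:
    """Full distribution-classification pipeline.

    For each of ``n_datasets`` random datasets (one random sample per sample
    group) the observed niche breadth per cluster is compared with breadths
    from ``n_null`` quasiswap null matrices of the integer-rescaled
    abundance sub-matrix; calls are combined by majority vote. Clusters with
    mean relative abundance below ``min_mean_abundance`` are excluded.
    """
    tss = matrix.tss()
    keep = tss.data.mean(axis=1) >= min_mean_abundance
    data = tss.data.loc[keep]
    gcs = list(data.index)
    by_group: Dict[int, List[str]] = {}
    for sample, group in groups.items():
        by_group.setdefault(group, []).append(sample)
    rng = np.random.default_rng(seed)
    observed: Dict[str, List[float]] = {gc: [] for gc in gcs}
    nulls: Dict[str, List[List[float]]] = {gc: [] for gc in gcs}
    for d in range(n_datasets):
        chosen = [
            sorted(by_group[g])[rng.integers(0, len(by_group[g]))]
            for g in sorted(by_group)
        ]
        sub = data[chosen].to_numpy()
        counts = np.round(sub * count_scale).astype(np.int64)
        null_mats = quasiswap_null(
            counts, n_null=n_null, seed=int(rng.integers(0, 2**31 - 1))
        )
        for i, gc in enumerate(gcs):
            row = counts[i]
            if row.sum() == 0:
                continue
            observed[gc].append(niche_breadth(row))
            nulls[gc].append(
                [
                    niche_breadth(nm[i]) if nm[i].sum() > 0 else 1.0
                    for nm in null_mats
                ]
            )
    calls = []
    for gc in gcs:
        if not observed[gc]:
            continue
        calls.append(classify_distribution(gc, observed[gc], nulls[gc]))
    return calls
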