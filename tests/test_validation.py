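import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agnostos import validation as val
from agnostos.model import Gene, GeneCluster


# ---------------------------------------------------------------------------
# broken-stick threshold


def test_broken_stick_three_values():
    # shares (0.70, 0.20, 0.10); E = (0.6111, 0.2778, 0.1111): only rank 1
    # exceeds its expectation, so the threshold is the rank-1 value
    assert val.broken_stick_threshold([0.70, 0.20, 0.10]) == pytest.approx(0.70)


def test_broken_stick_two_values():
    # E_1 = (1 + 1/2)/2 = 0.75 < 0.9
    assert val.broken_stick_threshold([0.9, 0.1]) == pytest.approx(0.9)


def test_broken_stick_exact_expectations_give_zero():
    # shares equal to E_k exactly: nothing strictly exceeds
    n = 3
    inv = 1.0 / np.arange(1, n + 1)
    shares = np.cumsum(inv[::-1])[::-1] / n
    assert val.broken_stick_threshold(shares.tolist()) == 0.0


def test_broken_stick_all_zero_errors():
    with pytest.raises(ValueError):
        val.broken_stick_threshold([0.0, 0.0])


def test_broken_stick_resample_agrees_within_one_rank():
    values = [0.5, 0.3, 0.1, 0.05, 0.03, 0.02]
    closed = val.broken_stick_threshold(values)
    resampled = val.broken_stick_threshold(
        values, method="resample", n_iter=200, seed=3
    )
    ranked = sorted(values, reverse=True)
    i = ranked.index(closed)
    neighborhood = ranked[max(0, i - 1) : i + 2]
    assert min(neighborhood) <= resampled <= max(neighborhood)


@given(st.lists(st.floats(min_value=0.01, max_value=100, allow_nan=False),
                min_size=2, max_size=30))
@settings(max_examples=50, deadline=None)
def test_broken_stick_threshold_is_zero_or_an_input(values):
    threshold = val.broken_stick_threshold(values)
    assert threshold == 0.0 or any(
        np.isclose(threshold, v) for v in values
    )


# ---------------------------------------------------------------------------
# size flagging


def test_flag_small_clusters_boundary():
    mk = lambda n, i: GeneCluster(
        id=f"c{i}", representative=f"c{i}",
        members={f"c{i}"} | {f"c{i}_g{j}" for j in range(n - 1)},
    )
    clusters = val.flag_small_clusters([mk(9, 0), mk(10, 1)], min_size=10)
    assert clusters[0].category == "FLAGGED"
    assert clusters[1].category != "FLAGGED"


def test_flag_small_clusters_min_size_one_flags_nothing():
    c = GeneCluster(id="c", representative="c", members={"c"})
    assert val.flag_small_clusters([c], min_size=1)[0].category != "FLAGGED"


# ---------------------------------------------------------------------------
# SSN build / trim / representative


def _genes(seqs):
    return [Gene(id=k, sequence=v) for k, v in seqs.items()]


def test_build_ssn_identical_sequences():
    genes = _genes({"a": "MKVLA", "b": "MKVLA", "c": "MKVLA"})
    graph = val.build_ssn(genes)
    assert graph.number_of_edges() == 3
    weights = {d["weight"] for _, _, d in graph.edges(data=True)}
    assert len(weights) == 1
    assert max(weights) == pytest.approx(1.0)


def test_build_ssn_two_members_single_edge():
    graph = val.build_ssn(_genes({"a": "MKVLA", "b": "MKVLT"}))
    assert graph.number_of_edges() == 1


def test_build_ssn_scorer_symmetry(rng):
    amino = "ACDEFGHIKLMNPQRSTVWY"
    scorer = val.make_default_scorer()
    for _ in range(5):
        a = "".join(rng.choice(list(amino), size=30))
        b = "".join(rng.choice(list(amino), size=35))
        assert scorer(a, b) == pytest.approx(scorer(b, a))


def test_trim_ssn_triangle():
    graph = nx.Graph()
    graph.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 3.0)])
    trimmed = val.trim_ssn(graph)
    assert not trimmed.has_edge("a", "b")
    assert trimmed.has_edge("b", "c") and trimmed.has_edge("a", "c")


def test_trim_ssn_tree_unchanged():
    graph = nx.Graph()
    graph.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 2.0)])
    trimmed = val.trim_ssn(graph)
    assert set(trimmed.edges) == set(graph.edges)


def test_trim_ssn_disconnected_errors():
    graph = nx.Graph()
    graph.add_weighted_edges_from([("a", "b", 1.0), ("c", "d", 1.0)])
    with pytest.raises(ValueError):
        val.trim_ssn(graph)


def exhaustive_trim_threshold(graph):
    """Oracle: largest edge-weight threshold keeping the graph connected."""
    weights = sorted({d["weight"] for _, _, d in graph.edges(data=True)})
    best = None
    for t in weights:
        sub = nx.Graph()
        sub.add_nodes_from(graph.nodes)
        sub.add_edges_from(
            (u, v) for u, v, d in graph.edges(data=True) if d["weight"] >= t
        )
        if nx.is_connected(sub):
            best = t
    return best


def random_connected_graph(rng, n_nodes):
    while True:
        graph = nx.gnp_random_graph(n_nodes, 0.5, seed=int(rng.integers(2**31)))
        if nx.is_connected(graph) and graph.number_of_edges() > 0:
            break
    for u, v in graph.edges:
        graph[u][v]["weight"] = float(rng.integers(1, 20))
    return graph


def test_trim_threshold_matches_exhaustive_oracle(rng):
    for _ in range(40):
        n = int(rng.integers(3, 9))
        graph = random_connected_graph(rng, n)
        trimmed = val.trim_ssn(graph)
        t_star = min(d["weight"] for _, _, d in trimmed.edges(data=True))
        assert t_star == exhaustive_trim_threshold(graph)
        assert nx.is_connected(trimmed)
        assert set(trimmed.nodes) == set(graph.nodes)


def test_select_representative_path_center():
    graph = nx.Graph()
    graph.add_weighted_edges_from(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "e", 1.0)]
    )
    assert val.select_representative(graph) == "c"


def test_select_representative_single_node():
    graph = nx.Graph()
    graph.add_node("only")
    assert val.select_representative(graph) == "only"


def test_select_representative_clique_tie_break():
    graph = nx.Graph()
    graph.add_weighted_edges_from(
        [("b", "a", 1.0), ("a", "c", 1.0), ("b", "c", 1.0)]
    )
    assert val.select_representative(graph) == "a"


def test_select_representative_permutation_invariant(rng):
    graph = random_connected_graph(rng, 6)
    rep = val.select_representative(graph)
    shuffled = nx.Graph()
    edges = list(graph.edges(data=True))
    rng.shuffle(edges)
    shuffled.add_nodes_from(sorted(graph.nodes, reverse=True))
    shuffled.add_edges_from(edges)
    assert val.select_representative(shuffled) == rep


# ---------------------------------------------------------------------------
# MSA outliers


def test_detect_msa_outliers_flags_random_sequence(rng):
    amino = "ACDEFGHIKLMNPQRSTVWY"
    root = "".join(rng.choice(list(amino), size=60))
    aln = {}
    for i in range(10):
        seq = list(root)
        for j in rng.choice(60, size=2, replace=False):
            seq[j] = amino[rng.integers(20)]
        aln[f"m{i}"] = "".join(seq)
    aln["intruder"] = "".join(rng.choice(list(amino), size=60))
    outliers = val.detect_msa_outliers(aln, representative="m0")
    assert outliers == {"intruder"}


def test_detect_msa_outliers_all_identical():
    aln = {f"m{i}": "MKVLA" for i in range(5)}
    assert val.detect_msa_outliers(aln, "m0") == set()


def test_detect_msa_outliers_small_alignment_degenerate():
    aln = {"a": "MKVLA", "b": "WWWWW"}
    assert val.detect_msa_outliers(aln, "a") == set()


def test_detect_msa_outliers_missing_representative():
    with pytest.raises(ValueError):
        val.detect_msa_outliers({"a": "MK"}, "zz")


# ---------------------------------------------------------------------------
# shadow genes


def _gene(gid, start, end, strand):
    return Gene(id=gid, sequence="M", contig="ctg", start=start, end=end,
                strand=strand)


def test_shadow_opposite_strand_overlap():
    a = _gene("short", 100, 399, "+")   # 300 bp
    b = _gene("long", 330, 1229, "-")   # 900 bp, overlap 70 bp
    assert val.flag_shadow_genes([a, b]) == {"short"}


def test_shadow_disjoint_genes():
    a = _gene("a", 1, 300, "+")
    b = _gene("b", 400, 700, "-")
    assert val.flag_shadow_genes([a, b]) == set()


def test_shadow_small_same_strand_overlap():
    # 10 bp overlap on 300 bp genes: below both thresholds
    a = _gene("a", 1, 300, "+")
    b = _gene("b", 291, 590, "+")
    assert val.flag_shadow_genes([a, b]) == set()


def test_shadow_same_strand_majority_overlap():
    a = _gene("a", 1, 300, "+")
    b = _gene("b", 101, 250, "+")  # 150 bp gene fully inside a
    assert val.flag_shadow_genes([a, b]) == {"b"}


def test_shadow_tie_breaks_on_start():
    a = _gene("a", 1, 300, "+")
    b = _gene("b", 50, 349, "-")  # same length, overlap 251
    assert val.flag_shadow_genes([a, b]) == {"b"}


# ---------------------------------------------------------------------------
# validate_clusters


def _identical_cluster(cid, n, seq="MKVLAWYTTE"):
    genes = {f"{cid}_g{i}": Gene(id=f"{cid}_g{i}", sequence=seq)
             for i in range(n)}
    cluster = GeneCluster(
        id=f"{cid}_g0", representative=f"{cid}_g0", members=set(genes)
    )
    return cluster, genes


def test_validate_shadow_fraction_discards():
    cluster, genes = _identical_cluster("c", 10)
    for i, g in enumerate(genes.values()):
        if i < 4:  # 40% shadow
            g.flags.add("shadow")
    reports, clusters = val.validate_clusters([cluster], genes)
    assert reports[0].decision == "discard"
    assert clusters[0].category == "DISCARDED"


def test_validate_clean_cluster_kept_unchanged():
    cluster, genes = _identical_cluster("c", 10)
    before = set(cluster.members)
    reports, clusters = val.validate_clusters([cluster], genes)
    assert reports[0].decision == "keep"
    assert clusters[0].members == before


def test_validate_removes_single_outlier(rng):
    amino = "ACDEFGHIKLMNPQRSTVWY"
    root = "".join(rng.choice(list(amino), size=50))
    genes = {}
    for i in range(19):
        seq = list(root)
        for j in rng.choice(50, size=2, replace=False):
            seq[j] = amino[rng.integers(20)]
        genes[f"g{i}"] = Gene(id=f"g{i}", sequence="".join(seq))
    genes["bad"] = Gene(id="bad", sequence="".join(rng.choice(list(amino), size=50)))
    cluster = GeneCluster(id="g0", representative="g0", members=set(genes))
    # a second clean cluster so the outlier-fraction distribution has support
    other, other_genes = _identical_cluster("o", 10)
    genes.update(other_genes)
    reports, clusters = val.validate_clusters([cluster, other], genes)
    by_id = {r.cluster_id: r for r in reports}
    assert by_id["g0"].outlier_genes == {"bad"}
    target = next(c for c in clusters if c.id == "g0")
    if by_id["g0"].decision == "keep":
        assert "bad" not in target.members
        assert target.size == 19
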