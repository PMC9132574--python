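import pytest
from hypothesis import given, settings, strategies as st

from agnostos import classification as cls
from agnostos.functional import DomainArchitecture
from agnostos.model import GeneCluster, HomologHit, RefinementHit


def da(*domains):
    return DomainArchitecture(tokens=tuple((d, "", "none") for d in domains))


def hh(evalue=1e-40, annotation="kinase", duf=False, bitscore=100.0):
    return HomologHit(
        query="q", target="t", evalue=evalue, bitscore=bitscore,
        target_annotation=annotation, target_is_duf=duf,
    )


# ---------------------------------------------------------------------------
# consensus architecture


def test_consensus_da_majority_path():
    gene_das = {"g1": da("A", "B", "C"), "g2": da("A", "B", "C"), "g3": da("A", "B")}
    completeness = {"g1": True, "g2": True, "g3": False}
    assert cls.consensus_da(gene_das, completeness) == ("A", "B", "C")


def test_consensus_da_collapses_repeats():
    assert cls.consensus_da({"g1": da("A", "A", "B")}, {"g1": True}) == ("A", "B")


def test_consensus_da_single_gene():
    assert cls.consensus_da({"g1": da("X", "Y")}, {"g1": False}) == ("X", "Y")


def test_consensus_da_completeness_breaks_weight_ties():
    # equal path weights; complete-gene support decides
    gene_das = {"g1": da("A"), "g2": da("B"), "g3": da("A"), "g4": da("B")}
    completeness = {"g1": False, "g2": True, "g3": False, "g4": False}
    # path A: weight 1.0; path B: weight 1.5 -> B wins outright
    assert cls.consensus_da(gene_das, completeness) == ("B",)


def test_consensus_da_no_genes_errors():
    with pytest.raises(ValueError):
        cls.consensus_da({}, {})


# ---------------------------------------------------------------------------
# annotated-route classification


def test_classify_annotated_all_duf_is_gu():
    assert cls.classify_annotated(("DUF123", "DUF456")) == "GU"


def test_classify_annotated_mixed_is_k():
    assert cls.classify_annotated(("DUF123", "PF00069")) == "K"


def test_classify_annotated_known_is_k():
    assert cls.classify_annotated(("PF00069",)) == "K"


def test_classify_annotated_empty_errors():
    with pytest.raises(ValueError):
        cls.classify_annotated(())


def test_duf_predicate_accession_list():
    pred = cls.make_duf_predicate(["PF09999"])
    assert pred("PF09999") and pred("DUF42") and not pred("PF00001")


# ---------------------------------------------------------------------------
# homolog filtering


def test_filter_homologs_sixty_percent_rule():
    hits = [hh(1e-100), hh(1e-70), hh(1e-30)]
    kept = cls.filter_homologs(hits)
    assert hits[0] in kept and hits[1] in kept and hits[2] not in kept


def test_filter_homologs_single_hit():
    hits = [hh(1e-7)]
    assert cls.filter_homologs(hits) == hits


def test_filter_homologs_weak_best():
    hits = [hh(1e-5), hh(1e-3)]  # cutoff |log| >= 3
    assert len(cls.filter_homologs(hits)) == 2


def test_filter_homologs_always_keeps_best():
    hits = [hh(1e-50), hh(1e-20)]
    assert hits[0] in cls.filter_homologs(hits, log_fraction=0.99)


@given(st.lists(st.floats(min_value=1e-150, max_value=1e-2), min_size=1,
                max_size=15))
@settings(max_examples=50, deadline=None)
def test_filter_homologs_monotone_in_factor(evalues):
    hits = [hh(e) for e in evalues]
    sizes = [
        len(cls.filter_homologs(hits, log_fraction=f))
        for f in (0.2, 0.4, 0.6, 0.8, 1.0)
    ]
    assert sizes == sorted(sizes, reverse=True)
    for f in (0.2, 0.6, 1.0):
        kept = cls.filter_homologs(hits, log_fraction=f)
        assert min(hits, key=lambda h: h.evalue) in kept


# ---------------------------------------------------------------------------
# voting


def test_vote_majority_unknown():
    hits = [hh(annotation="hypothetical protein")] * 3 + [hh(annotation="kinase")]
    assert cls.vote_category(hits) == "unknown"


def test_vote_tie_goes_to_known():
    hits = [hh(annotation="hypothetical protein")] * 2 + [hh(annotation="kinase")] * 2
    assert cls.vote_category(hits) == "known"


def test_vote_all_functional():
    assert cls.vote_category([hh(), hh(annotation="transporter")]) == "known"


def test_vote_duf_flag_counts_as_unknown():
    hits = [hh(annotation="some domain", duf=True)] * 3 + [hh()]
    assert cls.vote_category(hits) == "unknown"


# ---------------------------------------------------------------------------
# unannotated-route classification


def test_classify_unannotated_no_hits_is_eu():
    assert cls.classify_unannotated([], []) == "EU"


def test_classify_unannotated_uniref_unknown_is_gu():
    hits = [hh(annotation="uncharacterized protein")] * 3
    assert cls.classify_unannotated(hits, []) == "GU"


def test_classify_unannotated_nr_fallback_known_is_kwp():
    hits = [hh(annotation="DNA polymerase")] * 3
    assert cls.classify_unannotated([], hits) == "KWP"


# ---------------------------------------------------------------------------
# refinement


def rh(prob, cov=0.8, target="PF00069", annotation="kinase", duf=False,
       evalue=1e-10, span=(1, 100)):
    return RefinementHit(
        query_gc="gc", target=target, probability=prob, target_cov=cov,
        target_annotation=annotation, target_is_duf=duf, evalue=evalue,
        q_start=span[0], q_end=span[1],
    )


def test_refine_eu_known_hit_to_kwp():
    assert cls.refine_eu([rh(0.92, annotation="ABC transporter")]) == "KWP"


def test_refine_eu_below_probability_stays_eu():
    assert cls.refine_eu([rh(0.85)]) == "EU"


def test_refine_eu_unknown_hits_to_gu():
    hits = [rh(0.95, annotation="hypothetical protein")] * 3
    assert cls.refine_eu(hits) == "GU"


def test_refine_kwp_known_pfam_to_k():
    assert cls.refine_kwp([rh(0.95, cov=0.7)]) == "K"


def test_refine_kwp_low_coverage_unchanged():
    assert cls.refine_kwp([rh(0.95, cov=0.5)]) == "KWP"


def test_refine_kwp_duf_only_to_gu():
    assert cls.refine_kwp([rh(0.93, cov=0.8, target="DUF1234")]) == "GU"


def test_refine_kwp_overlap_resolution_prefers_smaller_evalue():
    # overlapping DUF (better e-value) masks the known-Pfam hit
    duf_hit = rh(0.95, cov=0.8, target="DUF9", evalue=1e-50, span=(1, 100))
    pf_hit = rh(0.95, cov=0.8, target="PF00001", evalue=1e-10, span=(10, 90))
    assert cls.refine_kwp([duf_hit, pf_hit]) == "GU"


def test_refinement_monotone_toward_known():
    # EU can only move to {EU, GU, KWP}; KWP only to {KWP, GU, K}
    for hits in ([], [rh(0.5)], [rh(0.99)], [rh(0.99, duf=True, annotation="x")]):
        assert cls.refine_eu(hits) in ("EU", "GU", "KWP")
        assert cls.refine_kwp(hits) in ("KWP", "GU", "K")


# ---------------------------------------------------------------------------
# high-quality selection


def _cluster(cid, members, category="K"):
    c = GeneCluster(id=members[0], representative=members[0],
                    members=set(members), category=category)
    c.id = cid
    return c


def test_hq_requires_complete_representative():
    c = _cluster("c1", ["a", "b", "c"])
    completeness = {"a": False, "b": True, "c": True}
    flags = cls.select_high_quality([c], completeness)
    assert flags["c1"] is False


def test_hq_above_one_third():
    c1 = _cluster("c1", ["a", "b"])
    c2 = _cluster("c2", ["d", "e", "f", "g", "h"])
    completeness = {"a": True, "b": False, "d": True,
                    "e": False, "f": False, "g": False, "h": False}
    flags = cls.select_high_quality([c1, c2], completeness)
    assert flags["c1"] is True    # rep complete, 50% > 1/3
    assert flags["c2"] is False   # 20% < 1/3


# ---------------------------------------------------------------------------
# non-redundant architectures


def test_collapse_fragment_into_parent():
    das = [(("A", "B"), 0.6), (("A", "B", "C"), 0.9)]
    assert cls.collapse_fragmented_das(das) == [("A", "B", "C")]


def test_fragment_with_enough_complete_genes_kept():
    das = [(("A", "B"), 0.8), (("A", "B", "C"), 0.9)]
    out = cls.collapse_fragmented_das(das)
    assert ("A", "B") in out and ("A", "B", "C") in out


def test_identical_das_deduplicated():
    das = [(("A", "B"), 0.5), (("A", "B"), 0.9)]
    assert cls.collapse_fragmented_das(das) == [("A", "B")]


def test_divergent_pairs_not_collapsed():
    # cosine distance of completely different token strings is 1 >= 0.9
    das = [(("XXX",), 0.1), (("YYY", "ZZZ"), 0.9)]
    assert len(cls.collapse_fragmented_das(das)) == 2


def test_qgram_cosine_distance_bounds():
    assert cls.qgram_cosine_distance("ABC", "ABC") == pytest.approx(0.0)
    assert cls.qgram_cosine_distance("AAAA", "BBBB") == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# partition property


def test_categories_partition_validated_clusters(small_truth_bundle):
    from agnostos import functional as fn
    from tests.conftest import clusters_from_membership

    genes, membership, truth, evidence = small_truth_bundle
    domain_hits, uniref, nr, _, _ = evidence
    clusters = clusters_from_membership(membership)
    gene_das = fn.architectures_by_gene(domain_hits)
    decisions = cls.classify_clusters(
        clusters, gene_das, truth.gene_complete, uniref, nr
    )
    assert len(decisions) == len(clusters)
    assert {d.cluster_id for d in decisions} == {c.id for c in clusters}
    assert all(d.category in ("K", "KWP", "GU", "EU") for d in decisions)


def test_category_recovery_zero_noise(small_truth_bundle):
    from agnostos import functional as fn
    from tests.conftest import clusters_from_membership

    genes, membership, truth, evidence = small_truth_bundle
    domain_hits, uniref, nr, _, _ = evidence
    clusters = clusters_from_membership(membership)
    gene_das = fn.architectures_by_gene(domain_hits)
    decisions = cls.classify_clusters(
        clusters, gene_das, truth.gene_complete, uniref, nr
    )
    rep2fam = {m[0]: f for f, m in truth.family_genes.items()}
    assert all(
        d.category == truth.family_category[rep2fam[d.cluster_id]]
        for d in decisions
    )
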