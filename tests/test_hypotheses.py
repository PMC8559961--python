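"""Six-hypothesis classification, CYP clustering, locus filtering and
consolidation on constructed records."""

import pytest

from congenomics.annotation import Gene
from congenomics.hypotheses import (
    CandidateGene,
    CandidateSet,
    Thresholds,
    classify_candidates,
    consolidate,
    detect_cyp_clusters,
    filter_by_loci,
)
from congenomics.integration import JoinedRecord, LayerResult
from congenomics.locus import LocusInterval
from congenomics.variants import EffectClass, VariantSite

COMPS = ("SP/ROCK", "CKR/ROCK")


def joined(gene_id, gene_class="CYP", transcript=("up", "up"), protein=("up", "up"),
           chrom="1", start=100, end=200, accession=None):
    rec = JoinedRecord(gene_id=gene_id, accession=accession, gene_class=gene_class,
                       chrom=chrom, start=start, end=end)
    for comp, call in zip(COMPS, transcript or ()):
        if call is not None:
            rec.transcript[comp] = LayerResult(1.5 if call == "up" else -1.5 if call == "down" else 0.1, call)
    for comp, call in zip(COMPS, protein or ()):
        if call is not None:
            rec.protein[comp] = LayerResult(1.0 if call == "up" else -1.0 if call == "down" else 0.0, call)
    return rec


def resistance_snp(gene_id, category="non_synonymous", chrom="1", pos=150):
    return VariantSite(chrom, pos, "A", "G", 60.0,
                       {"ROCK": "hom_ref", "SP": "hom_alt", "CKR": "hom_alt"},
                       effect=EffectClass(category, gene_id))


class TestClassification:
    def test_dual_layer_up_cyp_is_h2_h3(self):
        sets = classify_candidates([joined("c1")], [], {})
        assert sets["H2"].gene_ids == ["c1"]
        assert sets["H3"].gene_ids == ["c1"]
        assert sets["H6"].gene_ids == []

    def test_protein_only_up_cyp_is_h6(self):
        # the "transcript up in SP only" signature: protein up in both strains
        rec = joined("c2", transcript=("up", "ns"), protein=("up", "up"))
        sets = classify_candidates([rec], [], {})
        assert sets["H6"].gene_ids == ["c2"]
        assert sets["H2"].gene_ids == []

    def test_up_in_one_strain_only_matches_nothing(self):
        rec = joined("c3", transcript=("up", "ns"), protein=("up", "ns"))
        sets = classify_candidates([rec], [], {})
        assert all(not s.genes for s in sets.values())

    def test_h6_requires_transcript_quantified(self):
        rec = joined("c4", transcript=None, protein=("up", "up"))
        sets = classify_candidates([rec], [], {})
        assert sets["H6"].gene_ids == []

    def test_accession_only_protein_cyp_reported_separately(self):
        rec = joined(None, transcript=None, protein=("up", "up"), accession="EAT1")
        sets = classify_candidates([rec], [], {})
        assert sets["H6"].accession_only == ["EAT1"]
        assert sets["H6"].gene_ids == []

    def test_nonsyn_snp_routes_cyp_to_h1_and_switch_to_h4(self):
        recs = [joined("cyp1", transcript=("ns", "ns"), protein=("ns", "ns")),
                joined("tf1", gene_class="TF", transcript=("ns", "ns"), protein=None)]
        snps = [resistance_snp("cyp1"), resistance_snp("tf1")]
        sets = classify_candidates(recs, snps, {})
        assert sets["H1"].gene_ids == ["cyp1"]
        assert sets["H1"].genes[0].notes == "no_expression_change"
        assert sets["H4"].gene_ids == ["tf1"]

    def test_synonymous_snp_does_not_qualify(self):
        recs = [joined("cyp1", transcript=("ns", "ns"), protein=("ns", "ns"))]
        sets = classify_candidates(recs, [resistance_snp("cyp1", "synonymous")], {})
        assert sets["H1"].gene_ids == []

    def test_switch_altered_in_both_directions_is_h5(self):
        up = joined("tfU", gene_class="TF", transcript=("up", "up"), protein=None)
        down = joined("lncD", gene_class="lncRNA", transcript=("down", "down"), protein=None)
        mixed = joined("tfM", gene_class="TF", transcript=("up", "down"), protein=None)
        sets = classify_candidates([up, down, mixed], [], {})
        assert sets["H5"].gene_ids == ["lncD", "tfU"] or set(sets["H5"].gene_ids) == {"tfU", "lncD"}
        assert "tfM" not in sets["H5"].gene_ids

    def test_snp_gene_absent_from_joined_uses_catalog(self):
        catalog = {"tf9": Gene("tf9", "1", 10, 500, "+", "TF")}
        sets = classify_candidates([], [resistance_snp("tf9")], catalog)
        assert sets["H4"].gene_ids == ["tf9"]

    def test_order_invariance(self):
        recs = [joined(f"c{i}") for i in range(5)] + [
            joined(f"t{i}", gene_class="TF", transcript=("up", "up"), protein=None)
            for i in range(5)
        ]
        fwd = classify_candidates(recs, [], {})
        rev = classify_candidates(recs[::-1], [], {})
        for h in fwd:
            assert sorted(fwd[h].gene_ids) == sorted(rev[h].gene_ids)

    def test_h23_and_h6_disjoint(self):
        recs = [joined("a"), joined("b", transcript=("ns", "ns"), protein=("up", "up"))]
        sets = classify_candidates(recs, [], {})
        assert not set(sets["H2"].gene_ids) & set(sets["H6"].gene_ids)


def cand(gene_id, chrom="1", start=0, end=1000, gene_class="CYP"):
    return CandidateGene(gene_id, gene_class, chrom, start, end)


class TestClusters:
    def test_chain_within_gap_forms_one_cluster(self):
        genes = [cand("a", start=0, end=1000), cand("b", start=50_000, end=51_000),
                 cand("c", start=120_000, end=121_000)]
        assert detect_cyp_clusters(genes, max_gap=100_000) == [["a", "b", "c"]]

    def test_matches_bruteforce_linkage_on_random_layout(self):
        import numpy as np

        rng = np.random.default_rng(0)
        genes = []
        for i, s in enumerate(sorted(rng.integers(0, 5_000_000, 40))):
            genes.append(cand(f"g{i}", start=int(s), end=int(s) + 1000))
        got = detect_cyp_clusters(genes, max_gap=100_000)
        # brute-force single linkage
        groups, current = [], [genes[0]]
        for g in genes[1:]:
            if g.start - current[-1].end <= 100_000:
                current.append(g)
            else:
                groups.append(current)
                current = [g]
        groups.append(current)
        expected = [[g.gene_id for g in grp] for grp in groups if len(grp) >= 2]
        assert got == expected

    def test_different_chromosomes_never_cluster(self):
        genes = [cand("a", chrom="1"), cand("b", chrom="2")]
        assert detect_cyp_clusters(genes, max_gap=10**9) == []


LOCI = [LocusInterval("1", 40_000_000, 250_000_000, 0, 0)]


class TestLocusFilter:
    def test_gene_inside_locus_passes(self):
        sets = {"H5": CandidateSet("H5", [cand("g", start=100_000_000, end=100_030_000,
                                               gene_class="TF")])}
        out = filter_by_loci(sets, LOCI, placed_chromosomes={"1", "2", "3"})
        assert out["H5"].genes[0].filter_status == "pass"

    def test_gene_on_locus_free_chromosome_fails(self):
        sets = {"H5": CandidateSet("H5", [cand("g", chrom="2", start=100_000_000,
                                               end=100_030_000, gene_class="TF")])}
        out = filter_by_loci(sets, LOCI, placed_chromosomes={"1", "2", "3"})
        assert out["H5"].genes[0].filter_status == "fail"

    def test_h3_and_h6_exempt(self):
        sets = {
            "H3": CandidateSet("H3", [cand("a", chrom="2")]),
            "H6": CandidateSet("H6", [cand("b", chrom="2")]),
        }
        out = filter_by_loci(sets, LOCI, placed_chromosomes={"1", "2", "3"})
        assert out["H3"].genes[0].filter_status == "exempt"
        assert out["H6"].genes[0].filter_status == "exempt"

    def test_unplaced_scaffold_flagged_not_dropped(self):
        sets = {"H4": CandidateSet("H4", [cand("g", chrom="NIGP0101", gene_class="TF")])}
        out = filter_by_loci(sets, LOCI, placed_chromosomes={"1", "2", "3"})
        assert out["H4"].genes[0].filter_status == "unfilterable"
        assert out["H4"].genes[0] in out["H4"].surviving()

    def test_empty_locus_list_keeps_only_exempt_and_unplaced(self):
        sets = {
            "H3": CandidateSet("H3", [cand("a")]),
            "H5": CandidateSet("H5", [cand("b", gene_class="TF"),
                                      cand("c", chrom="NIGP1", gene_class="TF")]),
        }
        out = filter_by_loci(sets, [], placed_chromosomes={"1"})
        survivors = {g.gene_id for s in out.values() for g in s.surviving()}
        assert survivors == {"a", "c"}

    def test_missing_coordinates_on_placed_gene_error(self):
        sets = {"H5": CandidateSet("H5", [CandidateGene("g", "TF", "1", None, None)])}
        with pytest.raises(ValueError, match="coordinates"):
            filter_by_loci(sets, LOCI, placed_chromosomes={"1"})

    def test_never_adds_genes(self):
        sets = {"H5": CandidateSet("H5", [cand("a", gene_class="TF"),
                                          cand("b", chrom="2", gene_class="TF")])}
        out = filter_by_loci(sets, LOCI, placed_chromosomes={"1", "2"})
        assert {g.gene_id for g in out["H5"].genes} == {"a", "b"}
        post = consolidate(out, "post_filter")
        pre = consolidate(sets, "pre_filter")
        assert set(post.union_ids) <= set(pre.union_ids)


class TestConsolidate:
    def _sets(self):
        return {
            "H4": CandidateSet("H4", [cand("a", gene_class="TF"), cand("b", gene_class="TF")]),
            "H5": CandidateSet("H5", [cand("b", gene_class="TF"), cand("c", gene_class="TF")]),
            "H6": CandidateSet("H6", [cand("d")]),
        }

    def test_disjoint_union(self):
        sets = {"H4": CandidateSet("H4", [cand("a"), cand("b")]),
                "H5": CandidateSet("H5", [cand("c")])}
        assert consolidate(sets).union_size == 3

    def test_shared_members_deduplicated(self):
        res = consolidate(self._sets())
        assert res.union_size == 4  # a, b, c, d
        assert res.switch_union_size == 3  # a, b, c
        assert res.per_hypothesis["H4"] == 2 and res.per_hypothesis["H5"] == 2

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError):
            consolidate(self._sets(), "mid_filter")


class TestThresholds:
    def test_defaults_are_study_values(self):
        t = Thresholds()
        assert (t.transcript_lfc, t.transcript_fdr, t.protein_p) == (1.0, 0.01, 0.05)
        assert t.window_size == 10_000_000 and t.locus_seed_count == 100

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="protein_p"):
            Thresholds(protein_p=0)
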