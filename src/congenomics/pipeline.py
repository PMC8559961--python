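"""One-call orchestration of the full analysis over a dataset.

Chains the stages in the order a study would run them: variant quality
filtering -> resistance-pattern selection -> effect annotation -> 10 Mb
window scan and locus calling; CPM filter -> TMM -> NB exact test per
strain comparison; razor -> rollup -> total-amount normalisation ->
protein t-tests; layer join; hypothesis classification, CYP cluster
detection, locus filtering and consolidation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import diffexpr, integration, locus, proteomics, variants
from .hypotheses import (
    CandidateSet,
    Consolidation,
    Thresholds,
    classify_candidates,
    consolidate,
    detect_cyp_clusters,
    filter_by_loci,
)
from .simulate import COMPARISONS, SyntheticDataset


@dataclass
class AnalysisResult:
    resistance_snps: list[variants.VariantSite]
    window_counts: list[locus.WindowCounts]
    loci: list[locus.LocusInterval]
    de: dict[str, list[diffexpr.DERecord]]
    proteins: list[proteomics.ProteinQuantRecord]
    joined: list[integration.JoinedRecord]
    hypothesis_sets: dict[str, CandidateSet]
    filtered_sets: dict[str, CandidateSet]
    cyp_clusters: list[list[str]] = field(default_factory=list)
    consolidation_pre: Consolidation | None = None
    consolidation_post: Consolidation | None = None


def analyze(
    dataset: SyntheticDataset,
    thresholds: Thresholds | None = None,
    comparisons: tuple[str, str] = COMPARISONS,
) -> AnalysisResult:
    thresholds = thresholds or Thresholds()
    catalog = {g.gene_id: g for g in dataset.genes}

    # --- variants -> loci
    kept = variants.filter_quality(dataset.variants)
    res_snps = variants.select_resistance_snps(kept)
    variants.annotate_sites(res_snps, dataset.genes, dataset.genome)
    wc = locus.window_counts(res_snps, dataset.chrom_lengths, thresholds.window_size)
    loci = locus.call_loci(wc, thresholds.locus_seed_count)

    # --- transcripts
    de: dict[str, list[diffexpr.DERecord]] = {}
    for comp in comparisons:
        a, b = comp.split("/")
        filtered = diffexpr.filter_genes(dataset.counts, strains=[a, b])
        de[comp] = diffexpr.test_de(
            filtered, a, b,
            lfc_threshold=thresholds.transcript_lfc,
            fdr_threshold=thresholds.transcript_fdr,
        )

    # --- proteins
    prot = proteomics.normalize_total(proteomics.rollup(proteomics.assign_razor(dataset.psms)))
    for comp in comparisons:
        a, b = comp.split("/")
        proteomics.test_protein_de(
            prot, dataset.truth.channel_strain, a, b, p_threshold=thresholds.protein_p
        )

    # --- join and classify
    id_map = {p.protein_id: (None if p.protein_id.startswith("XP_") else p.protein_id)
              for p in prot}
    all_de = [r for comp in comparisons for r in de[comp]]
    joined = integration.join_layers(all_de, prot, id_map, catalog)
    sets = classify_candidates(joined, res_snps, catalog, thresholds, comparisons)
    clusters = detect_cyp_clusters(sets["H3"], thresholds.cluster_max_gap)
    filtered = filter_by_loci(sets, loci, placed_chromosomes=set(dataset.chrom_lengths))
    return AnalysisResult(
        resistance_snps=res_snps,
        window_counts=wc,
        loci=loci,
        de=de,
        proteins=prot,
        joined=joined,
        hypothesis_sets=sets,
        filtered_sets=filtered,
        cyp_clusters=clusters,
        consolidation_pre=consolidate(sets, "pre_filter"),
        consolidation_post=consolidate(filtered, "post_filter"),
    )
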