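# congenomics

Congenic-strain multi-omics mapping of cytochrome P450 (CYP)–mediated
insecticide resistance.

Metabolic resistance to pyrethroids in *Aedes aegypti* is driven by
over-expressed or mutated CYP detoxification enzymes, but the *causes*
of that over-expression — promoter mutations, gene duplications, mutated
regulators ("switches": transcription factors or lncRNAs), or protein
stabilisation — are hard to separate. A powerful design compares three
strains: a susceptible recipient (**ROCK**), a resistant donor (**SP**)
and a **congenic** line (**CKR**) carrying only the donor's resistance
loci introgressed into the recipient background, all referenced against
the genome strain (LVP). `congenomics` implements the downstream
analysis of that design for RNA-seq counts, variant calls and TMT
proteomics, plus a ground-truthed synthetic data generator so the whole
pipeline is testable without any raw sequencing or spectra.

## What it computes

* **Resistance-associated SNPs** — sites with QUAL ≥ 30 that are
  homozygous-alternate in both resistant strains and
  homozygous-reference in ROCK and the reference genome
  (`variants.select_resistance_snps`), with a codon-level effect
  annotator (non-synonymous / synonymous / 5′ / 3′-or-intron /
  intergenic).
* **Locus scan** — counts of those SNPs in non-overlapping 10 Mb
  windows; windows with > 100 SNPs seed resistance loci, adjacent
  supra-threshold windows merge (`locus.window_counts`,
  `locus.call_loci`).
* **Differential transcript expression** — CPM > 1 in ≥ 4 samples
  filter, TMM normalisation, a negative-binomial exact test with
  moderated dispersion, Benjamini–Hochberg FDR; a gene is called when
  |log₂FC| ≥ 1 and FDR ≤ 0.01 (`diffexpr.test_de`).
* **Protein quantification** — razor+unique peptide assignment,
  PSM signal-to-noise rollup to proteins, normalisation on total
  peptide amount, two-sided t-tests at p ≤ 0.05
  (`proteomics`).
* **Variant-informed protein databases** — strain SNPs substituted into
  the genome, strand-aware CDS translation, longest isoform per gene
  (`proteome_db.build_strain_database`).
* **Integration and candidate classification** — transcript/protein
  join, Pearson concordance of log₂ fold-changes, and a six-hypothesis
  engine (H1 mutated CYP, H2 promoter-driven CYP, H3 duplicated CYP
  cluster, H4 mutated switch, H5 mis-expressed switch, H6 stabilised
  CYP protein) with CYP cluster detection, locus filtering and
  candidate consolidation (`hypotheses`, `pipeline.analyze`).

## Worked example

The packaged candidate tables (see `congenomics.datasets`) run the
candidate engine end to end:

```python
from congenomics import datasets
from congenomics.hypotheses import (
    classify_candidates, consolidate, detect_cyp_clusters, filter_by_loci,
)

records = datasets.load_cyp_expression()
sets = classify_candidates(records, [], {})
print("dual-layer up CYPs (H2/H3):", len(sets["H2"].genes))
print("protein-only up CYPs (H6):", len(sets["H6"].genes), "+", sets["H6"].accession_only)

cand = datasets.load_candidate_sets()
pre = consolidate(cand, "pre_filter")
filt = filter_by_loci(cand, datasets.study_resistance_loci(),
                      placed_chromosomes=datasets.STUDY_CHROMOSOMES)
post = consolidate(filt, "post_filter")
print("candidates before locus filter:", pre.union_size)
print("switch candidates (H4|H5) after filter:", post.switch_union_size)
```

prints

```
dual-layer up CYPs (H2/H3): 10
protein-only up CYPs (H6): 5 + ['EAT33129.1']
candidates before locus filter: 139
switch candidates (H4|H5) after filter: 65
```

Ten CYPs are up-regulated as both transcript and protein in both
resistant strains (the H2/H3 set, containing three tight clusters —
`detect_cyp_clusters` finds them); five annotated CYPs plus one
accession-only protein are up-regulated as protein only, the signature
of protein stabilisation (H6); the six hypothesis lists consolidate to
139 unique candidates, and filtering the switch candidates against the
mapped resistance loci on chromosomes 1 and 3 leaves 65.

The synthetic generator exercises the same pipeline with a known answer:

```python
from congenomics.simulate import SimulationConfig, simulate_congenic_design
from congenomics.pipeline import analyze

ds = simulate_congenic_design(SimulationConfig(seed=1))
res = analyze(ds)
print(len(res.resistance_snps), [(l.chrom, l.start, l.end) for l in res.loci])
```

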