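# Methods

## The strain design and what each comparison isolates

Three strains are analysed against a reference genome (LVP): ROCK, a
susceptible laboratory strain; SP, a field-derived pyrethroid-resistant
strain; and CKR, a congenic line carrying SP's resistance loci in a
ROCK background. Because CKR shares ROCK's genome everywhere except the
introgressed blocks, any molecular difference present in *both* SP and
CKR but absent from ROCK is a candidate cause of resistance, and its
genomic position must fall inside an introgressed block unless the
mechanism is invisible to a SNP scan (duplication) or acts in trans
(a stabilising factor elsewhere).

## Resistance-associated SNP selection

Variant sites are kept when the phred-scaled call confidence is at
least 30 (a site exactly at 30 is retained; the filter removes calls
*below* 30). Each site's genotype pattern across
(ROCK, SP, CKR) is classified into four codes when all three calls are
homozygous — `a`: ROCK differs from SP = CKR; `b`: SP differs;
`c`: CKR differs; `d`: all equal — and `uninformative` whenever any
call is heterozygous or missing. The *resistance-associated* pattern is
code `a` with SP = CKR homozygous-alternate and ROCK
homozygous-reference (the reference strain is reference-allele by
construction), i.e. the donor allele fixed in both resistant strains.
Multi-allelic records are split into biallelic sites before
classification.

Coding effects are annotated per SNP by strand-aware codon translation
of the spliced CDS: categories are non-synonymous, synonymous, 5′ UTR,
3′-UTR-or-intron and intergenic. When a SNP hits several overlapping
transcripts the single most severe category is reported (non-synonymous
> synonymous > 5′ > 3′/intron); coding indels are binned as
non-synonymous with an `indel` detail. This annotator intentionally
covers only the effect classes the candidate rules consume, not the
full vocabulary of a general-purpose effect predictor.

## Locus scan

Resistance-associated SNPs are counted in non-overlapping windows
tiling each chromosome (default 10 Mb; SNP at position p lands in
window ⌊(p−1)/w⌋). Windows whose count strictly exceeds 100 seed loci;
adjacent supra-threshold windows merge into one interval. A count of
exactly 100 is not a seed. Tiling (not sliding) windows match how the
density scan is binned and make the conservation invariant exact: window
counts per chromosome sum to the SNP count. No permutation null is
attached to peaks — the threshold is the published operational rule.

## Differential transcript expression

Genes enter testing when CPM > 1 in at least 4 of the compared samples
and the count total is non-zero in each strain. Between-sample scaling
uses the trimmed mean of M-values (TMM): the reference sample is the
one whose upper-quartile count rate is closest to the mean upper
quartile; log-ratios M and average intensities A are computed over
genes positive in both samples, doubly trimmed (30 % on M, 5 % on A),
and combined with inverse delta-method variance weights; factors are
rescaled to geometric mean 1.

Testing uses a negative-binomial exact test conditional on group
totals, after scaling all samples to the geometric-mean effective
library size and rounding ("pseudo-counts"). Counts are modelled
NB(μ, φ) with Var = μ + φμ². A common dispersion maximises the summed
conditional log-likelihood over genes; per-gene (tagwise) dispersions
maximise the gene's own conditional likelihood plus a shared average
likelihood weighted by prior.df / residual.df (prior.df = 10), on a
log-spaced grid around the common value. The two group totals are then
compared exactly: the sum of n NB(μ, φ) draws is NB with size n/φ, and
the p-value sums the probabilities of all partitions of the overall
total no more likely than the observed one. P-values are adjusted by
Benjamini–Hochberg; calls require |log₂FC| ≥ 1 and FDR ≤ 0.01. Fold
changes are reported from normalised group means with a 0.5
pseudo-count guard (display only — testing uses the unguarded counts);
positive log₂FC means higher in the first-named (resistant) strain.
This is a from-scratch implementation of the classic count-model
workflow, not a wrapper; exact numeric equality with any particular
package's shrinkage constants is not claimed. A cross-validation test
runs the canonical R exact-test workflow on an identical simulated
matrix and checks that p-value rankings and the up-called gene sets
agree.

## Protein quantification

PSM-level TMT signal-to-noise values carry the quantification. Shared
peptides are resolved by the razor rule: each peptide goes to the
candidate protein with the largest number of distinct peptides in the
table, ties to the lexicographically smallest protein id (an explicit,
order-invariant tie-break). Protein abundance per channel is the sum of
its PSMs' S/N; rollup conserves channel totals exactly. Channels are
then normalised so every channel total equals the mean raw total
("normalisation on total peptide amount"), an idempotent scaling that
preserves within-channel ratios. Rollup precedes normalisation.

Differences between strains are tested per protein with a two-sided
two-sample t-test (equal variances) on log₂(normalised abundance + 1),
called at p ≤ 0.05 with the sign of the log₂ ratio of group means. No
multiple-testing correction is applied by default, mirroring the raw
per-protein criterion the candidate rules use; BH can be switched on
(`adjust=True`). The upstream acquisition pipeline's internal test is
not re-implemented; candidate classification depends only on the
p ≤ 0.05 call, not on matching any vendor's exact p-values. No isotope
impurity correction is applied (instrument-specific input).

## Variant-informed protein database

Strain-homozygous SNPs are substituted into the reference genome (the
reference allele is checked at every site; overlapping variants are
rejected), spliced CDS sequences are extracted strand-aware and
translated with the standard code, translation truncates at the first
stop codon (a stop before the annotated end sets a `premature_stop`
flag; ambiguous bases translate to X with a warning), and the longest
isoform per gene is kept (ties to the smallest transcript id).
Substituting at genome level makes intronic/intergenic variants
harmless by construction. Indels are excluded from database
construction because length-changing edits would shift annotation
coordinates downstream; the sequence-level `apply_variants` primitive
supports them. With zero variants the strain database is byte-identical
to the reference database.

## Integration and the six hypotheses

Transcript and protein results join per gene (full outer join);
proteins with no annotated gene are retained under their accession as
protein-only records. Concordance is the Pearson correlation of log₂
fold-changes over genes quantified in both layers — a deliberately
optimistic convention (discordant absences are excluded) kept for
comparability.

Candidate rules, evaluated on the SP/ROCK and CKR/ROCK comparisons:

| H | class | rule |
|---|-------|------|
| H1 | CYP | non-synonymous resistance SNP; no expression change required (an `expression_changed` note records whether one exists) |
| H2 | CYP | transcript **and** protein up in **both** resistant strains |
| H3 | CYP | same membership as H2, read as duplication of a CYP or tight CYP cluster |
| H4 | switch (TF/lncRNA) | non-synonymous resistance SNP |
| H5 | switch | transcript up in both strains **or** down in both (regulators may be enhancers or repressors) |
| H6 | CYP | protein up in both strains, **not** transcript-up-in-both, both layers quantified |

H6's "not up in both" reading reproduces the observed pattern where a
CYP up as transcript in only one strain still counts as protein-only;
protein entries with no gene id that meet the H6 signature are reported
separately and excluded from the candidate gene list. CYP clusters are
single-linkage groups of H2/H3 CYPs whose spans lie within 100 kb on
one chromosome (the 100 kb gap is this package's operational choice; the
cluster concept itself has no published distance rule).

Locus filtering passes a gene when its span intersects any mapped
resistance locus. H3 is exempt (duplications are invisible to a SNP
density scan) and H6 is exempt (the stabilising factor, not the CYP, is
the mapped entity); genes on unplaced scaffolds cannot be filtered and
are retained with an `unfilterable` flag. Consolidation deduplicates by
gene id across hypotheses and reports per-hypothesis counts, the total
union and the H4 ∪ H5 switch union. Switch membership (TF vs lncRNA)
comes from the annotation's `gene_class` tag — identifying regulators
is curation, not computation, here.

## Synthetic data generator

The generator emulates the congenic design, not raw reads or spectra:

* **Genome & annotation** — random-base chromosomes at one-tenth the
  real chromosome scale (31/47/41 Mb defaults keep full-scale runs in
  seconds while preserving multi-window geometry); two-exon genes with
  UTRs and CDS length a multiple of 3; `gene_class` tags with ~8 % TF
  and ~8 % lncRNA; CYPs include a planted 3-gene tandem cluster.
* **Variants** — donor SNPs at 15/Mb (Poisson; between the genome
  average and the observed peak density of the real scan), hom-alt in
  SP genome-wide and in CKR only inside introgressed blocks; shared
  background divergence vs the reference at 1/Mb; heterozygous calls
  injected at 2 % to exercise the homozygosity filter (residual
  heterozygosity of the real strains is unknown — this is a
  placeholder, not an inference); 5 % of sites drawn with QUAL < 30.
  A non-synonymous SNP is planted in the causal switch and in
  block-resident H1-style CYPs (the resistance pattern can only exist
  inside a block under this design, so H1 CYPs are drawn from
  block-resident genes).
* **Counts** — NB(μ, φ) with per-gene base means 2^U(3, 9) and
  dispersion 0.05 (BCV ≈ 0.22, the conservative end for genetically
  identical laboratory strains reared in parallel; planted-effect genes
  and CYPs draw from the upper mean range, as detoxification genes are
  highly expressed); planted log₂FC 2.0 on regulated CYPs and the
  switch in both resistant strains, consistent with the fold-change
  range observed for real regulated CYPs; per-sample library factors
  U(0.8, 1.25).
* **Proteins** — protein log₂ effects are transcript effects scaled by
  a concordance of 0.8; stabilized CYPs get protein-only effects
  (transcript effect exactly 0); per-protein S/N split over 1–4 PSMs
  with log-normal noise at CV 20 % (no published MS noise model — this
  is a generic multiplicative-error choice); 10 % of non-leading PSMs
  gain a second candidate protein to exercise razor assignment; a 4/3/3
  ROCK/SP/CKR channel layout and 4/4/4 RNA replicates mirror the real
  design; two proteins carry no gene annotation.
* **Truth** — block coordinates, per-site pattern labels recorded from
  the construction path (not by calling the classifier), per-gene true
  fold changes, and the planted switch / regulated / stabilized /
  H1 CYP id lists.

Identical config and seed give identical datasets; all randomness flows
from one `numpy` Generator.

What the generator does **not** emulate: read-level artefacts
(mapping bias, positional coverage), linkage beyond fixed introgression
blocks, transcript-level quantification uncertainty, peptide
detectability as a function of sequence, and missing-value structure in
MS data. Passing recovery tests therefore demonstrates the *logic* of
the pipeline under the stated noise models, not robustness to every
artefact of real data. One visible consequence: the synthetic CYP
transcript-protein Pearson r (~0.3 at desk scale) is far below the
real study's 0.80, because the small synthetic CYP panel contains a
much higher fraction of deliberately discordant (stabilized) CYPs than
a real 76-CYP panel does.

## Numerical and scale choices

* Internal coordinates are 0-based half-open; VCF/GFF3 emit 1-based
  inclusive. QUAL is serialised at one decimal and S/N at four, so
  write→read round-trips are exact.
* The exact-test partition sum is computed in log space and normalised;
  a zero overall total gives p = 1.
* Dispersion optimisation is bounded in [10⁻⁶, 5]; the tagwise grid
  spans 2^±8 around the common value in 33 points.
* Simulation problem sizes in the test-suite and acceptance script
  (40–70 Mb genomes, 30–60 genes/chromosome, 10–50 seeds per recovery
  property) were chosen so the stochastic recovery criteria are
  measured on comfortably powered designs while a full run of the suite
  stays in the order of a minute.
* Ties: razor assignment and longest-isoform selection break ties by
  lexicographic id; these are contracts, tested as such.

## Known limitations

* The effect annotator ignores splice-site and regulatory region
  classes; UTR assignment presumes annotated CDS boundaries.
* The NB exact test assumes a two-group design; no batch covariates or
  GLM contrasts.
* Protein inference is razor-by-count only — no parsimony groups or
  shared-peptide probabilistic apportioning.
* The locus caller reports merged supra-threshold windows; it attaches
  no statistical significance to peaks.
* Heterozygous proteome variants are not expanded into allelic protein
  pairs.
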