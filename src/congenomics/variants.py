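"""Variant quality filtering, strain genotype-pattern classification and
coding-effect annotation.

The experimental design compares three strains against the reference
genome (LVP): ROCK (susceptible recipient background), SP (resistant
donor) and CKR (congenic: SP resistance loci introgressed into ROCK).
A site is *resistance associated* when both resistant strains carry the
alternate allele homozygously while ROCK and the reference carry the
reference allele — the genotype signature expected of an introgressed
donor block under selection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .annotation import Gene

STRAINS = ("ROCK", "SP", "CKR")

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GENOTYPES = (HOM_REF, HET, HOM_ALT, MISSING)

EFFECT_CATEGORIES = (
    "non_synonymous",
    "synonymous",
    "five_prime",
    "three_prime_or_intron",
    "intergenic",
)
# when a SNP hits several overlapping transcripts the most severe single
# category is reported
_SEVERITY = {c: i for i, c in enumerate(EFFECT_CATEGORIES)}


class AnnotationError(ValueError):
    """Raised when a gene model is structurally unusable (e.g. CDS length not a multiple of 3)."""


@dataclass
class EffectClass:
    category: str
    gene_id: str | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.category not in EFFECT_CATEGORIES:
            raise ValueError(f"unknown effect category {self.category!r}")
        if self.category != "intergenic" and self.gene_id is None:
            raise ValueError("gene_id required for genic effect categories")


@dataclass
class VariantSite:
    """One biallelic site with per-strain genotype calls.

    The reference strain (LVP) is implicitly homozygous-reference; only
    the three study strains appear in ``genotypes``.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    qual: float
    genotypes: dict[str, str]
    effect: EffectClass | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if self.qual < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: qual must be >= 0")
        unknown = set(self.genotypes) - set(STRAINS)
        if unknown:
            raise ValueError(f"{self.chrom}:{self.pos}: unknown strain keys {sorted(unknown)}")
        if set(self.genotypes) != set(STRAINS):
            missing = set(STRAINS) - set(self.genotypes)
            raise ValueError(f"{self.chrom}:{self.pos}: missing strain genotypes {sorted(missing)}")
        bad = {s: g for s, g in self.genotypes.items() if g not in GENOTYPES}
        if bad:
            raise ValueError(f"{self.chrom}:{self.pos}: invalid genotype codes {bad}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class PatternClass:
    """Genotype pattern across ROCK/SP/CKR.

    Codes (all three strains homozygous, non-missing):
      a: ROCK differs from SP = CKR
      b: SP differs from ROCK = CKR
      c: CKR differs from ROCK = SP
      d: ROCK = SP = CKR
    Any heterozygous or missing call makes the site uninformative.
    """

    code: str
    resistance_associated: bool


def filter_quality(sites: list[VariantSite], min_qual: float = 30.0) -> list[VariantSite]:
    """Drop sites with QUAL below ``min_qual``; a site exactly at the
    threshold is retained.  Order preserving and idempotent."""
    if min_qual < 0:
        raise ValueError("min_qual must be >= 0")
    return [s for s in sites if s.qual >= min_qual]


def classify_genotype_pattern(site: VariantSite) -> PatternClass:
    r = site.genotypes["ROCK"]
    s = site.genotypes["SP"]
    c = site.genotypes["CKR"]
    hom = {HOM_REF, HOM_ALT}
    if not (r in hom and s in hom and c in hom):
        return PatternClass("uninformative", False)
    if r == s == c:
        return PatternClass("d", False)
    if s == c:  # ROCK is the odd one out
        resistant = r == HOM_REF and s == HOM_ALT  # SP=CKR share the non-reference allele
        return PatternClass("a", resistant)
    if r == c:
        return PatternClass("b", False)
    return PatternClass("c", False)


def select_resistance_snps(sites: list[VariantSite]) -> list[VariantSite]:
    """Sites homozygous-alternate in both SP and CKR and homozygous-reference
    in ROCK (and, implicitly, in the reference genome)."""
    return [s for s in sites if classify_genotype_pattern(s).resistance_associated]


def count_by_chromosome(sites: list[VariantSite]) -> dict[str, int]:
    return dict(Counter(s.chrom for s in sites))


def _spliced_cds(genome: dict[str, str], chrom: str, cds: list[tuple[int, int]], strand: str) -> str:
    seq = "".join(genome[chrom][s:e] for s, e in sorted(cds))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_offset(cds: list[tuple[int, int]], strand: str, pos0: int) -> int | None:
    """Offset of genomic position ``pos0`` within the spliced CDS (5'->3'), or None."""
    ordered = sorted(cds)
    running = 0
    offsets = []
    for s, e in ordered:
        if s <= pos0 < e:
            offsets.append(running + (pos0 - s))
        running += e - s
    if not offsets:
        return None
    off = offsets[0]
    if strand == "-":
        total = sum(e - s for s, e in ordered)
        off = total - 1 - off
    return off


def _classify_in_transcript(site: VariantSite, gene: Gene, tr, genome: dict[str, str]) -> EffectClass | None:
    pos0 = site.pos - 1
    if not (gene.start <= pos0 < gene.end):
        return None
    if tr.cds and tr.cds_length % 3 != 0:
        raise AnnotationError(
            f"transcript {tr.transcript_id}: CDS length {tr.cds_length} is not a multiple of 3"
        )
    in_exon = any(s <= pos0 < e for s, e in tr.exons)
    off = _cds_offset(tr.cds, gene.strand, pos0) if tr.cds else None
    if off is not None:
        if not site.is_snp:
            return EffectClass("non_synonymous", gene.gene_id, "indel")
        cds_seq = _spliced_cds(genome, gene.chrom, tr.cds, gene.strand)
        codon_i = off // 3
        within = off % 3
        codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
        alt_base = site.alt_allele
        if gene.strand == "-":
            alt_base = str(Seq(alt_base).reverse_complement())
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_ref == aa_alt:
            return EffectClass("synonymous", gene.gene_id, f"{aa_ref}{codon_i + 1}{aa_alt}")
        return EffectClass("non_synonymous", gene.gene_id, f"{aa_ref}{codon_i + 1}{aa_alt}")
    if in_exon and tr.cds:
        cds_start = min(s for s, _ in tr.cds)
        cds_end = max(e for _, e in tr.cds)
        if pos0 < cds_start:
            upstream = gene.strand == "+"
        elif pos0 >= cds_end:
            upstream = gene.strand == "-"
        else:  # inside the CDS span but not in a CDS interval: intronic slippage, treat below
            return EffectClass("three_prime_or_intron", gene.gene_id, "intron")
        if upstream:
            return EffectClass("five_prime", gene.gene_id, "5' UTR")
        return EffectClass("three_prime_or_intron", gene.gene_id, "3' UTR")
    if in_exon:  # non-coding transcript
        return EffectClass("three_prime_or_intron", gene.gene_id, "non-coding exon")
    return EffectClass("three_prime_or_intron", gene.gene_id, "intron")


def annotate_effect(
    site: VariantSite, genes: list[Gene], genome: dict[str, str]
) -> EffectClass:
    """Classify a variant's predicted coding effect against gene models.

    Coding SNPs are translated (strand-aware) and compared codon-by-codon;
    exonic positions outside the CDS map to the 5' or 3' UTR by strand;
    intronic positions join the 3'/intron bucket; everything else is
    intergenic.  With several overlapping transcripts the most severe
    category wins.
    """
    if site.chrom not in genome:
        raise ValueError(f"{site.chrom}:{site.pos}: contig {site.chrom!r} not in genome")
    if site.pos > len(genome[site.chrom]):
        raise ValueError(
            f"{site.chrom}:{site.pos}: position beyond contig length {len(genome[site.chrom])}"
        )
    best: EffectClass | None = None
    for gene in genes:
        if gene.chrom != site.chrom:
            continue
        for tr in gene.transcripts:
            eff = _classify_in_transcript(site, gene, tr, genome)
            if eff is not None and (best is None or _SEVERITY[eff.category] < _SEVERITY[best.category]):
                best = eff
        if not gene.transcripts and gene.start <= site.pos - 1 < gene.end:
            eff = EffectClass("three_prime_or_intron", gene.gene_id, "gene body")
            if best is None or _SEVERITY[eff.category] < _SEVERITY[best.category]:
                best = eff
    return best if best is not None else EffectClass("intergenic")


def annotate_sites(
    sites: list[VariantSite], genes: list[Gene], genome: dict[str, str]
) -> list[VariantSite]:
    """Annotate ``effect`` in place on every site; returns the same list."""
    for s in sites:
        s.effect = annotate_effect(s, genes, genome)
    return sites
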