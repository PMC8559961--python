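"""Strain-specific, variant-informed protein database construction.

Strain variants are substituted into the reference genome, spliced CDS
sequences are extracted strand-aware and translated with the standard
genetic code, and one protein — the longest isoform — is kept per gene.
Applying variants at the genome level (rather than per transcript) makes
intronic and intergenic variants harmless by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

from .annotation import Gene
from .variants import HOM_ALT, AnnotationError, VariantSite


@dataclass
class ProteinSeq:
    gene_id: str
    transcript_id: str
    sequence: str
    premature_stop: bool = False
    has_ambiguous: bool = False


def variants_for_strain(sites: list[VariantSite], strain: str) -> list[tuple[str, int, str, str]]:
    """(chrom, pos, ref, alt) tuples at which ``strain`` is homozygous-alternate."""
    return [
        (s.chrom, s.pos, s.ref_allele, s.alt_allele)
        for s in sites
        if s.genotypes[strain] == HOM_ALT
    ]


def apply_variants(
    genome_seq: dict[str, str],
    variants: list[tuple[str, int, str, str]],
) -> dict[str, str]:
    """Substitute homozygous variants into the reference sequence.

    Variants are (chrom, 1-based pos, ref, alt); the reference allele
    must match the genome at its position.  Overlapping variants are
    rejected.  Indels are applied high-to-low so earlier substitutions
    keep their coordinates; sequence length changes only through them.
    """
    by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for chrom, pos, ref, alt in variants:
        if chrom not in genome_seq:
            raise ValueError(f"{chrom}:{pos}: contig {chrom!r} not in genome")
        if pos < 1 or pos - 1 + len(ref) > len(genome_seq[chrom]):
            raise ValueError(f"{chrom}:{pos}: variant outside contig bounds")
        by_chrom.setdefault(chrom, []).append((pos, ref, alt))

    out = dict(genome_seq)
    for chrom, muts in by_chrom.items():
        muts.sort()
        for (p1, r1, _), (p2, _, _) in zip(muts, muts[1:]):
            if p1 + len(r1) > p2:
                raise ValueError(f"{chrom}:{p2}: variant overlaps preceding variant at {p1}")
        seq = out[chrom]
        for pos, ref, alt in reversed(muts):
            observed = seq[pos - 1 : pos - 1 + len(ref)]
            if observed != ref:
                raise ValueError(
                    f"{chrom}:{pos}: reference allele mismatch (expected {ref!r}, genome has {observed!r})"
                )
            seq = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
        out[chrom] = seq
    return out


def extract_and_translate(genome_seq: dict[str, str], genes: list[Gene]) -> list[ProteinSeq]:
    """Translate every transcript's spliced CDS.

    Translation stops at the first stop codon; a stop before the end of
    the CDS truncates the protein and sets ``premature_stop``.  Runs of
    N in the CDS translate to X residues with a warning.
    """
    proteins = []
    for gene in genes:
        for tr in gene.transcripts:
            if not tr.cds:
                continue
            if tr.cds_length % 3 != 0:
                raise AnnotationError(
                    f"transcript {tr.transcript_id}: CDS length {tr.cds_length} not a multiple of 3"
                )
            cds = "".join(genome_seq[gene.chrom][s:e] for s, e in sorted(tr.cds))
            if gene.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            aa = str(Seq(cds).translate())
            stop = aa.find("*")
            if stop == -1:
                protein, premature = aa, False
            else:
                protein, premature = aa[:stop], stop < len(aa) - 1
            has_x = "X" in protein
            if has_x:
                warnings.warn(
                    f"transcript {tr.transcript_id}: ambiguous bases translate to X",
                    stacklevel=2,
                )
            proteins.append(ProteinSeq(gene.gene_id, tr.transcript_id, protein, premature, has_x))
    return proteins


def longest_isoform(proteins: list[ProteinSeq]) -> list[ProteinSeq]:
    """One protein per gene: the longest isoform, ties broken by the
    lexicographically smallest transcript id."""
    best: dict[str, ProteinSeq] = {}
    for p in sorted(proteins, key=lambda p: (-len(p.sequence), p.transcript_id)):
        best.setdefault(p.gene_id, p)
    return [best[g] for g in sorted(best)]


def build_strain_database(
    genome_seq: dict[str, str],
    genes: list[Gene],
    sites: list[VariantSite],
    strain: str,
) -> list[ProteinSeq]:
    """Full database build: substitute the strain's homozygous SNPs,
    translate every transcript and keep the longest isoform per gene.

    Indels are excluded here (with a warning) because they would shift
    annotation coordinates downstream; `apply_variants` itself supports
    them for sequence-level use.
    """
    muts = variants_for_strain(sites, strain)
    snps = [(c, p, r, a) for c, p, r, a in muts if len(r) == 1 and len(a) == 1]
    if len(snps) < len(muts):
        warnings.warn(
            f"{len(muts) - len(snps)} indel(s) skipped in database construction "
            "(annotation coordinates are only valid under length-preserving substitution)",
            stacklevel=2,
        )
    strain_genome = apply_variants(genome_seq, snps)
    return longest_isoform(extract_and_translate(strain_genome, genes))


def write_protein_fasta(proteins: list[ProteinSeq], strain: str, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.gene_id}|{p.transcript_id} strain={strain}\n{p.sequence}\n")
    return path
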