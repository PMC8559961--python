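"""Readers and writers for the pipeline's file formats.

VCF v4.2 (GT + QUAL, four sample columns ROCK/SP/CKR/LVP), FASTA,
gene-count TSV (first column gene id, one column per sample, strain
encoded as the sample-name prefix) and PSM TSV (peptide, semicolon-
separated candidate proteins, one S/N column per channel).  GFF3 lives
in :mod:`congenomics.annotation`.

QUAL and S/N are serialised at fixed decimal precision (1 and 4 places)
so that write -> read round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .diffexpr import CountMatrix
from .proteomics import PSMRecord
from .variants import HET, HOM_ALT, HOM_REF, MISSING, STRAINS, VariantSite

VCF_SAMPLES = ("ROCK", "SP", "CKR", "LVP")
_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    sites: list[VariantSite], chrom_lengths: dict[str, int], path: str | Path
) -> Path:
    """Write sites as VCF v4.2 with GT for ROCK/SP/CKR and the reference
    strain LVP (always 0/0)."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=congenomics",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c},length={n}>" for c, n in chrom_lengths.items()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(VCF_SAMPLES))
    for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
        gts = [_GT_STR[s.genotypes[strain]] for strain in STRAINS] + ["0/0"]
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t{s.qual:.1f}\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path) -> list[VariantSite]:
    """Parse a VCF into VariantSites; multi-allelic records are split
    into biallelic sites (the genotype of each strain is interpreted
    against one alternate allele at a time)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx = {name: samples.index(name) for name in samples}
    sites: list[VariantSite] = []
    for v in vcf:
        for alt_i, alt in enumerate(v.ALT, start=1):
            genotypes: dict[str, str] = {}
            for strain in STRAINS:
                a = v.genotypes[idx[strain]][:2]
                if -1 in a:
                    genotypes[strain] = MISSING
                elif a[0] == a[1] == 0:
                    genotypes[strain] = HOM_REF
                elif a[0] == a[1] == alt_i:
                    genotypes[strain] = HOM_ALT
                elif alt_i in a or a[0] == a[1]:
                    # one copy of this alt, or homozygous for a different alt
                    genotypes[strain] = HET if alt_i in a else HOM_REF
                else:
                    genotypes[strain] = HOM_REF
            sites.append(
                VariantSite(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref_allele=v.REF,
                    alt_allele=alt,
                    qual=round(float(v.QUAL), 2) if v.QUAL is not None else 0.0,
                    genotypes=genotypes,
                )
            )
    return sites


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_counts(cm: CountMatrix, path: str | Path) -> Path:
    df = cm.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    return Path(path)


def read_counts(path: str | Path, sample_strain: dict[str, str] | None = None) -> CountMatrix:
    """Load a counts TSV.  When no explicit sample -> strain map is
    given, the strain is taken as the sample-name prefix before '_'."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sample_strain is None:
        sample_strain = {s: s.rsplit("_", 1)[0] for s in df.columns}
    return CountMatrix(df, sample_strain)


def write_psms(psms: list[PSMRecord], channels: list[str], path: str | Path) -> Path:
    rows = []
    for p in psms:
        row: dict[str, object] = {"peptide": p.peptide, "proteins": ";".join(p.proteins)}
        for ch in channels:
            row[ch] = f"{p.sn.get(ch, 0.0):.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_psms(path: str | Path) -> tuple[list[PSMRecord], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "proteins": str})
    channels = [c for c in df.columns if c not in ("peptide", "proteins")]
    psms = [
        PSMRecord(
            peptide=row["peptide"],
            proteins=tuple(row["proteins"].split(";")),
            sn={ch: float(row[ch]) for ch in channels},
        )
        for _, row in df.iterrows()
    ]
    return psms, channels
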