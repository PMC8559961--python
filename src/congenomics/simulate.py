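"""Synthetic congenic-strain multi-omics dataset generator.

Emulates the three-strain design used to map CYP-mediated pyrethroid
resistance: a susceptible recipient strain (ROCK), a resistant donor
strain (SP) and a congenic strain (CKR) carrying SP-derived introgressed
blocks in a ROCK background, all called against a reference genome
(LVP).  The generator produces, with a recorded ground truth:

* a genome and gene annotation (genes with mRNA/exon/CDS structure and
  gene-class tags: CYP, TF, lncRNA, other);
* variant sites: donor-specific SNPs (hom-alt in SP genome-wide, hom-alt
  in CKR only inside introgressed blocks), background divergence shared
  by all three strains, a small het-injection rate, and planted
  non-synonymous SNPs in a causal "switch" and in H1-style CYPs;
* a negative-binomial RNA-seq count matrix with planted fold-changes on
  regulated CYPs and the causal switch;
* a PSM-level TMT table whose protein abundances propagate the
  transcript effects scaled by a configurable concordance, plus
  "stabilized" CYPs with protein-only effects.

Same config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .annotation import Gene, Transcript, read_gff3, write_gff3
from .diffexpr import CountMatrix
from .proteomics import PSMRecord
from .variants import HET, HOM_ALT, HOM_REF, STRAINS, VariantSite

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

COMPARISONS = ("SP/ROCK", "CKR/ROCK")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic congenic dataset.

    Defaults mirror the published design at one-tenth genome scale:
    three chromosomes, introgressed donor blocks on chromosomes 1 and 3
    (the chromosome-3 block containing the causal locus), ten regulated
    CYPs, five stabilized CYPs, 4/4/4 RNA-seq replicates and 4/3/3 TMT
    channels for ROCK/SP/CKR.
    """

    chromosome_lengths: tuple[tuple[str, int], ...] = (
        ("1", 31_000_000),
        ("2", 47_000_000),
        ("3", 41_000_000),
    )
    n_genes_per_chrom: int = 100
    donor_snp_density: float = 15.0  # expected donor SNPs per Mb (Poisson)
    background_snp_density: float = 1.0  # strain-vs-reference divergence per Mb
    het_rate: float = 0.02  # per-site chance one strain is heterozygous
    low_qual_rate: float = 0.05  # fraction of sites assigned QUAL < 30
    introgressed_blocks: tuple[tuple[str, int, int], ...] = (
        ("1", 5_000_000, 25_000_000),
        ("3", 28_000_000, 40_000_000),
    )
    causal_locus: tuple[str, int, int] | None = ("3", 30_000_000, 36_000_000)
    n_regulated_cyps: int = 10
    n_stabilized_cyps: int = 5
    n_h1_cyps: int = 1  # CYPs given a non-synonymous resistance SNP
    planted_log2fc: float = 2.0
    protein_concordance: float = 0.8  # fraction of transcript effect seen in protein
    rna_replicates: dict[str, int] = field(
        default_factory=lambda: {"ROCK": 4, "SP": 4, "CKR": 4}
    )
    tmt_channels: dict[str, int] = field(
        default_factory=lambda: {"ROCK": 4, "SP": 3, "CKR": 3}
    )
    nb_mean_log_range: tuple[float, float] = (3.0, 9.0)  # log2 of NB base means
    # BCV ~0.22: the conservative end of the range expected for
    # genetically identical laboratory strains reared in parallel
    nb_dispersion: float = 0.05
    psm_per_protein: int = 4
    protein_detect_fraction: float = 0.7
    protein_cv: float = 0.2  # log-normal multiplicative S/N noise
    shared_peptide_rate: float = 0.1
    n_unannotated_proteins: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosome_lengths)
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.introgressed_blocks:
            if chrom not in lengths:
                raise ValueError(f"introgressed_blocks: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(
                    f"introgressed_blocks: block {chrom}:{start}-{end} outside chromosome"
                )
            per_chrom.setdefault(chrom, []).append((start, end))
        for chrom, blocks in per_chrom.items():
            blocks.sort()
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                if e1 > s2:
                    raise ValueError(
                        f"introgressed_blocks: overlapping blocks on chromosome {chrom}"
                    )
        if self.causal_locus is not None:
            c, s, e = self.causal_locus
            if not any(
                c == bc and bs <= s and e <= be for bc, bs, be in self.introgressed_blocks
            ):
                raise ValueError("causal_locus: must be contained in an introgressed block")
        if not 0.0 <= self.protein_concordance <= 1.0:
            raise ValueError("protein_concordance: must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion: must be > 0")
        if self.psm_per_protein < 1:
            raise ValueError("psm_per_protein: must be >= 1")
        for name, mapping in (("rna_replicates", self.rna_replicates),
                              ("tmt_channels", self.tmt_channels)):
            for strain in STRAINS:
                if mapping.get(strain, 0) < 2:
                    raise ValueError(f"{name}: strain {strain} needs >= 2 replicates")


@dataclass
class TruthRecord:
    """Ground truth recorded at generation time, independent of the
    analysis code paths it is used to check."""

    introgressed_blocks: list[tuple[str, int, int]]
    causal_locus: tuple[str, int, int] | None
    switch_id: str | None
    regulated_cyp_ids: list[str]
    stabilized_cyp_ids: list[str]
    h1_cyp_ids: list[str]
    transcript_log2fc: dict[str, dict[str, float]]  # gene -> comparison -> lfc
    protein_log2fc: dict[str, dict[str, float]]
    site_patterns: dict[str, dict]  # "chrom:pos" -> {code, resistance_associated, qual}
    protein_detected_ids: list[str]
    unannotated_protein_ids: list[str]
    sample_strain: dict[str, str]
    channel_strain: dict[str, str]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[Gene]
    variants: list[VariantSite]
    counts: CountMatrix
    psms: list[PSMRecord]
    channels: list[str]
    truth: TruthRecord

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.config.chromosome_lengths)

    def transcript_sequences(self) -> dict[str, str]:
        out = {}
        for g in self.genes:
            for t in g.transcripts:
                seq = "".join(self.genome[g.chrom][s:e] for s, e in t.exons)
                out[t.transcript_id] = seq
        return out


def sample_negative_binomial(
    mean: float | np.ndarray, dispersion: float, size, rng: np.random.Generator
) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (Var = mu + phi mu^2)."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _random_genome(lengths: dict[str, int], rng: np.random.Generator) -> dict[str, str]:
    return {
        chrom: _BASES[rng.integers(0, 4, size=n, dtype=np.uint8)].tobytes().decode("ascii")
        for chrom, n in lengths.items()
    }


def _make_gene(gene_id: str, chrom: str, start: int, strand: str,
               gene_class: str, cyp_name: str | None, rng: np.random.Generator) -> Gene:
    """Two-exon gene with 5'/3' UTRs; CDS split across both exons."""
    utr5, utr3 = 120, 150
    cds1 = int(rng.integers(80, 200)) * 3
    cds2 = int(rng.integers(80, 200)) * 3
    intron = int(rng.integers(200, 800))
    exon1 = (start, start + utr5 + cds1)
    exon2_start = exon1[1] + intron
    exon2 = (exon2_start, exon2_start + cds2 + utr3)
    if strand == "+":
        cds = [(start + utr5, exon1[1]), (exon2_start, exon2_start + cds2)]
        exons = [exon1, exon2]
    else:  # mirror: UTR3 first on the genome, 5' UTR at the right end
        exons = [exon1, exon2]
        cds = [(start + utr3, exon1[1]), (exon2_start, exon2_start + cds2)]
    gene = Gene(
        gene_id=gene_id, chrom=chrom, start=exons[0][0], end=exons[-1][1],
        strand=strand, gene_class=gene_class, cyp_name=cyp_name,
        transcripts=[Transcript(transcript_id=f"{gene_id}.t1", exons=exons, cds=cds)],
    )
    return gene


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[Gene]:
    lengths = dict(config.chromosome_lengths)
    genes: list[Gene] = []
    counter = 0
    for chrom, length in config.chromosome_lengths:
        slot = length // (config.n_genes_per_chrom + 1)
        for i in range(config.n_genes_per_chrom):
            counter += 1
            start = slot * (i + 1) + int(rng.integers(0, max(1, slot // 4)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _make_gene(f"SYNG{counter:05d}", chrom, start, strand, "other", None, rng)
            )
    # assign classes: CYPs (regulated + stabilized + extras), switches
    rng.shuffle(genes)  # class assignment decoupled from position
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def _inside(pos: int, chrom: str, intervals) -> bool:
    return any(c == chrom and s < pos <= e for c, s, e in intervals)


def _assign_classes(
    genes: list[Gene], config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[str], list[str], list[str], str | None]:
    """Tag genes with classes and pick the planted-effect genes.

    Returns (regulated_cyp_ids, stabilized_cyp_ids, h1_cyp_ids, switch_id).
    The first three regulated CYPs are relocated to form a tight cluster,
    mimicking tandemly duplicated CYP arrays.
    """
    pool = [g for g in genes]
    rng.shuffle(pool)
    switch_id = None
    if config.causal_locus is not None:
        c, s, e = config.causal_locus
        inside = [g for g in pool if g.chrom == c and s <= g.start and g.end <= e]
        if not inside:
            raise ValueError("causal_locus: no gene falls inside the causal locus")
        switch = inside[0]
        switch.gene_class = "TF"
        switch_id = switch.gene_id
        pool.remove(switch)

    # H1-style CYPs carry a resistance-pattern SNP, which under the congenic
    # design can only exist inside an introgressed block
    in_block = [
        g for g in pool
        if any(g.chrom == c and s <= g.start and g.end <= e
               for c, s, e in config.introgressed_blocks)
    ]
    if len(in_block) < config.n_h1_cyps:
        raise ValueError(
            "n_h1_cyps: not enough genes inside introgressed blocks "
            f"({len(in_block)} available)"
        )
    h1_genes = in_block[: config.n_h1_cyps]
    pool = [g for g in pool if g not in h1_genes]

    n_cyps = config.n_regulated_cyps + config.n_stabilized_cyps + 2
    if n_cyps + 10 > len(pool):
        raise ValueError("n_genes_per_chrom too small for the requested CYP counts")
    cyps = pool[:n_cyps] + h1_genes
    for i, g in enumerate(cyps):
        g.gene_class = "CYP"
        g.cyp_name = f"CYP9S{i + 1}"
    regulated = [g.gene_id for g in cyps[: config.n_regulated_cyps]]
    stabilized = [
        g.gene_id
        for g in cyps[config.n_regulated_cyps : config.n_regulated_cyps + config.n_stabilized_cyps]
    ]
    h1 = [g.gene_id for g in h1_genes]
    rest = pool[n_cyps:]
    n_tf = max(2, len(rest) // 12)
    n_lnc = max(2, len(rest) // 12)
    for g in rest[:n_tf]:
        g.gene_class = "TF"
    for g in rest[n_tf : n_tf + n_lnc]:
        g.gene_class = "lncRNA"

    # cluster the first three regulated CYPs (if available) right next to
    # each other to exercise cluster detection
    if config.n_regulated_cyps >= 3:
        a, b, c3 = (next(g for g in genes if g.gene_id == gid) for gid in regulated[:3])
        for mover, anchor in ((b, a), (c3, b)):
            shift = anchor.end + 20_000 - mover.start
            mover.chrom = anchor.chrom
            mover.start += shift
            mover.end += shift
            for t in mover.transcripts:
                t.exons = [(s + shift, e + shift) for s, e in t.exons]
                t.cds = [(s + shift, e + shift) for s, e in t.cds]
    return regulated, stabilized, h1, switch_id


def _plant_nonsyn_snp(
    gene: Gene, genome: dict[str, str], rng: np.random.Generator
) -> tuple[int, str, str] | None:
    """Pick a CDS position and alternate base giving a non-synonymous
    change (brute-force over codon alternatives)."""
    from Bio.Seq import Seq

    tr = gene.transcripts[0]
    cds_ivs = sorted(tr.cds)
    positions = [p for s, e in cds_ivs for p in range(s, e)]
    for _ in range(50):
        pos0 = positions[int(rng.integers(0, len(positions)))]
        ref = genome[gene.chrom][pos0]
        offset = 0
        for s, e in cds_ivs:
            if s <= pos0 < e:
                offset += pos0 - s
                break
            offset += e - s
        if gene.strand == "-":
            total = sum(e - s for s, e in cds_ivs)
            offset = total - 1 - offset
        cds = "".join(genome[gene.chrom][s:e] for s, e in cds_ivs)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        codon_i, within = divmod(offset, 3)
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        aa_ref = str(Seq(codon).translate())
        for alt in "ACGT":
            if alt == ref:
                continue
            alt_t = str(Seq(alt).reverse_complement()) if gene.strand == "-" else alt
            alt_codon = codon[:within] + alt_t + codon[within + 1 :]
            if str(Seq(alt_codon).translate()) != aa_ref:
                return pos0 + 1, ref, alt
    return None


def _simulate_variants(
    config: SimulationConfig,
    genome: dict[str, str],
    genes: list[Gene],
    planted_nonsyn: dict[str, tuple[str, int, str, str]],
    rng: np.random.Generator,
) -> tuple[list[VariantSite], dict[str, dict]]:
    lengths = dict(config.chromosome_lengths)
    blocks = list(config.introgressed_blocks)
    raw: list[tuple[str, int, str]] = []  # (chrom, pos, origin)
    for chrom, length in config.chromosome_lengths:
        mb = length / 1e6
        n_donor = rng.poisson(config.donor_snp_density * mb)
        for pos in sorted(rng.integers(1, length + 1, size=n_donor)):
            raw.append((chrom, int(pos), "donor"))
        n_bg = rng.poisson(config.background_snp_density * mb)
        for pos in sorted(rng.integers(1, length + 1, size=n_bg)):
            raw.append((chrom, int(pos), "background"))
    for gene_id, (chrom, pos, ref, alt) in planted_nonsyn.items():
        raw.append((chrom, pos, f"planted:{gene_id}:{ref}:{alt}"))

    seen: set[tuple[str, int]] = set()
    sites: list[VariantSite] = []
    patterns: dict[str, dict] = {}
    # planted sites win position collisions against random ones
    for chrom, pos, origin in sorted(
        raw, key=lambda x: (x[0], x[1], 0 if x[2].startswith("planted:") else 1)
    ):
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        if origin.startswith("planted:"):
            _, _gid, ref, alt = origin.split(":")
            genotypes = {"ROCK": HOM_REF, "SP": HOM_ALT, "CKR": HOM_ALT}
            code, resistant = "a", True
            qual = round(float(rng.uniform(60, 900)), 1)
        else:
            ref = genome[chrom][pos - 1]
            alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            if origin == "donor":
                in_block = _inside(pos, chrom, blocks)
                genotypes = {
                    "ROCK": HOM_REF,
                    "SP": HOM_ALT,
                    "CKR": HOM_ALT if in_block else HOM_REF,
                }
                code, resistant = ("a", True) if in_block else ("b", False)
            else:
                genotypes = {"ROCK": HOM_ALT, "SP": HOM_ALT, "CKR": HOM_ALT}
                code, resistant = "d", False
            if rng.random() < config.het_rate:
                strain = STRAINS[int(rng.integers(0, 3))]
                genotypes[strain] = HET
                code, resistant = "uninformative", False
            if rng.random() < config.low_qual_rate:
                qual = round(float(rng.uniform(2, 29.9)), 1)
            else:
                qual = round(float(rng.uniform(30, 900)), 1)
        sites.append(VariantSite(chrom, pos, ref, alt, qual, genotypes))
        patterns[f"{chrom}:{pos}"] = {
            "code": code,
            "resistance_associated": resistant,
            "qual": qual,
        }
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites, patterns


def _simulate_counts(
    config: SimulationConfig,
    genes: list[Gene],
    transcript_lfc: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> CountMatrix:
    lo, hi = config.nb_mean_log_range
    base = {}
    for g in genes:
        if g.gene_id in transcript_lfc or g.gene_class == "CYP":
            # detox CYPs and planted-effect genes are highly expressed
            base[g.gene_id] = 2.0 ** rng.uniform(max(lo, hi - 3), hi)
        else:
            base[g.gene_id] = 2.0 ** rng.uniform(lo, hi)
    samples: list[str] = []
    sample_strain: dict[str, str] = {}
    for strain in STRAINS:
        for i in range(config.rna_replicates[strain]):
            name = f"{strain}_{i + 1}"
            samples.append(name)
            sample_strain[name] = strain
    lib_factor = {s: rng.uniform(0.8, 1.25) for s in samples}
    data = np.zeros((len(genes), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        strain = sample_strain[sample]
        comp = f"{strain}/ROCK"
        for i, g in enumerate(genes):
            mu = base[g.gene_id] * lib_factor[sample]
            if strain != "ROCK":
                mu *= 2.0 ** transcript_lfc.get(g.gene_id, {}).get(comp, 0.0)
            data[i, j] = sample_negative_binomial(mu, config.nb_dispersion, None, rng)
    df = pd.DataFrame(data, index=[g.gene_id for g in genes], columns=samples)
    return CountMatrix(df, sample_strain)


def _random_peptide(rng: np.random.Generator) -> str:
    n = int(rng.integers(8, 16))
    return "".join(_AA_ALPHABET[i] for i in rng.integers(0, len(_AA_ALPHABET), size=n)) + "K"


def _simulate_psms(
    config: SimulationConfig,
    protein_ids: list[str],
    protein_lfc: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> tuple[list[PSMRecord], list[str], dict[str, str]]:
    channels: list[str] = []
    channel_strain: dict[str, str] = {}
    for strain in STRAINS:
        for i in range(config.tmt_channels[strain]):
            name = f"{strain}_{i + 1}"
            channels.append(name)
            channel_strain[name] = strain
    sigma = float(np.sqrt(np.log1p(config.protein_cv**2)))
    psms: list[PSMRecord] = []
    for prot in protein_ids:
        base = 10.0 ** rng.uniform(1.2, 3.0)
        n_psm = int(rng.integers(1, config.psm_per_protein + 1))
        weights = rng.dirichlet(np.ones(n_psm))
        for k in range(n_psm):
            peptide = _random_peptide(rng)
            candidates = (prot,)
            if k > 0 and rng.random() < config.shared_peptide_rate:
                other = protein_ids[int(rng.integers(0, len(protein_ids)))]
                if other != prot:
                    candidates = tuple(sorted((prot, other)))
            sn = {}
            for ch in channels:
                strain = channel_strain[ch]
                mu = base * weights[k]
                if strain != "ROCK":
                    mu *= 2.0 ** protein_lfc.get(prot, {}).get(f"{strain}/ROCK", 0.0)
                noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
                sn[ch] = round(mu * noise, 4)
            psms.append(PSMRecord(peptide, candidates, sn))
    return psms, channels, channel_strain


def simulate_congenic_design(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset described in the module docstring."""
    rng = np.random.default_rng(config.seed)
    lengths = dict(config.chromosome_lengths)

    genome = _random_genome(lengths, rng)
    genes = _place_genes(config, rng)
    regulated, stabilized, h1_cyps, switch_id = _assign_classes(genes, config, rng)
    by_id = {g.gene_id: g for g in genes}

    # planted non-synonymous resistance SNPs: causal switch + H1 CYPs
    planted_nonsyn: dict[str, tuple[str, int, str, str]] = {}
    targets = ([switch_id] if switch_id else []) + h1_cyps
    for gid in targets:
        planted = _plant_nonsyn_snp(by_id[gid], genome, rng)
        if planted is not None:
            pos, ref, alt = planted
            planted_nonsyn[gid] = (by_id[gid].chrom, pos, ref, alt)

    variants, site_patterns = _simulate_variants(config, genome, genes, planted_nonsyn, rng)

    transcript_lfc: dict[str, dict[str, float]] = {}
    protein_lfc: dict[str, dict[str, float]] = {}
    for gid in regulated:
        transcript_lfc[gid] = {c: config.planted_log2fc for c in COMPARISONS}
        protein_lfc[gid] = {
            c: config.planted_log2fc * config.protein_concordance for c in COMPARISONS
        }
    for gid in stabilized:
        transcript_lfc[gid] = {c: 0.0 for c in COMPARISONS}
        protein_lfc[gid] = {c: config.planted_log2fc for c in COMPARISONS}
    if switch_id is not None:
        transcript_lfc[switch_id] = {c: config.planted_log2fc for c in COMPARISONS}
        protein_lfc[switch_id] = {
            c: config.planted_log2fc * config.protein_concordance for c in COMPARISONS
        }

    counts = _simulate_counts(config, genes, transcript_lfc, rng)

    # proteins: all CYPs and the switch are detected; a random fraction of
    # the rest; plus a few proteins with no annotated gene
    detected = [
        g.gene_id
        for g in genes
        if g.gene_class == "CYP"
        or g.gene_id == switch_id
        or rng.random() < config.protein_detect_fraction
    ]
    unannotated = [f"XP_SYN{i + 1:04d}" for i in range(config.n_unannotated_proteins)]
    psms, channels, channel_strain = _simulate_psms(
        config, detected + unannotated, protein_lfc, rng
    )

    truth = TruthRecord(
        introgressed_blocks=[tuple(b) for b in config.introgressed_blocks],
        causal_locus=config.causal_locus,
        switch_id=switch_id,
        regulated_cyp_ids=sorted(regulated),
        stabilized_cyp_ids=sorted(stabilized),
        h1_cyp_ids=sorted(h1_cyps),
        transcript_log2fc=transcript_lfc,
        protein_log2fc=protein_lfc,
        site_patterns=site_patterns,
        protein_detected_ids=sorted(detected),
        unannotated_protein_ids=unannotated,
        sample_strain=dict(counts.sample_strain),
        channel_strain=channel_strain,
    )
    return SyntheticDataset(config, genome, genes, variants, counts, psms, channels, truth)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as VCF, GFF3, FASTA (genome + transcripts),
    counts TSV, PSM TSV and a truth JSON; all files round-trip through
    the package's readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": cio.write_vcf(dataset.variants, dataset.chrom_lengths, out / "variants.vcf"),
        "gff3": write_gff3(dataset.genes, out / "annotation.gff3"),
        "genome": cio.write_fasta(dataset.genome, out / "genome.fa"),
        "transcripts": cio.write_fasta(dataset.transcript_sequences(), out / "transcripts.fa"),
        "counts": cio.write_counts(dataset.counts, out / "counts.tsv"),
        "psms": cio.write_psms(dataset.psms, dataset.channels, out / "psms.tsv"),
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    truth_dict = dataclasses.asdict(dataset.truth)
    paths["truth"].write_text(json.dumps(truth_dict, indent=1))
    paths["config"].write_text(json.dumps(dataclasses.asdict(dataset.config), indent=1))
    return paths


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["chromosome_lengths"] = tuple((c, int(n)) for c, n in d["chromosome_lengths"])
    d["introgressed_blocks"] = tuple((c, int(s), int(e)) for c, s, e in d["introgressed_blocks"])
    if d.get("causal_locus") is not None:
        c, s, e = d["causal_locus"]
        d["causal_locus"] = (c, int(s), int(e))
    d["nb_mean_log_range"] = tuple(d["nb_mean_log_range"])
    return SimulationConfig(**d)


def load_dataset(out_dir: str | Path) -> SyntheticDataset:
    """Reconstruct a written dataset through the package's own readers."""
    out = Path(out_dir)
    config = _config_from_dict(json.loads((out / "config.json").read_text()))
    truth_raw = json.loads((out / "truth.json").read_text())
    truth_raw["introgressed_blocks"] = [tuple(b) for b in truth_raw["introgressed_blocks"]]
    if truth_raw.get("causal_locus") is not None:
        truth_raw["causal_locus"] = tuple(truth_raw["causal_locus"])
    truth = TruthRecord(**truth_raw)
    counts = cio.read_counts(out / "counts.tsv", truth.sample_strain)
    psms, channels = cio.read_psms(out / "psms.tsv")
    return SyntheticDataset(
        config=config,
        genome=cio.read_fasta(out / "genome.fa"),
        genes=read_gff3(out / "annotation.gff3"),
        variants=cio.read_vcf(out / "variants.vcf"),
        counts=counts,
        psms=psms,
        channels=channels,
        truth=truth,
    )
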