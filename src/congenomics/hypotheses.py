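"""Six-hypothesis candidate classification, CYP cluster detection, locus
filtering and candidate consolidation.

Six mechanistic hypotheses for CYP-mediated pyrethroid resistance are
evaluated against joined transcript/protein evidence and resistance-
associated SNP annotations:

  H1  non-synonymous resistance SNP in a CYP (enzyme with a faster
      detoxification rate; no expression change required)
  H2  CYP up-regulated at both transcript and protein level in both
      resistant strains (cis promoter mutation)
  H3  same expression signature as H2, interpreted as gene duplication
      (possibly of a tight CYP cluster); shares membership with H2
  H4  non-synonymous resistance SNP in a "switch" (transcription factor
      or lncRNA regulator of CYPs)
  H5  switch with altered transcript expression (up or down — both
      enhancers and repressors matter) in both resistant strains
  H6  CYP up-regulated as protein in both strains but not as transcript
      in both — protein stabilisation

Candidates whose genomic position falls inside a mapped resistance locus
survive locus filtering; H3 (duplications are invisible to a SNP density
scan) and H6 (the stabilising factor, not the CYP itself, is the mapped
entity) are exempt, and genes on unplaced scaffolds cannot be filtered
and are retained with a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .annotation import Gene
from .integration import JoinedRecord
from .locus import LocusInterval
from .variants import VariantSite

HYPOTHESES = ("H1", "H2", "H3", "H4", "H5", "H6")
SWITCH_CLASSES = ("TF", "lncRNA")

# locus-filter status vocabulary
UNFILTERED = "unfiltered"
PASSED = "pass"
FAILED = "fail"
EXEMPT = "exempt"
UNFILTERABLE = "unfilterable"  # unplaced scaffold: retained, flagged


@dataclass
class Thresholds:
    transcript_lfc: float = 1.0
    transcript_fdr: float = 0.01
    protein_p: float = 0.05
    window_size: int = 10_000_000
    locus_seed_count: int = 100
    cluster_max_gap: int = 100_000

    def __post_init__(self) -> None:
        for name in ("transcript_lfc", "transcript_fdr", "protein_p", "window_size",
                     "locus_seed_count", "cluster_max_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Thresholds.{name} must be positive")


@dataclass
class CandidateGene:
    gene_id: str
    gene_class: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    filter_status: str = UNFILTERED
    notes: str = ""


@dataclass
class CandidateSet:
    hypothesis: str
    genes: list[CandidateGene] = field(default_factory=list)
    accession_only: list[str] = field(default_factory=list)  # protein-only entries with no gene id
    provenance: str = ""

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def surviving(self) -> list[CandidateGene]:
        return [g for g in self.genes if g.filter_status in (UNFILTERED, PASSED, EXEMPT, UNFILTERABLE)]


def _up_in_both(rec: JoinedRecord, layer: str, comparisons: tuple[str, str]) -> bool:
    results = getattr(rec, layer)
    return all(c in results and results[c].call == "up" for c in comparisons)


def _altered_in_both(rec: JoinedRecord, comparisons: tuple[str, str]) -> bool:
    t = rec.transcript
    if not all(c in t for c in comparisons):
        return False
    calls = {t[c].call for c in comparisons}
    return calls == {"up"} or calls == {"down"}


def _candidate(rec: JoinedRecord, notes: str = "") -> CandidateGene:
    return CandidateGene(
        gene_id=rec.gene_id,
        gene_class=rec.gene_class or "other",
        chrom=rec.chrom,
        start=rec.start,
        end=rec.end,
        notes=notes,
    )


def classify_candidates(
    joined: list[JoinedRecord],
    resistance_snps: list[VariantSite],
    gene_catalog: dict[str, Gene] | None = None,
    thresholds: Thresholds | None = None,
    comparisons: tuple[str, str] = ("SP/ROCK", "CKR/ROCK"),
) -> dict[str, CandidateSet]:
    """Assign genes to hypothesis sets per the rules above.

    ``resistance_snps`` must carry effect annotations; the expression
    calls embedded in ``joined`` already encode the numeric thresholds,
    which are recorded in each set's provenance.
    """
    thresholds = thresholds or Thresholds()
    catalog = gene_catalog or {}
    sets = {h: CandidateSet(h) for h in HYPOTHESES}
    prov = (
        f"transcript: |log2FC|>={thresholds.transcript_lfc}, FDR<={thresholds.transcript_fdr}; "
        f"protein: p<={thresholds.protein_p}; comparisons: {', '.join(comparisons)}"
    )
    for s in sets.values():
        s.provenance = prov

    nonsyn_genes = {
        s.effect.gene_id
        for s in resistance_snps
        if s.effect is not None and s.effect.category == "non_synonymous" and s.effect.gene_id
    }

    by_gene = {r.gene_id: r for r in joined if r.gene_id is not None}

    # SNP-driven hypotheses (H1, H4): membership comes from the annotation,
    # not from expression, so genes absent from the joined table still count.
    for gene_id in sorted(nonsyn_genes):
        if gene_id in by_gene:
            rec = by_gene[gene_id]
            gene_class = rec.gene_class
        elif gene_id in catalog:
            g = catalog[gene_id]
            rec = JoinedRecord(gene_id=gene_id, gene_class=g.gene_class,
                               chrom=g.chrom, start=g.start, end=g.end)
            gene_class = g.gene_class
        else:
            warnings.warn(f"gene {gene_id} has a non-synonymous resistance SNP but no "
                          "annotation record; skipped", stacklevel=2)
            continue
        if gene_class == "CYP":
            changed = any(res.call != "ns" for res in rec.transcript.values()) or any(
                res.call != "ns" for res in rec.protein.values()
            )
            sets["H1"].genes.append(
                _candidate(rec, notes="expression_changed" if changed else "no_expression_change")
            )
        elif gene_class in SWITCH_CLASSES:
            sets["H4"].genes.append(_candidate(rec))

    for rec in joined:
        if rec.gene_id is None:
            # accession-only protein entries can still show the stabilisation
            # signature, but without a gene id they are reported separately
            if rec.gene_class == "CYP" and _up_in_both(rec, "protein", comparisons):
                sets["H6"].accession_only.append(rec.accession)
            continue
        if rec.gene_class is None:
            warnings.warn(f"gene {rec.gene_id} has no gene_class; skipped", stacklevel=2)
            continue
        if rec.gene_class == "CYP":
            transcript_up = _up_in_both(rec, "transcript", comparisons)
            protein_up = _up_in_both(rec, "protein", comparisons)
            if transcript_up and protein_up:
                cand = _candidate(rec)
                sets["H2"].genes.append(cand)
                sets["H3"].genes.append(replace(cand))
            elif protein_up and rec.layer_presence == "both" and not transcript_up:
                sets["H6"].genes.append(_candidate(rec, notes="protein_only_up"))
        elif rec.gene_class in SWITCH_CLASSES:
            if _altered_in_both(rec, comparisons):
                sets["H5"].genes.append(_candidate(rec))

    for s in sets.values():
        s.genes.sort(key=lambda g: (g.chrom or "", g.start if g.start is not None else -1, g.gene_id))
    return sets


def detect_cyp_clusters(
    candidates: list[CandidateGene] | CandidateSet,
    max_gap: int = 100_000,
) -> list[list[str]]:
    """Single-linkage clustering of candidate CYPs along each chromosome:
    genes whose spans lie within ``max_gap`` bp of each other join one
    cluster; clusters of size >= 2 are reported in coordinate order."""
    genes = candidates.genes if isinstance(candidates, CandidateSet) else candidates
    placed = [g for g in genes if g.chrom is not None and g.start is not None]
    clusters: list[list[str]] = []
    by_chrom: dict[str, list[CandidateGene]] = {}
    for g in sorted(placed, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        run = [by_chrom[chrom][0]]
        for g in by_chrom[chrom][1:]:
            if g.start - run[-1].end <= max_gap:
                run.append(g)
            else:
                if len(run) >= 2:
                    clusters.append([x.gene_id for x in run])
                run = [g]
        if len(run) >= 2:
            clusters.append([x.gene_id for x in run])
    return clusters


def filter_by_loci(
    candidate_sets: dict[str, CandidateSet],
    loci: list[LocusInterval],
    placed_chromosomes: set[str] | None = None,
) -> dict[str, CandidateSet]:
    """Flag every candidate against the mapped resistance loci.

    A gene passes when its span intersects any locus.  H3 and H6 members
    are exempt and pass unconditionally; genes on chromosomes outside
    ``placed_chromosomes`` (when given) are unplaced-scaffold entries
    that cannot be filtered and are retained with a flag.
    """
    out: dict[str, CandidateSet] = {}
    for h, cset in candidate_sets.items():
        new = CandidateSet(h, [], list(cset.accession_only), cset.provenance)
        for g in cset.genes:
            g = replace(g)
            if h in ("H3", "H6"):
                g.filter_status = EXEMPT
            elif placed_chromosomes is not None and g.chrom is not None and g.chrom not in placed_chromosomes:
                g.filter_status = UNFILTERABLE
            else:
                if g.chrom is None or g.start is None or g.end is None:
                    raise ValueError(
                        f"gene {g.gene_id}: no coordinates and not on an unplaced scaffold"
                    )
                hit = any(lc.overlaps(g.chrom, g.start, g.end) for lc in loci)
                g.filter_status = PASSED if hit else FAILED
            new.genes.append(g)
        out[h] = new
    return out


@dataclass
class Consolidation:
    stage: str  # pre_filter / post_filter
    per_hypothesis: dict[str, int]
    union_ids: list[str]
    switch_union_ids: list[str]  # H4 | H5

    @property
    def union_size(self) -> int:
        return len(self.union_ids)

    @property
    def switch_union_size(self) -> int:
        return len(self.switch_union_ids)


def consolidate(candidate_sets: dict[str, CandidateSet], stage: str = "pre_filter") -> Consolidation:
    """Deduplicated union of all hypothesis sets (gene ids), with
    per-hypothesis counts and the H4|H5 "switch" union reported.  For
    ``post_filter``, only genes whose flag is pass/exempt/unfilterable
    survive."""
    if stage not in ("pre_filter", "post_filter"):
        raise ValueError("stage must be 'pre_filter' or 'post_filter'")

    def members(h: str) -> list[CandidateGene]:
        cset = candidate_sets[h]
        if stage == "pre_filter":
            return list(cset.genes)
        return cset.surviving()

    per_h: dict[str, int] = {}
    seen: dict[str, CandidateGene] = {}
    switch: dict[str, CandidateGene] = {}
    for h in HYPOTHESES:
        if h not in candidate_sets:
            per_h[h] = 0
            continue
        mem = members(h)
        per_h[h] = len(mem)
        for g in mem:
            seen.setdefault(g.gene_id, g)
            if h in ("H4", "H5"):
                switch.setdefault(g.gene_id, g)

    def order(genes: dict[str, CandidateGene]) -> list[str]:
        return [
            g.gene_id
            for g in sorted(
                genes.values(),
                key=lambda g: (g.chrom or "~", g.start if g.start is not None else -1, g.gene_id),
            )
        ]

    return Consolidation(stage, per_h, order(seen), order(switch))
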