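"""Joining transcript- and protein-level results and quantifying their
concordance.

Gene-level differential-expression records and protein quantification
records are merged into one row per gene (full outer join), tracking
whether each gene was measured in both layers or only one.  Concordance
between layers is summarised by the Pearson correlation of log2
fold-changes over genes quantified in both layers — by construction an
optimistic convention, since discordant absences are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .annotation import Gene
from .diffexpr import DERecord
from .proteomics import ProteinQuantRecord


@dataclass
class LayerResult:
    log2fc: float
    call: str


@dataclass
class JoinedRecord:
    gene_id: str | None  # None for proteins with no annotated gene
    accession: str | None = None  # carries the protein id when gene_id is None
    gene_class: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    transcript: dict[str, LayerResult] = field(default_factory=dict)  # comparison -> result
    protein: dict[str, LayerResult] = field(default_factory=dict)

    @property
    def layer_presence(self) -> str:
        if self.transcript and self.protein:
            return "both"
        if self.transcript:
            return "transcript_only"
        return "protein_only"

    @property
    def key(self) -> str:
        return self.gene_id if self.gene_id is not None else f"accession:{self.accession}"


@dataclass
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    n: int
    defined: bool = True


def join_layers(
    de_records: list[DERecord],
    protein_records: list[ProteinQuantRecord],
    id_map: dict[str, str | None],
    gene_catalog: dict[str, Gene] | None = None,
) -> list[JoinedRecord]:
    """Full outer join of the two layers on gene id.

    ``id_map`` resolves protein ids to gene ids; a protein mapping to
    ``None`` is retained as a protein-only record under its accession.
    Duplicate gene ids within one layer and comparison are rejected.
    """
    joined: dict[str, JoinedRecord] = {}

    def get(key: str, gene_id: str | None, accession: str | None) -> JoinedRecord:
        if key not in joined:
            rec = JoinedRecord(gene_id=gene_id, accession=accession)
            if gene_id and gene_catalog and gene_id in gene_catalog:
                g = gene_catalog[gene_id]
                rec.gene_class, rec.chrom, rec.start, rec.end = g.gene_class, g.chrom, g.start, g.end
            joined[key] = rec
        return joined[key]

    seen_t: set[tuple[str, str]] = set()
    for r in de_records:
        if (r.gene_id, r.comparison) in seen_t:
            raise ValueError(f"duplicate transcript record for gene {r.gene_id} ({r.comparison})")
        seen_t.add((r.gene_id, r.comparison))
        rec = get(r.gene_id, r.gene_id, None)
        rec.transcript[r.comparison] = LayerResult(r.log2fc, r.call)

    seen_p: set[tuple[str, str]] = set()
    for pr in protein_records:
        gene_id = id_map.get(pr.protein_id, pr.protein_id)
        key = gene_id if gene_id is not None else f"accession:{pr.protein_id}"
        for comp, res in pr.comparisons.items():
            if (key, comp) in seen_p:
                raise ValueError(f"duplicate protein record for {key} ({comp})")
            seen_p.add((key, comp))
            rec = get(key, gene_id, pr.protein_id if gene_id is None else None)
            rec.protein[comp] = LayerResult(res.log2_ratio, res.call)

    return list(joined.values())


def presence_counts(joined: list[JoinedRecord]) -> dict[str, int]:
    out = {"both": 0, "transcript_only": 0, "protein_only": 0}
    for r in joined:
        out[r.layer_presence] += 1
    return out


def pearson_logfc(
    joined: list[JoinedRecord],
    comparison: str,
    subset_filter=None,
) -> CorrelationResult:
    """Pearson correlation (and least-squares line) of transcript vs
    protein log2 fold-changes for one comparison, over genes quantified
    in both layers (optionally restricted by ``subset_filter``)."""
    pairs = [
        (r.transcript[comparison].log2fc, r.protein[comparison].log2fc)
        for r in joined
        if comparison in r.transcript
        and comparison in r.protein
        and (subset_filter is None or subset_filter(r))
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 genes with both layers, got {len(pairs)}")
    x = pd.Series([p[0] for p in pairs])
    y = pd.Series([p[1] for p in pairs])
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"), len(pairs), False)
    r, _ = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(float(r), float(fit.slope), float(fit.intercept), len(pairs))


def resolution_gain(n_single: float, n_both: float) -> float:
    """Fold increase in mapping resolution from intersecting evidence:
    the ratio of candidates from one strain alone to candidates shared
    across strains (fewer shared candidates = sharper resolution)."""
    if n_both <= 0:
        raise ValueError("shared candidate count must be > 0")
    return n_single / n_both


def joined_table(joined: list[JoinedRecord]) -> pd.DataFrame:
    rows = []
    for r in joined:
        row: dict[str, object] = {
            "gene": r.key,
            "gene_class": r.gene_class,
            "chrom": r.chrom,
            "layer_presence": r.layer_presence,
        }
        for comp, res in sorted(r.transcript.items()):
            row[f"mrna_log2fc_{comp}"] = res.log2fc
            row[f"mrna_call_{comp}"] = res.call
        for comp, res in sorted(r.protein.items()):
            row[f"protein_log2fc_{comp}"] = res.log2fc
            row[f"protein_call_{comp}"] = res.call
        rows.append(row)
    return pd.DataFrame(rows)
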