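"""Packaged worked-example tables.

Three small tables transcribed from the published study accompany the
package so the candidate engine can be exercised end to end without any
raw data:

* ``cyp_expression_table.tsv`` — per-CYP log2 fold-changes (mRNA and
  protein, SP/ROCK and CKR/ROCK); a blank cell means no significant
  change.  One entry (CYP9J7) is a protein identified only under an
  external accession, with no annotated gene.
* ``candidate_table_synthetic_coords.tsv`` — the six hypothesis
  candidate lists.  The genomic coordinates in this file are SYNTHETIC
  stand-ins: the study did not print per-gene coordinates, so positions
  were constructed to be consistent with the published locus-filter
  outcomes (kept genes inside the mapped loci, dropped genes outside,
  unplaced-scaffold genes on named scaffolds) and with the published
  CYP cluster structure.  The TF/lncRNA split for switches is likewise
  an approximate reconstruction; neither affects any candidate count.
* ``resolution_table.tsv`` — candidate counts per strain comparison used
  for the fold-resolution calculation.

The mapped resistance loci (chromosome 1: 40-250 Mb and 300-310 Mb;
chromosome 3: 310-320 Mb and 330-360 Mb) are exposed as
:func:`study_resistance_loci`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .hypotheses import HYPOTHESES, CandidateGene, CandidateSet
from .integration import JoinedRecord, LayerResult
from .locus import LocusInterval

MB = 1_000_000

STUDY_CHROMOSOMES = {"1", "2", "3"}


def _read(name: str) -> pd.DataFrame:
    with resources.files("congenomics").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def study_resistance_loci() -> list[LocusInterval]:
    """The mapped resistance locus intervals from the 10 Mb window scan."""
    return [
        LocusInterval("1", 40 * MB, 250 * MB, peak_count=0, total_snps=0),
        LocusInterval("1", 300 * MB, 310 * MB, peak_count=0, total_snps=0),
        LocusInterval("3", 310 * MB, 320 * MB, peak_count=0, total_snps=0),
        LocusInterval("3", 330 * MB, 360 * MB, peak_count=0, total_snps=0),
    ]


def load_cyp_expression() -> list[JoinedRecord]:
    """The CYP expression summary as joined transcript/protein records.

    Every listed CYP was quantified in both layers except the
    accession-only entry, which was detected as protein only.  Non-blank
    cells are significant up-regulated log2 fold-changes; blank cells
    become 'ns' calls with the fold-change unavailable (0.0)."""
    df = _read("cyp_expression_table.tsv")
    records = []
    for _, row in df.iterrows():
        annotated = bool(row["annotated"])
        rec = JoinedRecord(
            gene_id=row["accession"] if annotated else None,
            accession=None if annotated else row["accession"],
            gene_class="CYP",
        )
        for comp, mrna_col, prot_col in (
            ("SP/ROCK", "mrna_sp_rock", "protein_sp_rock"),
            ("CKR/ROCK", "mrna_ckr_rock", "protein_ckr_rock"),
        ):
            if annotated:  # transcript layer quantified for all annotated genes
                if pd.notna(row[mrna_col]):
                    rec.transcript[comp] = LayerResult(float(row[mrna_col]), "up")
                else:
                    rec.transcript[comp] = LayerResult(0.0, "ns")
            if pd.notna(row[prot_col]):
                rec.protein[comp] = LayerResult(float(row[prot_col]), "up")
            else:
                rec.protein[comp] = LayerResult(0.0, "ns")
        records.append(rec)
    return records


def load_candidate_sets() -> dict[str, CandidateSet]:
    """The published pre-filter candidate sets, ready for locus filtering
    and consolidation.  The stabilized-CYP hypothesis additionally lists
    the accession-only protein entry separately."""
    df = _read("candidate_table_synthetic_coords.tsv")
    sets = {h: CandidateSet(h) for h in HYPOTHESES}
    for _, row in df.iterrows():
        for h in str(row["hypotheses"]).split(","):
            sets[h].genes.append(
                CandidateGene(
                    gene_id=row["gene_id"],
                    gene_class=row["gene_class"],
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
    sets["H6"].accession_only.append("EAT33129.1")
    for s in sets.values():
        s.genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return sets


def load_resolution_table() -> pd.DataFrame:
    return _read("resolution_table.tsv")
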