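"""Gene models and GFF3 input/output.

Coordinates are stored internally as 0-based half-open intervals and
converted to the 1-based inclusive GFF3 convention only at the file
boundary.  Each gene carries a ``gene_class`` tag (``CYP``, ``TF``,
``lncRNA`` or ``other``) that downstream candidate classification relies
on; CYPs may additionally carry a conventional ``cyp_name``.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

GENE_CLASSES = ("CYP", "TF", "lncRNA", "other")


@dataclass
class Transcript:
    """One mRNA: ordered, non-overlapping exon and CDS intervals (0-based, half-open)."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            ordered = sorted(ivs)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if e1 > s2:
                    raise ValueError(
                        f"transcript {self.transcript_id}: overlapping {name} "
                        f"intervals ({s1},{e1}) and ({s2},{e2})"
                    )
            if ivs != ordered:
                ivs.sort()

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str = "other"
    cyp_name: str | None = None
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span [{self.start},{self.end})")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(
                f"gene {self.gene_id}: gene_class {self.gene_class!r} not in {GENE_CLASSES}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def write_gff3(genes: list[Gene], path: str | Path) -> Path:
    """Write gene/mRNA/exon/CDS features with ID/Parent/gene_class attributes."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};gene_class={g.gene_class}"
        if g.cyp_name:
            attrs += f";cyp_name={g.cyp_name}"
        lines.append(
            f"{g.chrom}\tcongenomics\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for t in g.transcripts:
            lines.append(
                f"{g.chrom}\tcongenomics\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={t.transcript_id};Parent={g.gene_id}"
            )
            for s, e in t.exons:
                lines.append(
                    f"{g.chrom}\tcongenomics\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={t.transcript_id}"
                )
            # phase is recomputed from running CDS length, 5'->3'
            cds = t.cds if g.strand == "+" else list(reversed(t.cds))
            consumed = 0
            for s, e in cds:
                phase = (3 - consumed % 3) % 3
                lines.append(
                    f"{g.chrom}\tcongenomics\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"Parent={t.transcript_id}"
                )
                consumed += e - s
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gff3(path: str | Path) -> list[Gene]:
    """Load genes (with transcript/exon/CDS structure) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = Gene(
            gene_id=gf.id,
            chrom=gf.seqid,
            start=gf.start - 1,
            end=gf.end,
            strand=gf.strand,
            gene_class=gf.attributes.get("gene_class", ["other"])[0],
            cyp_name=(gf.attributes.get("cyp_name") or [None])[0],
        )
        for mf in db.children(gf, featuretype="mRNA", order_by="start"):
            tr = Transcript(transcript_id=mf.id)
            for ef in db.children(mf, featuretype="exon", order_by="start"):
                tr.exons.append((ef.start - 1, ef.end))
            for cf in db.children(mf, featuretype="CDS", order_by="start"):
                tr.cds.append((cf.start - 1, cf.end))
            tr.exons.sort()
            tr.cds.sort()
            gene.transcripts.append(tr)
        genes.append(gene)
    return genes
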