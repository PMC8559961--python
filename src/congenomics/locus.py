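"""Windowed SNP-density locus scan.

Resistance-associated SNPs are counted in fixed, non-overlapping windows
tiling each chromosome (default 10 Mb).  Windows whose count strictly
exceeds a seed threshold (default 100 SNPs/window) are called, and runs
of adjacent supra-threshold windows are merged into one locus interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .variants import VariantSite

DEFAULT_WINDOW = 10_000_000
DEFAULT_SEED_COUNT = 100


@dataclass
class WindowCounts:
    chrom: str
    chrom_length: int
    window_size: int
    counts: list[int] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    def window_bounds(self, i: int) -> tuple[int, int]:
        """Half-open bp interval of window ``i``, clipped to the chromosome."""
        return (i * self.window_size, min((i + 1) * self.window_size, self.chrom_length))


@dataclass
class LocusInterval:
    chrom: str
    start: int
    end: int  # half-open, window aligned (end may be clipped to chrom length)
    peak_count: int
    total_snps: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"locus {self.chrom}:{self.start}-{self.end}: start must be < end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and self.start < end


def window_counts(
    snps: list[VariantSite],
    chrom_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW,
) -> list[WindowCounts]:
    """Count SNPs per half-open tiling window; each SNP lands in exactly
    one window via floor((pos-1)/window_size)."""
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    out = {
        chrom: WindowCounts(chrom, length, window_size, [0] * math.ceil(length / window_size))
        for chrom, length in chrom_lengths.items()
    }
    for s in snps:
        if s.chrom not in out:
            raise ValueError(f"SNP {s.chrom}:{s.pos}: unknown chromosome {s.chrom!r}")
        wc = out[s.chrom]
        if s.pos > wc.chrom_length:
            raise ValueError(
                f"SNP {s.chrom}:{s.pos}: position beyond chromosome length {wc.chrom_length}"
            )
        wc.counts[(s.pos - 1) // window_size] += 1
    return list(out.values())


def call_loci(
    windows: list[WindowCounts], threshold: int = DEFAULT_SEED_COUNT
) -> list[LocusInterval]:
    """Merge runs of adjacent windows with count strictly greater than
    ``threshold`` into locus intervals (a window exactly at the threshold
    is not a seed)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    loci: list[LocusInterval] = []
    for wc in windows:
        run: list[int] = []
        for i, n in enumerate(list(wc.counts) + [0]):  # sentinel closes a trailing run
            if i < wc.n_windows and n > threshold:
                run.append(i)
                continue
            if run:
                start = run[0] * wc.window_size
                end = min((run[-1] + 1) * wc.window_size, wc.chrom_length)
                sub = wc.counts[run[0] : run[-1] + 1]
                loci.append(LocusInterval(wc.chrom, start, end, max(sub), sum(sub)))
                run = []
    return loci


def write_window_tsv(windows: list[WindowCounts], path: str | Path) -> Path:
    path = Path(path)
    lines = ["chrom\twindow_start\twindow_end\tcount"]
    for wc in windows:
        for i, n in enumerate(wc.counts):
            s, e = wc.window_bounds(i)
            lines.append(f"{wc.chrom}\t{s}\t{e}\t{n}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_loci_bed(loci: list[LocusInterval], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{lc.chrom}\t{lc.start}\t{lc.end}\tlocus_{i + 1}\t{lc.total_snps}"
        for i, lc in enumerate(loci)
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
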