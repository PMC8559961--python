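"""TMT reporter-ion quantification: PSM-to-protein rollup and testing.

Peptide-spectrum matches carry per-channel signal-to-noise (S/N) values.
Shared peptides are resolved by the razor rule (assigned to the candidate
protein with the most distinct peptides, ties broken by smallest protein
id), S/N is summed per protein per channel, channels are normalised to a
common total peptide amount, and two-group differences are tested with a
two-sided t-test on log2 abundances at p <= 0.05 (no multiple-testing
correction by default, matching the raw per-protein significance rule;
BH adjustment can be switched on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

PROTEIN_P_THRESHOLD = 0.05


@dataclass
class PSMRecord:
    peptide: str
    proteins: tuple[str, ...]
    sn: dict[str, float]  # channel -> signal/noise

    def __post_init__(self) -> None:
        if len(self.proteins) < 1:
            raise ValueError(f"PSM {self.peptide!r}: empty candidate protein list")
        neg = {ch: v for ch, v in self.sn.items() if v < 0}
        if neg:
            raise ValueError(f"PSM {self.peptide!r}: negative S/N values {neg}")


@dataclass
class ComparisonResult:
    log2_ratio: float
    pvalue: float
    call: str  # up / down / ns


@dataclass
class ProteinQuantRecord:
    protein_id: str
    abundance: dict[str, float]  # per-channel summed S/N
    normalized: dict[str, float] | None = None
    n_peptides: int = 0
    n_unique_peptides: int = 0
    comparisons: dict[str, ComparisonResult] = field(default_factory=dict)


def assign_razor(psms: list[PSMRecord]) -> list[PSMRecord]:
    """Resolve shared peptides to a single protein each.

    A protein's score is its number of distinct candidate peptides over
    the whole table; each shared peptide goes to the highest-scoring
    candidate, ties to the lexicographically smallest id.  Deterministic
    and independent of input order.
    """
    peptides_per_protein: dict[str, set[str]] = {}
    for psm in psms:
        for prot in psm.proteins:
            peptides_per_protein.setdefault(prot, set()).add(psm.peptide)
    out = []
    for psm in psms:
        winner = min(psm.proteins, key=lambda p: (-len(peptides_per_protein[p]), p))
        out.append(PSMRecord(psm.peptide, (winner,), dict(psm.sn)))
    return out


def rollup(psms: list[PSMRecord]) -> list[ProteinQuantRecord]:
    """Sum S/N per protein per channel.  Channel totals are conserved:
    the summed abundance over proteins equals the summed PSM S/N."""
    by_protein: dict[str, list[PSMRecord]] = {}
    for psm in psms:
        if len(psm.proteins) != 1:
            raise ValueError(f"PSM {psm.peptide!r}: run assign_razor first")
        by_protein.setdefault(psm.proteins[0], []).append(psm)
    records = []
    for prot in sorted(by_protein):
        group = by_protein[prot]
        channels: dict[str, float] = {}
        for psm in group:
            for ch, v in psm.sn.items():
                channels[ch] = channels.get(ch, 0.0) + v
        peptides = {p.peptide for p in group}
        records.append(
            ProteinQuantRecord(
                protein_id=prot,
                abundance=channels,
                n_peptides=len(peptides),
                n_unique_peptides=len(peptides),  # post-razor every peptide is uniquely assigned
            )
        )
    return records


def normalize_total(records: list[ProteinQuantRecord]) -> list[ProteinQuantRecord]:
    """Normalise on total peptide amount: every channel is scaled so its
    total equals the mean raw channel total.  Within-channel ratios are
    unchanged and the operation is idempotent."""
    channels = sorted({ch for r in records for ch in r.abundance})
    totals = {ch: sum(r.abundance.get(ch, 0.0) for r in records) for ch in channels}
    zero = [ch for ch, t in totals.items() if t == 0]
    if zero:
        raise ValueError(f"zero-total channel(s): {zero}")
    target = float(np.mean(list(totals.values())))
    out = []
    for r in records:
        norm = {ch: v * target / totals[ch] for ch, v in r.abundance.items()}
        out.append(
            ProteinQuantRecord(
                r.protein_id, dict(r.abundance), norm, r.n_peptides,
                r.n_unique_peptides, dict(r.comparisons),
            )
        )
    return out


def test_protein_de(
    records: list[ProteinQuantRecord],
    channel_strain: dict[str, str],
    strain_a: str,
    strain_b: str,
    p_threshold: float = PROTEIN_P_THRESHOLD,
    adjust: bool = False,
) -> list[ProteinQuantRecord]:
    """Two-sided two-sample t-test on log2(normalised abundance + 1)
    between the channels of two strains; the log2 ratio of group means is
    reported with positive values meaning higher in ``strain_a``."""
    chan_a = sorted(ch for ch, s in channel_strain.items() if s == strain_a)
    chan_b = sorted(ch for ch, s in channel_strain.items() if s == strain_b)
    if len(chan_a) < 2 or len(chan_b) < 2:
        raise ValueError(
            f"need >= 2 channels per strain, got {strain_a}:{len(chan_a)}, "
            f"{strain_b}:{len(chan_b)}"
        )
    comparison = f"{strain_a}/{strain_b}"
    ratios, pvals = [], []
    for r in records:
        if r.normalized is None:
            raise ValueError(f"protein {r.protein_id}: normalise before testing")
        a = np.array([r.normalized.get(ch, 0.0) for ch in chan_a])
        b = np.array([r.normalized.get(ch, 0.0) for ch in chan_b])
        ratios.append(float(np.log2(a.mean() + 0.5) - np.log2(b.mean() + 0.5)))
        la, lb = np.log2(a + 1), np.log2(b + 1)
        if np.allclose(la.std(), 0) and np.allclose(lb.std(), 0):
            pvals.append(1.0 if np.isclose(la.mean(), lb.mean()) else 0.0)
        else:
            pvals.append(float(stats.ttest_ind(la, lb, equal_var=True).pvalue))
    crit = bh_adjust(pvals) if adjust else np.asarray(pvals)
    for r, ratio, p, c in zip(records, ratios, pvals, crit):
        if c <= p_threshold and ratio > 0:
            call = "up"
        elif c <= p_threshold and ratio < 0:
            call = "down"
        else:
            call = "ns"
        r.comparisons[comparison] = ComparisonResult(ratio, p, call)
    return records


def protein_table(records: list[ProteinQuantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "protein": r.protein_id,
            "n_peptides": r.n_peptides,
        }
        for ch, v in sorted(r.abundance.items()):
            row[f"raw_{ch}"] = v
        if r.normalized:
            for ch, v in sorted(r.normalized.items()):
                row[f"norm_{ch}"] = v
        for comp, res in sorted(r.comparisons.items()):
            row[f"log2_ratio_{comp}"] = res.log2_ratio
            row[f"pvalue_{comp}"] = res.pvalue
            row[f"call_{comp}"] = res.call
        rows.append(row)
    return pd.DataFrame(rows)
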