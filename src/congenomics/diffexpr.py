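"""Gene-level differential expression for two-group strain comparisons.

The workflow mirrors the standard count-based RNA-seq analysis: genes are
kept when their counts-per-million exceed 1 in at least 4 samples (and
are non-zero in each compared strain), between-sample scaling uses the
trimmed mean of M-values (TMM), and testing uses a negative-binomial
exact test conditional on group totals, with a common dispersion shared
across genes shrunk toward per-gene (tagwise) estimates by weighted
conditional likelihood.  P-values are adjusted with Benjamini-Hochberg,
and a gene is called differentially expressed when |log2FC| >= 1 and
FDR <= 0.01.

The dispersion model, in brief: counts are NB(mu, phi) with
Var = mu + phi*mu^2.  After scaling all samples to a common effective
library size, the conditional likelihood of phi given the group totals
is maximised — jointly over genes for the common value, and per gene
with a prior weight on the shared likelihood for the tagwise values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.01


@dataclass
class CountMatrix:
    """Genes x samples raw counts with a sample -> strain map."""

    counts: pd.DataFrame  # integer counts, index = gene ids, columns = sample ids
    sample_strain: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        unmapped = set(self.counts.columns) - set(self.sample_strain)
        if unmapped:
            raise ValueError(f"samples without a strain mapping: {sorted(unmapped)}")

    def samples_for(self, strain: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_strain[s] == strain]

    def subset_strains(self, strains: list[str]) -> "CountMatrix":
        cols = [s for s in self.counts.columns if self.sample_strain[s] in strains]
        return CountMatrix(self.counts[cols], {s: self.sample_strain[s] for s in cols})

    def subset_genes(self, genes: pd.Index) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], dict(self.sample_strain))


@dataclass
class DERecord:
    gene_id: str
    comparison: str  # "A/B": positive log2fc means higher in A
    log2fc: float
    pvalue: float
    fdr: float
    call: str  # up / down / ns


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each sample column scaled to sum to 1e6."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return mat * 1e6 / totals


def filter_genes(
    counts: CountMatrix,
    cpm_min: float = 1.0,
    min_samples: int = 4,
    strains: list[str] | None = None,
) -> CountMatrix:
    """Expression filter ahead of testing.

    Keeps genes with CPM > ``cpm_min`` in at least ``min_samples`` of the
    compared samples, and with a non-zero count total in every strain
    present (a gene silent in one whole strain is dropped).
    """
    cm = counts.subset_strains(strains) if strains else counts
    if min_samples > cm.counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples {cm.counts.shape[1]}"
        )
    keep = (cpm(cm) > cpm_min).sum(axis=1) >= min_samples
    for strain in sorted(set(cm.sample_strain.values())):
        keep &= cm.counts[cm.samples_for(strain)].sum(axis=1) > 0
    return cm.subset_genes(cm.counts.index[keep])


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed mean of M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count rate is
    closest to the mean upper quartile.  For every other sample, log
    ratios (M) and average log intensities (A) against the reference are
    computed over genes expressed in both, doubly trimmed (30% on M, 5%
    on A), and averaged with inverse delta-method variance weights.
    """
    mat = (counts.counts if isinstance(counts, CountMatrix) else counts).astype(float)
    if (mat.sum(axis=1) == 0).any():
        raise ValueError("all-zero gene rows present; run filter_genes first")
    lib = mat.sum(axis=0)
    rate = mat / lib
    uq = rate.apply(lambda col: np.quantile(col[col > 0], 0.75), axis=0)
    ref = (uq - uq.mean()).abs().idxmin()

    factors = {}
    for sample in mat.columns:
        if sample == ref:
            factors[sample] = 1.0
            continue
        y_k, y_r = mat[sample].values, mat[ref].values
        n_k, n_r = lib[sample], lib[ref]
        ok = (y_k > 0) & (y_r > 0)
        yk, yr = y_k[ok], y_r[ok]
        m = np.log2((yk / n_k) / (yr / n_r))
        a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
        w = (n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr)
        if len(m) == 0 or np.allclose(m, m[0]):
            # degenerate: all ratios identical (e.g. exact scalar multiple)
            factors[sample] = float(2 ** (m[0] if len(m) else 0.0))
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            factors[sample] = 1.0
            continue
        wt = 1.0 / w[keep]
        factors[sample] = float(2 ** (np.sum(wt * m[keep]) / np.sum(wt)))

    f = pd.Series(factors)[mat.columns]
    f /= np.exp(np.mean(np.log(f)))
    return f


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# NB dispersion estimation by conditional likelihood on equalised libraries
# ---------------------------------------------------------------------------

def _group_cond_loglik(y: np.ndarray, r: float) -> np.ndarray:
    """Conditional NB log-likelihood of dispersion (r = 1/phi) given the
    group total, for equal library sizes.  y: genes x samples."""
    n = y.shape[1]
    z = y.sum(axis=1)
    return (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )


def _cond_loglik(groups: list[np.ndarray], phi: float) -> np.ndarray:
    r = 1.0 / phi
    total = None
    for y in groups:
        ll = _group_cond_loglik(y, r)
        total = ll if total is None else total + ll
    return total


def estimate_common_dispersion(groups: list[np.ndarray]) -> float:
    """Maximise the summed conditional log-likelihood over genes."""

    def neg(log_phi: float) -> float:
        return -float(_cond_loglik(groups, np.exp(log_phi)).sum())

    res = minimize_scalar(neg, bounds=(np.log(1e-6), np.log(5.0)), method="bounded")
    return float(np.exp(res.x))


def estimate_tagwise_dispersion(
    groups: list[np.ndarray], common: float, prior_df: float = 10.0
) -> np.ndarray:
    """Per-gene dispersions from weighted conditional likelihood: each
    gene's own likelihood plus ``prior_df/residual_df`` times the average
    likelihood across genes, maximised on a log-spaced grid around the
    common value."""
    resid_df = sum(y.shape[1] - 1 for y in groups)
    weight = prior_df / max(resid_df, 1)
    grid = common * 2.0 ** np.linspace(-8, 8, 33)
    ll = np.stack([_cond_loglik(groups, phi) for phi in grid], axis=1)  # genes x grid
    shared = ll.mean(axis=0)
    score = ll + weight * shared  # own likelihood plus prior-weighted shared likelihood
    best = np.argmax(score, axis=1)
    return grid[best]


def _exact_nb_pvalue(z_a: float, n_a: int, n_b: int, z: float, phi: float) -> float:
    """Exact two-sided NB test of group A total vs group B total,
    conditional on the overall total z, at equal per-sample means.

    The sum of n iid NB(mu, phi) draws is NB with size n/phi and mean
    n*mu; the conditional distribution of the group-A total given z is
    the normalised product of the two pmfs.  The p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    z = int(round(z))
    z_a = int(round(z_a))
    if z == 0:
        return 1.0
    mu = z / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    p_a = r_a / (r_a + n_a * mu)
    p_b = r_b / (r_b + n_b * mu)
    x = np.arange(z + 1)
    logf = (
        gammaln(x + r_a) - gammaln(x + 1) - gammaln(r_a) + r_a * np.log(p_a) + x * np.log1p(-p_a)
        + gammaln(z - x + r_b) - gammaln(z - x + 1) - gammaln(r_b)
        + r_b * np.log(p_b) + (z - x) * np.log1p(-p_b)
    )
    prob = np.exp(logf - logf.max())
    prob /= prob.sum()
    obs = prob[z_a]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-10)].sum()))


def test_de(
    counts: CountMatrix,
    strain_a: str,
    strain_b: str,
    lfc_threshold: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    prior_df: float = 10.0,
) -> list[DERecord]:
    """Two-group NB exact test between ``strain_a`` and ``strain_b``.

    Positive log2 fold-changes mean higher expression in ``strain_a``
    (by convention the first-named, resistant strain).  Fold-changes are
    computed from TMM-normalised means with a 0.5 pseudo-count guard;
    testing itself uses the integer pseudo-counts without the guard.
    """
    cm = counts.subset_strains([strain_a, strain_b])
    samples_a, samples_b = cm.samples_for(strain_a), cm.samples_for(strain_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >= 2 replicates per strain, got {strain_a}:{len(samples_a)}, "
            f"{strain_b}:{len(samples_b)}"
        )
    mat = cm.counts.astype(float)
    factors = tmm_factors(cm)
    eff_lib = mat.sum(axis=0) * factors
    target = float(np.exp(np.mean(np.log(eff_lib))))
    pseudo = np.rint(mat * (target / eff_lib)).astype(float)

    y_a = pseudo[samples_a].values
    y_b = pseudo[samples_b].values
    groups = [y_a, y_b]
    common = estimate_common_dispersion(groups)
    tagwise = estimate_tagwise_dispersion(groups, common, prior_df=prior_df)

    z_a, z_b = y_a.sum(axis=1), y_b.sum(axis=1)
    mean_a, mean_b = y_a.mean(axis=1), y_b.mean(axis=1)
    lfc = np.log2(mean_a + 0.5) - np.log2(mean_b + 0.5)
    pvals = np.array(
        [
            _exact_nb_pvalue(za, len(samples_a), len(samples_b), za + zb, phi)
            for za, zb, phi in zip(z_a, z_b, tagwise)
        ]
    )
    fdr = bh_adjust(pvals)

    records = []
    comparison = f"{strain_a}/{strain_b}"
    for gene, l, p, q in zip(mat.index, lfc, pvals, fdr):
        if q <= fdr_threshold and l >= lfc_threshold:
            call = "up"
        elif q <= fdr_threshold and l <= -lfc_threshold:
            call = "down"
        else:
            call = "ns"
        records.append(DERecord(str(gene), comparison, float(l), float(p), float(q), call))
    return records


def de_table(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "comparison": r.comparison,
                "log2fc": r.log2fc,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "call": r.call,
            }
            for r in records
        ]
    )
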