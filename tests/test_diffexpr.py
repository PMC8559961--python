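"""CPM, expression filtering, TMM normalisation, BH and the NB exact test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from congenomics.diffexpr import (
    CountMatrix,
    bh_adjust,
    cpm,
    filter_genes,
    tmm_factors,
)
from congenomics.diffexpr import test_de as run_de


def make_cm(data, strains=("SP", "SP", "ROCK", "ROCK"), genes=None):
    arr = np.asarray(data)
    cols = [f"{s}_{i}" for i, s in enumerate(strains)]
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=cols),
                       dict(zip(cols, strains)))


class TestCpm:
    def test_single_sample_proportions(self):
        cm = make_cm([[1], [3]], strains=("SP",))
        out = cpm(cm)
        assert out.iloc[:, 0].tolist() == [250_000.0, 750_000.0]

    def test_column_conservation(self):
        rng = np.random.default_rng(0)
        cm = make_cm(rng.integers(0, 500, size=(50, 8)),
                     strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        totals = cpm(cm).sum(axis=0)
        assert np.allclose(totals, 1e6, rtol=1e-6)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        mat = rng.integers(1, 100, size=(50, 8)).astype(float)
        cm = make_cm(mat, strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        expected = mat * 1e6 / mat.sum(axis=0, keepdims=True)
        assert np.allclose(cpm(cm).values, expected)

    def test_zero_total_sample_named(self):
        cm = make_cm([[0, 5], [0, 5]], strains=("SP", "ROCK"))
        with pytest.raises(ValueError, match="SP_0"):
            cpm(cm)


class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        cm = make_cm([[0] * 8, [50] * 8], strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        kept = filter_genes(cm)
        assert list(kept.counts.index) == ["g1"]

    def test_min_sample_boundary(self):
        # library size ~1e7 per sample: count 101 -> CPM ~10 (>1),
        # count 5 -> CPM 0.5 (<=1, keeps the strain total nonzero only)
        base = np.zeros((2, 8), dtype=int)
        filler = np.full((1, 8), 10_000_000)
        mat = np.vstack([base, filler])
        mat[0, :4] = 101  # above-threshold in exactly 4 samples
        mat[1, :3] = 101  # in exactly 3 samples
        mat[0, 4] = 5
        mat[1, 4] = 5
        cm = make_cm(mat, strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        kept = filter_genes(cm, cpm_min=1, min_samples=4)
        assert "g0" in kept.counts.index and "g1" not in kept.counts.index

    def test_gene_silent_in_one_strain_removed(self):
        mat = np.full((2, 8), 100)
        mat[0, 4:] = 0  # expressed only in SP
        cm = make_cm(mat, strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        assert "g0" not in filter_genes(cm).counts.index

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        cm = make_cm(rng.integers(0, 50, size=(100, 8)),
                     strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        once = filter_genes(cm)
        twice = filter_genes(once)
        assert once.counts.equals(twice.counts)

    def test_min_samples_larger_than_samples_rejected(self):
        cm = make_cm([[5] * 4], strains=("SP", "SP", "ROCK", "ROCK"))
        with pytest.raises(ValueError):
            filter_genes(cm, min_samples=5)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=200)
        cm = make_cm(np.column_stack([col, col]), strains=("SP", "ROCK"))
        assert np.allclose(tmm_factors(cm).values, 1.0)

    def test_exact_scalar_multiple_gives_unit_factors(self):
        # doubling every count doubles the library size; M-values are all 0
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, size=200)
        cm = make_cm(np.column_stack([col, 2 * col]), strains=("SP", "ROCK"))
        f = tmm_factors(cm)
        assert np.allclose(f.values, 1.0, atol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        cm = make_cm(rng.integers(1, 1000, size=(300, 6)),
                     strains=tuple(["SP"] * 3 + ["ROCK"] * 3))
        f = tmm_factors(cm)
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-10

    def test_all_zero_rows_rejected(self):
        cm = make_cm([[0, 0], [5, 9]], strains=("SP", "ROCK"))
        with pytest.raises(ValueError):
            tmm_factors(cm)


class TestBenjaminiHochberg:
    def test_hand_oracle(self):
        adj = bh_adjust([0.001, 0.02, 0.03, 0.9])
        assert np.allclose(adj, [0.004, 0.04, 0.04, 0.9])

    @staticmethod
    def _bh_by_hand(p):
        """Independent step-up implementation."""
        p = np.asarray(p, float)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        prev = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            prev = min(prev, p[i] * n / rank_from_top)
            adj[i] = prev
        return adj

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
                    max_size=40))
    def test_matches_hand_implementation_and_is_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert np.allclose(adj, self._bh_by_hand(pvals))
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestExactTest:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(0)
        block = rng.integers(5, 500, size=(80, 3))
        cm = make_cm(np.hstack([block, block]),
                     strains=tuple(["SP"] * 3 + ["ROCK"] * 3))
        recs = run_de(cm, "SP", "ROCK")
        assert all(r.call == "ns" for r in recs)
        assert all(abs(r.log2fc) < 0.2 for r in recs)

    def test_label_swap_negates_lfc_preserves_p(self):
        rng = np.random.default_rng(5)
        cm = make_cm(rng.negative_binomial(10, 0.05, size=(60, 8)),
                     strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        fwd = run_de(cm, "SP", "ROCK")
        rev = run_de(cm, "ROCK", "SP")
        for a, b in zip(fwd, rev):
            assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-9)
            assert a.pvalue == pytest.approx(b.pvalue, rel=1e-6)

    def test_call_thresholds_respected(self):
        rng = np.random.default_rng(7)
        mu = 2.0 ** rng.uniform(4, 9, 100)
        a = np.column_stack([rng.poisson(mu * np.where(np.arange(100) < 20, 4, 1))
                             for _ in range(4)])
        b = np.column_stack([rng.poisson(mu) for _ in range(4)])
        cm = make_cm(np.hstack([a, b]), strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        for r in run_de(cm, "SP", "ROCK"):
            if r.call == "up":
                assert r.log2fc >= 1 and r.fdr <= 0.01
            elif r.call == "down":
                assert r.log2fc <= -1 and r.fdr <= 0.01

    def test_single_replicate_rejected(self):
        cm = make_cm([[5, 5, 5]], strains=("SP", "ROCK", "ROCK"))
        with pytest.raises(ValueError, match="replicates"):
            run_de(cm, "SP", "ROCK")

    def test_agrees_with_independent_r_implementation(self, tmp_path):
        """Cross-validation against the canonical R exact-test workflow
        (TMM + conditional-likelihood dispersion + NB exact test) on a
        planted-effect matrix: p-value rankings nearly coincide and the
        up-called gene sets match."""
        import subprocess

        from congenomics.simulate import sample_negative_binomial

        rng = np.random.default_rng(11)
        n = 150
        mu = 2.0 ** rng.uniform(3, 9, n)
        eff = np.ones(n)
        eff[:20] = 4.0
        cols = [sample_negative_binomial(mu * eff, 0.05, None, rng) for _ in range(4)]
        cols += [sample_negative_binomial(mu, 0.05, None, rng) for _ in range(4)]
        cm = make_cm(np.column_stack(cols), strains=tuple(["SP"] * 4 + ["ROCK"] * 4))
        from congenomics.diffexpr import filter_genes as _filter

        cm = _filter(cm)
        recs = run_de(cm, "SP", "ROCK")
        mine = pd.DataFrame(
            {"gene": [r.gene_id for r in recs], "p": [r.pvalue for r in recs],
             "lfc": [r.log2fc for r in recs], "call": [r.call for r in recs]}
        ).set_index("gene")

        counts_path = tmp_path / "counts.tsv"
        out_path = tmp_path / "ref.tsv"
        cm.counts.to_csv(counts_path, sep="\t")
        rcode = f"""
suppressMessages(library(edgeR))
x <- read.delim("{counts_path}", row.names=1)
group <- factor(ifelse(grepl("^SP", colnames(x)), "SP", "ROCK"), levels=c("ROCK","SP"))
y <- DGEList(counts=x, group=group)
y <- calcNormFactors(y)
y <- estimateDisp(y)
tt <- topTags(exactTest(y), n=Inf, sort.by="none")$table
write.table(data.frame(gene=rownames(tt), tt), "{out_path}", sep="\\t",
            quote=FALSE, row.names=FALSE)
"""
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        theirs = pd.read_csv(out_path, sep="\t").set_index("gene")
        j = mine.join(theirs)

        from scipy.stats import spearmanr

        rho = spearmanr(-np.log10(j.p + 1e-300), -np.log10(j.PValue + 1e-300)).statistic
        assert rho >= 0.95
        assert np.abs(j.lfc - j.logFC).max() <= 0.3
        mine_up = set(j.index[j.call == "up"])
        their_up = set(j.index[(j.FDR <= 0.01) & (j.logFC >= 1)])
        assert len(mine_up & their_up) / max(1, len(mine_up | their_up)) >= 0.9
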