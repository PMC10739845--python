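"""Expression normalization (TMM, inverse-normal), cis scans, permutation
beta approximation, per-chromosome BH, and chromatin-state enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from telocausal import eqtl, synthetic
from telocausal.containers import TruthSet


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        counts = pd.DataFrame(
            np.tile([[10], [100], [1000]], (1, 4)),
            index=["g1", "g2", "g3"],
            columns=list("abcd"),
        )
        f = eqtl.tmm_factors(counts)
        np.testing.assert_allclose(f.values, 1.0)

    def test_pure_depth_difference_factors_equal(self):
        """Library B = 2x A count-for-count: composition is identical so the
        TMM factors agree (depth is handled by library size, not the factor)."""
        rng = np.random.default_rng(1)
        base = rng.integers(20, 2000, 300)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = eqtl.tmm_factors(counts)
        assert f["a"] == pytest.approx(f["b"], rel=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 5000, (400, 6)))
        f = eqtl.tmm_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_trimmed_mean_oracle_two_samples(self):
        """Direct-formula oracle: factors reproduce the weighted trimmed
        mean of M-values against the reference."""
        rng = np.random.default_rng(3)
        a = rng.integers(50, 3000, 500).astype(float)
        b = (a * rng.uniform(0.5, 2.0, 500)).round()
        counts = pd.DataFrame({"a": a, "b": b})
        f = eqtl.tmm_factors(counts, ref_sample="a")
        la, lb = a.sum(), b.sum()
        ra, rb = a / la, b / lb
        ok = (ra > 0) & (rb > 0)
        M = np.log2(rb[ok] / ra[ok])
        A = 0.5 * np.log2(rb[ok] * ra[ok])
        w = (lb - b[ok]) / (lb * b[ok]) + (la - a[ok]) / (la * a[ok])
        m_lo, m_hi = np.quantile(M, [0.3, 0.7])
        a_lo, a_hi = np.quantile(A, [0.05, 0.95])
        keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
        raw = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1 / w[keep]))
        expected = np.array([1.0, raw])
        expected /= stats.gmean(expected)
        assert f["b"] == pytest.approx(expected[1], rel=1e-9)

    def test_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            eqtl.tmm_factors(counts)


class TestInverseNormal:
    def test_hand_example_blom(self):
        out = eqtl.inverse_normal(np.array([3.0, 1.0, 2.0]))
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected)
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    @given(
        st.lists(st.integers(-10_000, 10_000), min_size=3, max_size=30, unique=True)
    )
    @settings(max_examples=40, deadline=None)
    def test_monotone_and_affine_invariant(self, xs):
        x = np.array(xs, dtype=float) / 100.0
        out = eqtl.inverse_normal(x)
        assert np.all(np.argsort(out) == np.argsort(x))
        np.testing.assert_allclose(out, eqtl.inverse_normal(2.5 * x - 7.0))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            eqtl.inverse_normal(np.ones(5))


class TestCisScan:
    def test_planted_eqtl_highly_significant(self, eqtl_dataset):
        geno, expr, truth = eqtl_dataset
        ne = eqtl.normalize_expression(eqtl.filter_expressed(expr))
        scan = eqtl.cis_scan(ne, expr.genes, geno)
        vid, gid, _ = truth.planted_eqtls[0]
        hit = scan.loc[(scan["gene_id"] == gid) & (scan["id"] == vid)]
        assert hit["p"].iloc[0] < 1e-10

    def test_window_boundary_inclusive(self):
        geno = synthetic.simulate_genotypes(
            60, 3, 1, seed=2, start_pos=1_000_000, spacing=1
        )
        # TSS such that variant 0 is exactly at TSS + 1e6 and variant 1 just out
        genes = pd.DataFrame(
            {"gene_id": ["gX"], "chrom": ["1"], "tss": [0], "strand": ["+"]}
        )
        ne = pd.DataFrame(
            np.random.default_rng(1).standard_normal((1, 60)),
            index=["gX"],
            columns=geno.samples,
        )
        scan = eqtl.cis_scan(ne, genes, geno, window=1e6)
        assert list(scan["id"]) == ["snp000000"]

    def test_null_p_uniform(self):
        geno = synthetic.simulate_genotypes(150, 40, 1, seed=3, spacing=100)
        rng = np.random.default_rng(4)
        ne = pd.DataFrame(
            rng.standard_normal((12, 150)),
            index=[f"g{i}" for i in range(12)],
            columns=geno.samples,
        )
        genes = pd.DataFrame(
            {"gene_id": ne.index, "chrom": "1", "tss": 2000, "strand": "+"}
        )
        scan = eqtl.cis_scan(ne, genes, geno)
        assert stats.kstest(scan["p"], "uniform").pvalue > 0.01

    def test_residualization_matches_full_regression(self, eqtl_dataset):
        """Covariate-residualized scan t-statistics equal the multiple
        regression oracle after the df correction."""
        import statsmodels.api as sm

        geno, expr, _ = eqtl_dataset
        ne = eqtl.normalize_expression(eqtl.filter_expressed(expr))
        rng = np.random.default_rng(5)
        C = rng.standard_normal((geno.n_samples, 3))
        scan = eqtl.cis_scan(ne, expr.genes, geno, covariates=C)
        row = scan.iloc[17]
        j = list(geno.variants["id"]).index(row["id"])
        X = sm.add_constant(np.column_stack([geno.dosages[:, j], C]))
        fit = sm.OLS(ne.loc[row["gene_id"]].to_numpy(), X).fit()
        assert row["beta"] == pytest.approx(fit.params[1], abs=1e-8)
        assert row["p"] == pytest.approx(fit.pvalues[1], abs=1e-8)


class TestPermutation:
    def test_single_variant_minima_uniform(self):
        """With one cis variant the permutation minima are U(0,1) and the
        fitted beta parameters are ~(1, 1)."""
        rng = np.random.default_rng(6)
        res = eqtl.permute_gene(
            rng.standard_normal(120),
            rng.standard_normal((120, 1)),
            ["v0"],
            n_perm=5000,
            seed=7,
        )
        assert res.beta_a == pytest.approx(1.0, abs=0.15)
        assert res.beta_b == pytest.approx(1.0, abs=0.15)

    def test_beta_approx_close_to_direct(self):
        """Beta-approximated p within +-0.03 of the direct empirical p."""
        rng = np.random.default_rng(8)
        geno = synthetic.simulate_genotypes(150, 15, 5, seed=9)
        diffs = []
        for g in range(20):
            y = rng.standard_normal(150)
            if g % 3 == 0:  # some genes carry weak signal
                y += 0.18 * geno.dosages[:, 4]
            res = eqtl.permute_gene(
                y, geno.dosages, list(geno.variants["id"]),
                n_perm=2000, seed=100 + g,
            )
            diffs.append(abs(res.p_beta - res.p_empirical))
        assert max(diffs) <= 0.03

    def test_fixed_seed_identical(self):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(80)
        X = rng.integers(0, 3, (80, 5)).astype(float)
        a = eqtl.permute_gene(y, X, list("abcde"), n_perm=200, seed=3)
        b = eqtl.permute_gene(y, X, list("abcde"), n_perm=200, seed=3)
        assert a.p_empirical == b.p_empirical and a.p_beta == b.p_beta


class TestFdr:
    def test_hand_bh_example(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "chrom": "1", "p": [0.001, 0.02, 0.9]}
        )
        out = eqtl.fdr_genes(df, alpha=0.05)
        assert list(out["egene"]) == [True, True, False]

    def test_matches_step_up_oracle_per_chromosome(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(40)],
                "chrom": rng.choice(["1", "2"], 40),
                "p": rng.uniform(0, 1, 40) ** 2,
            }
        )
        out = eqtl.fdr_genes(df, alpha=0.1)
        for chrom, grp in out.groupby("chrom"):
            p = grp["p"].to_numpy()
            m = len(p)
            order = np.argsort(p)
            thresh = 0.1 * (np.arange(1, m + 1)) / m
            passed = np.zeros(m, dtype=bool)
            below = np.where(p[order] <= thresh)[0]
            if below.size:
                passed[order[: below.max() + 1]] = True
            np.testing.assert_array_equal(grp["egene"].to_numpy(), passed)

    def test_all_ones_no_egenes(self):
        df = pd.DataFrame({"gene_id": ["a", "b"], "chrom": "1", "p": [1.0, 1.0]})
        assert not eqtl.fdr_genes(df, alpha=0.05)["egene"].any()


class TestStateEnrichment:
    def test_hypergeometric_extreme_table(self):
        """Fully separated 10/10 table: two-sided Fisher p = 2/C(20,10)."""
        states = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [1000], "state": ["TssA"]}
        )
        eq = pd.DataFrame({"chrom": "1", "pos": np.arange(1, 11) * 50})
        bg = pd.DataFrame({"chrom": "1", "pos": np.arange(1, 11) * 50 + 2000})
        out = eqtl.state_enrichment(eq, states, bg)
        from math import comb

        assert out["p"].iloc[0] == pytest.approx(2 / comb(20, 10), rel=1e-6)

    def test_identical_proportions_null(self):
        states = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [1000], "state": ["Enh"]}
        )
        eq = pd.DataFrame({"chrom": "1", "pos": [500, 1500]})
        bg = pd.DataFrame({"chrom": "1", "pos": [600, 1600]})
        out = eqtl.state_enrichment(eq, states, bg)
        assert out["odds_ratio"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(12)
        states = pd.DataFrame(
            {"chrom": "1", "start": [0], "end": [100_000], "state": ["TssA"]}
        )
        eq_in = rng.random(500) < 0.6
        eq = pd.DataFrame(
            {"chrom": "1",
             "pos": np.where(eq_in, rng.integers(1, 100_000, 500),
                             rng.integers(100_001, 1_000_000, 500))}
        )
        bg_in = rng.random(2000) < 0.2
        bg = pd.DataFrame(
            {"chrom": "1",
             "pos": np.where(bg_in, rng.integers(1, 100_000, 2000),
                             rng.integers(100_001, 1_000_000, 2000))}
        )
        out = eqtl.state_enrichment(eq, states, bg)
        assert out["odds_ratio"].iloc[0] > 1 and out["p"].iloc[0] < 0.05

    def test_empty_background_rejected(self):
        states = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [10], "state": ["x"]}
        )
        with pytest.raises(ValueError):
            eqtl.state_enrichment(
                pd.DataFrame({"chrom": "1", "pos": [5]}), states,
                pd.DataFrame(columns=["chrom", "pos"]),
            )
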