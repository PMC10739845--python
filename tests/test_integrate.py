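"""Colocalization, TWAS, SMR + HEIDI, transcriptional risk score, and the
causal-gene prioritization rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telocausal import integrate, synthetic
from telocausal.integrate import RegionPair


class TestWakefieldAbf:
    def test_closed_form_z_zero(self):
        """z = 0 with V = W gives ABF = sqrt(0.5)."""
        out = integrate.wakefield_log_abf(np.array([0.0]), np.array([0.15]))
        assert out[0] == pytest.approx(np.log(np.sqrt(0.5)), abs=1e-12)

    def test_no_information_limit(self):
        out = integrate.wakefield_log_abf(np.array([0.5]), np.array([1e6]))
        assert out[0] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_abs_z(self):
        se = np.full(50, 0.1)
        beta = np.linspace(0, 1, 50)
        out = integrate.wakefield_log_abf(beta, se)
        assert np.all(np.diff(out) > 0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            integrate.wakefield_log_abf(np.array([1.0]), np.array([0.0]))


class TestColoc:
    def test_posteriors_sum_to_one(self):
        pair = synthetic.simulate_region_pair(True, seed=1)
        res = integrate.coloc_abf(pair)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shared_causal_high_pp4(self):
        hits = sum(
            integrate.coloc_abf(synthetic.simulate_region_pair(True, seed=s)).pp4
            >= 0.8
            for s in range(25)
        )
        assert hits >= 23

    def test_distinct_causal_pp3_dominates(self):
        hits = sum(
            (lambda r: r.pp3 > r.pp4)(
                integrate.coloc_abf(synthetic.simulate_region_pair(False, seed=s))
            )
            for s in range(25)
        )
        assert hits >= 23

    def test_flat_signals_pp0_largest(self):
        rng = np.random.default_rng(3)
        m = 30
        pair = RegionPair(
            "g",
            [f"v{i}" for i in range(m)],
            rng.normal(0, 0.005, m),
            np.full(m, 0.01),
            rng.normal(0, 0.005, m),
            np.full(m, 0.01),
            np.eye(m),
        )
        res = integrate.coloc_abf(pair)
        assert np.argmax(res.pp) == 0

    def test_single_variant_low_resolution(self):
        pair = RegionPair(
            "g", ["v0"], np.array([0.5]), np.array([0.05]),
            np.array([0.4]), np.array([0.05]), np.eye(1),
        )
        res = integrate.coloc_abf(pair)
        assert res.low_resolution and res.pp[3] == pytest.approx(0.0, abs=1e-12)

    def test_null_variant_barely_moves_pp4(self):
        pair = synthetic.simulate_region_pair(True, seed=5)
        res = integrate.coloc_abf(pair)
        aug = RegionPair(
            pair.gene_id,
            pair.variant_ids + ["vnull"],
            np.append(pair.beta_eqtl, 0.0),
            np.append(pair.se_eqtl, pair.se_eqtl[0]),
            np.append(pair.beta_gwas, 0.0),
            np.append(pair.se_gwas, pair.se_gwas[0]),
            np.pad(pair.ld, ((0, 1), (0, 1)))
            + np.diag(np.append(np.zeros(len(pair.variant_ids)), 1.0)),
        )
        res2 = integrate.coloc_abf(aug)
        assert abs(res.pp4 - res2.pp4) < 0.01

    def test_two_tier_classification_rule(self):
        def fake(pp3, pp4):
            return integrate._classify(pp3, pp4)

        assert fake(0.1, 0.85) == "strong"
        assert fake(0.15, 0.55) == "suggestive"
        assert fake(0.3, 0.55) == "none"  # ratio below 3
        assert fake(0.01, 0.45) == "none"  # PP4 below 0.5


class TestTwas:
    def test_single_variant_identity(self):
        Z, _ = integrate.twas_assoc(np.array([1.0]), np.array([2.7]), np.eye(1))
        assert Z == pytest.approx(2.7)

    def test_perfect_ld_two_variants(self):
        """w = [0.5, 0.5], z = [3, 3], perfect LD: Z = 3."""
        R = np.ones((2, 2))
        Z, _ = integrate.twas_assoc(np.array([0.5, 0.5]), np.array([3.0, 3.0]), R)
        assert Z == pytest.approx(3.0)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError):
            integrate.twas_assoc(np.zeros(3), np.ones(3), np.eye(3))

    def test_null_gene_z_standard_normal(self):
        """Weights orthogonal to any signal give Z ~ N(0,1) over sims."""
        rng = np.random.default_rng(7)
        g = synthetic.simulate_genotypes(300, 20, 20, seed=8, ld_rho=0.8)
        R = integrate.regularize_ld(np.corrcoef(g.dosages, rowvar=False))
        L = np.linalg.cholesky(R)
        zs = []
        for _ in range(1500):
            z = L @ rng.standard_normal(20)
            w = rng.standard_normal(20)
            zs.append(integrate.twas_assoc(w, z, R)[0])
        assert abs(np.mean(zs)) < 0.08
        assert np.std(zs) == pytest.approx(1.0, abs=0.08)

    def test_top1_weight_hits_planted_variant(self):
        hits = 0
        for s in range(20):
            g = synthetic.simulate_genotypes(300, 30, 10, seed=50 + s)
            rng = np.random.default_rng(900 + s)
            x = g.dosages[:, 12]
            y = 0.65 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.65**2) * (
                rng.standard_normal(300)
            )
            w = integrate.fit_twas_weights(
                y, g.dosages, list(g.variants["id"]), method="top1", seed=s
            )
            if w is not None and int(np.argmax(np.abs(w.weights))) == 12:
                hits += 1
        assert hits >= 18

    def test_h2_gate_excludes_noise_genes(self):
        excluded = 0
        for s in range(20):
            g = synthetic.simulate_genotypes(200, 25, 5, seed=70 + s)
            y = np.random.default_rng(1000 + s).standard_normal(200)
            w = integrate.fit_twas_weights(
                y, g.dosages, list(g.variants["id"]), method="top1", seed=s
            )
            excluded += w is None
        assert excluded >= 18

    def test_top1_single_nonzero_weight(self):
        g = synthetic.simulate_genotypes(200, 15, 5, seed=90)
        x = g.dosages[:, 7]
        y = (x - x.mean()) / x.std()
        w = integrate.fit_twas_weights(y, g.dosages, list(g.variants["id"]),
                                       method="top1")
        assert w is not None and (w.weights != 0).sum() == 1


class TestSmr:
    def test_equal_z_closed_form(self):
        _, T, _ = integrate.smr_test(0.5, 0.5 / 4.0, 0.3, 0.3 / 4.0)
        assert T == pytest.approx(16.0 / 2.0)

    def test_hand_example_tail(self):
        b, T, p = integrate.smr_test(0.6, 0.1, 0.4, 0.1)
        assert T == pytest.approx(576.0 / 52.0)
        assert p == pytest.approx(stats.chi2.sf(576.0 / 52.0, 1), rel=1e-9)
        assert b == pytest.approx(0.4 / 0.6)

    def test_zero_gwas_effect(self):
        _, T, p = integrate.smr_test(0.5, 0.1, 0.0, 0.1)
        assert T == 0.0 and p == 1.0

    def test_zero_instrument_rejected(self):
        with pytest.raises(ValueError):
            integrate.smr_test(0.0, 0.1, 0.3, 0.1)

    def test_null_link_p_uniform(self):
        """Independent traits with a strong eQTL give uniform SMR p."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(1000):
            be = 0.5 + rng.normal(0, 0.05)
            bg = rng.normal(0, 0.02)
            _, _, p = integrate.smr_test(be, 0.05, bg, 0.02)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestHeidi:
    def test_shared_causal_passes(self):
        passes = sum(
            integrate.heidi_test(
                synthetic.simulate_region_pair(True, seed=s, z_eqtl=12, z_gwas=10)
            )[0]
            >= 0.01
            for s in range(30)
        )
        assert passes >= 26  # >= 85%

    def test_linkage_detected(self):
        fails = sum(
            integrate.heidi_test(
                synthetic.simulate_region_pair(
                    False, seed=400 + s, z_eqtl=12, z_gwas=10, distinct_r2=0.3
                )
            )[0]
            < 0.01
            for s in range(30)
        )
        assert fails >= 21  # >= 70%

    def test_too_few_snps_undefined(self):
        m = 3
        R = np.eye(m)  # nothing in the eligible LD band around the anchor
        pair = RegionPair(
            "g", [f"v{i}" for i in range(m)],
            np.array([0.5, 0.01, 0.01]), np.full(m, 0.05),
            np.array([0.3, 0.01, 0.01]), np.full(m, 0.05), R,
        )
        p, n = integrate.heidi_test(pair)
        assert np.isnan(p) and n < 3


class TestTrsAndPrioritize:
    def test_single_gene_hand_value(self):
        pred = pd.DataFrame({"gA": [1.5, -1.5]}, index=["s1", "s2"])
        twas = pd.DataFrame(
            {"gene_id": ["gA"], "z": [2.0], "significant": [True]}
        )
        trs = integrate.compute_trs(pred, twas)
        # per-gene standardization: [1.5, -1.5] -> [1, -1], times Z = 2
        assert trs["s1"] == pytest.approx(2.0)
        assert trs["s2"] == pytest.approx(-2.0)

    def test_no_significant_genes_zero_vector(self):
        pred = pd.DataFrame({"gA": [1.0, 2.0]}, index=["s1", "s2"])
        twas = pd.DataFrame({"gene_id": ["gA"], "z": [0.5], "significant": [False]})
        with pytest.warns(UserWarning):
            trs = integrate.compute_trs(pred, twas)
        assert (trs == 0).all()

    def test_prioritize_set_logic(self):
        coloc = [
            integrate.ColocResult("A", np.array([0, 0, 0, 0.1, 0.9]), 10, "strong"),
            integrate.ColocResult("B", np.array([0, 0, 0, 0.1, 0.6]), 10, "suggestive"),
            integrate.ColocResult("C", np.array([0, 0, 0, 0.1, 0.9]), 10, "strong"),
        ]
        twas = pd.DataFrame(
            {"gene_id": ["B", "D"], "z": [4.0, 3.5], "p": [1e-4, 1e-3],
             "q": [0.01, 0.02]}
        )
        smr = pd.DataFrame(
            {"gene_id": ["C", "E"], "p_smr": [1e-4, 1e-3],
             "p_heidi": [0.5, 0.8]}
        )
        out = integrate.prioritize(coloc, twas, smr)
        called = set(out.loc[out["causal"], "gene_id"])
        assert called == {"B", "C"}

    def test_empty_coloc_no_calls(self):
        twas = pd.DataFrame({"gene_id": ["A"], "z": [5.0], "p": [1e-7], "q": [0.001]})
        smr = pd.DataFrame({"gene_id": ["A"], "p_smr": [1e-5], "p_heidi": [0.9]})
        out = integrate.prioritize([], twas, smr)
        assert not out["causal"].any()

    def test_heidi_failure_blocks_smr_route(self):
        coloc = [integrate.ColocResult("A", np.array([0, 0, 0, 0.1, 0.9]), 10,
                                       "strong")]
        twas = pd.DataFrame(columns=["gene_id", "z", "p", "q"])
        smr = pd.DataFrame({"gene_id": ["A"], "p_smr": [1e-6], "p_heidi": [0.001]})
        out = integrate.prioritize(coloc, twas, smr)
        assert not out["causal"].any()

    def test_prioritize_monotone_in_coloc(self):
        twas = pd.DataFrame(
            {"gene_id": ["A", "B"], "z": [4.0, 4.0], "p": [1e-4, 1e-4],
             "q": [0.01, 0.01]}
        )
        smr = pd.DataFrame(columns=["gene_id", "p_smr", "p_heidi"])
        small = [integrate.ColocResult("A", np.array([0, 0, 0, 0.1, 0.9]), 5,
                                       "strong")]
        big = small + [integrate.ColocResult("B", np.array([0, 0, 0, 0.1, 0.6]),
                                             5, "suggestive")]
        called_small = set(
            integrate.prioritize(small, twas, smr).query("causal")["gene_id"]
        )
        called_big = set(
            integrate.prioritize(big, twas, smr).query("causal")["gene_id"]
        )
        assert called_small <= called_big
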