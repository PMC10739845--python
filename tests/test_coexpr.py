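"""Co-expression networks: soft connectivity, TOM modules, module-trait
correlation, sliding-window connectivity, track clustering, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from telocausal import coexpr


def factor_expression(n_genes, n_samples, loading, seed, n_factors=1):
    rng = np.random.default_rng(seed)
    per = n_genes // n_factors
    rows = []
    for f in range(n_factors):
        fac = rng.standard_normal(n_samples)
        for _ in range(per):
            rows.append(loading * fac + np.sqrt(1 - loading**2)
                        * rng.standard_normal(n_samples))
    X = np.vstack(rows)
    return pd.DataFrame(
        X, index=[f"g{i}" for i in range(len(rows))],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestSoftConnectivity:
    def test_perfectly_correlated_trio(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = pd.DataFrame(
            [base, 2 * base, -3 * base + 1],
            index=["a", "b", "c"],
            columns=list("vwxyz"),
        )
        k = coexpr.soft_connectivity(expr, power=9)
        np.testing.assert_allclose(k.values, 2.0, atol=1e-9)

    def test_independent_genes_near_zero(self):
        expr = factor_expression(30, 1000, 0.0, seed=1)
        k = coexpr.soft_connectivity(expr, power=9)
        assert k.mean() < 0.05 * 29

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=15, deadline=None)
    def test_affine_rescaling_invariance(self, a, b):
        expr = factor_expression(5, 40, 0.6, seed=2)
        k1 = coexpr.soft_connectivity(expr, power=9)
        expr2 = expr.copy()
        expr2.iloc[0] = a * expr2.iloc[0] + b
        k2 = coexpr.soft_connectivity(expr2, power=9)
        np.testing.assert_allclose(k1.values, k2.values, atol=1e-9)


class TestTom:
    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_tom_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, (8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tom = coexpr.tom_similarity(A)
        assert np.all(tom >= 0) and np.all(tom <= 1)
        np.testing.assert_allclose(tom, tom.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestModules:
    def test_two_planted_factors_recovered(self):
        hits = []
        for s in range(10):
            expr = factor_expression(100, 120, 0.9, seed=s, n_factors=2)
            mods = coexpr.detect_modules(expr, min_module_size=20)
            labels = mods.labels
            truth = np.repeat([0, 1], 50)
            best = 0.0
            for mod in set(labels) - {"unassigned"}:
                mask = (labels == mod).to_numpy()
                best = max(best, (truth[mask] == 0).mean(),
                           (truth[mask] == 1).mean())
            n_modules = len(set(labels) - {"unassigned"})
            hits.append(n_modules == 2 and best >= 0.9)
        assert np.mean(hits) >= 0.9

    def test_tiny_input_unassigned(self):
        expr = factor_expression(5, 30, 0.5, seed=3)
        mods = coexpr.detect_modules(expr, min_module_size=30)
        assert set(mods.labels) == {"unassigned"}

    def test_eigengene_tracks_module_mean(self):
        expr = factor_expression(60, 100, 0.9, seed=4)
        mods = coexpr.detect_modules(expr, min_module_size=20)
        me = mods.eigengenes.iloc[:, 0]
        mean_profile = expr.mean(axis=0)
        assert np.corrcoef(me, mean_profile)[0, 1] > 0


class TestModuleTrait:
    def test_constructed_trait_perfect_correlation(self):
        expr = factor_expression(50, 80, 0.95, seed=5)
        mods = coexpr.detect_modules(expr, min_module_size=20)
        trait = pd.Series(expr.sum(axis=0).to_numpy(), index=expr.columns)
        table = coexpr.module_trait(mods, trait)
        assert abs(table["r"].iloc[0]) > 0.9

    def test_trait_affine_invariance(self):
        expr = factor_expression(50, 80, 0.8, seed=6)
        mods = coexpr.detect_modules(expr, min_module_size=20)
        t = pd.Series(np.random.default_rng(7).standard_normal(80),
                      index=expr.columns)
        r1 = coexpr.module_trait(mods, t)["r"]
        r2 = coexpr.module_trait(mods, 3.0 * t + 2.0)["r"]
        np.testing.assert_allclose(r1, r2)

    def test_permuted_trait_rarely_significant(self):
        sig = 0
        for s in range(10):
            expr = factor_expression(60, 100, 0.8, seed=20 + s, n_factors=3)
            mods = coexpr.detect_modules(expr, min_module_size=15)
            rng = np.random.default_rng(50 + s)
            t = pd.Series(rng.standard_normal(100), index=expr.columns)
            table = coexpr.module_trait(mods, t)
            sig += int((table["q"] < 0.05).any())
        assert sig <= 1


def rtl_series(expr, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.standard_normal(expr.shape[1]), index=expr.columns)


class TestSlidingConnectivity:
    def test_window_count_and_turnover(self):
        n = 166
        expr = pd.DataFrame(
            np.abs(np.random.default_rng(8).standard_normal((40, n))) * 10,
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j:03d}" for j in range(n)],
        )
        track = coexpr.sliding_connectivity(expr, rtl_series(expr, 9),
                                            window_fraction=0.25)
        m = round(0.25 * n)
        assert len(track.windows) == n - m + 1
        for a, b in zip(track.windows, track.windows[1:]):
            assert len(set(a) ^ set(b)) == 2
            assert len(a) == m

    def test_rtl_dependent_module_tracks_decline(self):
        """Genes co-regulated only in high-RTL samples lose connectivity as
        the window slides toward low RTL."""
        declines = []
        for s in range(10):
            rng = np.random.default_rng(300 + s)
            n = 120
            rtl = pd.Series(np.sort(rng.standard_normal(n))[::-1],
                            index=[f"s{j:03d}" for j in range(n)])
            fac = rng.standard_normal(n)
            X = []
            for _ in range(25):
                g = 0.9 * fac + 0.44 * rng.standard_normal(n)
                g[n // 2:] = rng.standard_normal(n - n // 2)  # decouple low-RTL half
                X.append(g)
            for _ in range(25):
                X.append(rng.standard_normal(n))
            tpm = np.exp(np.vstack(X) * 0.5 + 5)
            expr = pd.DataFrame(tpm, index=[f"g{i}" for i in range(50)],
                                columns=rtl.index)
            track = coexpr.sliding_connectivity(
                expr, rtl, top_var_fraction=1.0, window_fraction=0.3
            )
            planted = [g for g in track.tracks.index if int(g[1:]) < 25]
            sub = track.tracks.loc[planted].to_numpy()
            slope = np.polyfit(np.arange(sub.shape[1]), sub.mean(axis=0), 1)[0]
            declines.append(slope < 0)
        assert np.mean(declines) >= 0.9

    def test_flat_structure_flat_tracks(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(
            np.exp(rng.standard_normal((30, 100)) * 0.01 + 3),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(100)],
        )
        track = coexpr.sliding_connectivity(expr, rtl_series(expr, 13),
                                            top_var_fraction=1.0)
        # per-gene variance of the raw track is negligible on the
        # connectivity scale (max possible k is n_genes - 1)
        assert track.raw.std(axis=1).max() < 0.02 * (expr.shape[0] - 1)

    def test_window_too_small_rejected(self):
        expr = factor_expression(20, 20, 0.5, seed=14)
        with pytest.raises(ValueError):
            coexpr.sliding_connectivity(expr, rtl_series(expr), window_fraction=0.2)


class TestClusterTracks:
    def test_two_shapes_separated(self):
        rng = np.random.default_rng(15)
        up = np.linspace(-1, 1, 50)
        tracks = np.vstack(
            [up + 0.05 * rng.standard_normal(50) for _ in range(40)]
            + [-up + 0.05 * rng.standard_normal(50) for _ in range(40)]
        )
        ct = coexpr.ConnectivityTrack(
            tracks=pd.DataFrame(tracks), windows=[[]] * 50
        )
        labels, k = coexpr.cluster_tracks(ct, k_max=8, seed=1)
        assert k == 2
        assert labels.iloc[:40].nunique() == 1 and labels.iloc[40:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_tracks_single_cluster(self):
        tracks = np.tile(np.linspace(0, 1, 30), (60, 1))
        ct = coexpr.ConnectivityTrack(tracks=pd.DataFrame(tracks),
                                      windows=[[]] * 30)
        _, k = coexpr.cluster_tracks(ct, seed=2)
        assert k == 1

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(16)
        tracks = pd.DataFrame(rng.standard_normal((60, 20)))
        ct = coexpr.ConnectivityTrack(tracks=tracks, windows=[[]] * 20)
        l1, k1 = coexpr.cluster_tracks(ct, seed=5)
        l2, k2 = coexpr.cluster_tracks(ct, seed=5)
        assert k1 == k2 and l1.equals(l2)


class TestSetEnrichment:
    def test_hypergeometric_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        selected = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        out = coexpr.set_enrichment(selected, universe, {"s": gene_set})
        expected = sum(
            stats.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11)
        )
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_selection_large_p(self):
        universe = {f"g{i}" for i in range(30)}
        out = coexpr.set_enrichment(
            {f"g{i}" for i in range(5)},
            universe,
            {"s": {f"g{i}" for i in range(20, 25)}},
        )
        assert out["p"].iloc[0] >= 0.5

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            coexpr.set_enrichment({"x"}, {"a", "b"}, {"s": {"a"}})
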