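import math

import numpy as np
import pandas as pd
import pytest

from meromix import ecology_stats as es
from meromix.synthetic_lake import gradient_community


def random_closed_table(rng, n_samples=6, n_taxa=5):
    raw = rng.random((n_samples, n_taxa)) ** 2  # skewed like real communities
    raw = raw / raw.sum(axis=1, keepdims=True) * 100.0
    return pd.DataFrame(
        raw,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )


class TestSimpson:
    def test_single_taxon_zero(self):
        row = pd.Series({"A": 100.0, "B": 0.0})
        assert es.simpson_diversity(row) == pytest.approx(0.0)

    def test_four_even_taxa(self):
        row = pd.Series({"A": 25.0, "B": 25.0, "C": 25.0, "D": 25.0})
        assert es.simpson_diversity(row) == pytest.approx(0.75)

    def test_row_not_closed_errors(self):
        with pytest.raises(ValueError, match="sums"):
            es.simpson_diversity(pd.Series({"A": 60.0}))

    def test_dominance_strictly_decreases_index(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            table = random_closed_table(rng, n_samples=1, n_taxa=6)
            row = table.iloc[0]
            boosted = row.copy()
            # shift 5% of everyone else onto the first taxon, if it already
            # holds a plurality (dominance transfer)
            top = row.idxmax()
            transfer = (row.drop(top) * 0.2)
            boosted[top] += transfer.sum()
            boosted[transfer.index] -= transfer
            assert es.simpson_diversity(boosted) < es.simpson_diversity(row)

    def test_bounded_by_richness(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            table = random_closed_table(rng, n_samples=1, n_taxa=7)
            value = es.simpson_diversity(table.iloc[0])
            assert 0.0 <= value <= 1.0 - 1.0 / 7.0 + 1e-12


class TestBrayCurtis:
    def test_identical_rows_100(self):
        table = pd.DataFrame(
            {"A": [60.0, 60.0], "B": [40.0, 40.0]}, index=["s1", "s2"])
        sim = es.bray_curtis(table)
        assert sim.loc["s1", "s2"] == pytest.approx(100.0)

    def test_disjoint_rows_zero(self):
        table = pd.DataFrame(
            {"A": [100.0, 0.0], "B": [0.0, 100.0]}, index=["s1", "s2"])
        assert es.bray_curtis(table).loc["s1", "s2"] == pytest.approx(0.0)

    def test_hand_computed_pair(self):
        # rows (100, 0) and (50, 50): y = (10, 0) and (sqrt50, sqrt50);
        # S = 200 * min-sum / total-sum = 200*sqrt(50) / (10 + 2*sqrt(50))
        table = pd.DataFrame(
            {"A": [100.0, 50.0], "B": [0.0, 50.0]}, index=["s1", "s2"])
        expected = 200.0 * math.sqrt(50) / (10.0 + 2.0 * math.sqrt(50))
        assert es.bray_curtis(table).loc["s1", "s2"] == pytest.approx(expected)

    def test_valid_similarity_matrix(self):
        rng = np.random.default_rng(8)
        table = random_closed_table(rng, n_samples=7)
        sim = es.bray_curtis(table)
        values = sim.to_numpy()
        np.testing.assert_allclose(values, values.T)
        np.testing.assert_allclose(np.diag(values), 100.0)
        assert (values >= -1e-12).all() and (values <= 100.0 + 1e-12).all()


class TestSimper:
    def test_conservation_on_random_tables(self):
        """Per-pair taxon similarity terms sum to the pair's Bray-Curtis
        value; dissimilarity terms to its complement (100 random tables)."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            table = random_closed_table(rng, n_samples=4, n_taxa=6)
            sim = es.bray_curtis(table)
            y = np.sqrt(table.to_numpy())
            for j in range(4):
                for k in range(j + 1, 4):
                    s_terms, d_terms = es._pair_terms(y[j], y[k])
                    assert abs(s_terms.sum() - sim.iloc[j, k]) < 1e-9
                    assert abs(d_terms.sum() - (100.0 - sim.iloc[j, k])) < 1e-9

    def test_contrasting_dominants_top_contributors(self):
        table = pd.DataFrame(
            {
                "A": [90.0, 88.0, 5.0, 4.0],
                "B": [5.0, 6.0, 90.0, 91.0],
                "C": [5.0, 6.0, 5.0, 5.0],
            },
            index=["g1a", "g1b", "g2a", "g2b"],
        )
        groups = {"g1a": "g1", "g1b": "g1", "g2a": "g2", "g2b": "g2"}
        result = es.simper(table, groups)
        top2 = list(result.between[("g1", "g2")].index[:2])
        assert set(top2) == {"A", "B"}

    def test_identical_groups_zero_dissimilarity(self):
        table = pd.DataFrame(
            {"A": [50.0] * 4, "B": [50.0] * 4},
            index=["a1", "a2", "b1", "b2"],
        )
        groups = {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"}
        result = es.simper(table, groups)
        assert result.mean_between[("g1", "g2")] == pytest.approx(0.0)
        assert (result.between[("g1", "g2")] == 0.0).all()

    def test_singleton_group_warns_and_skips(self):
        table = pd.DataFrame(
            {"A": [50.0, 60.0, 70.0], "B": [50.0, 40.0, 30.0]},
            index=["s1", "s2", "s3"],
        )
        groups = {"s1": "g1", "s2": "g1", "s3": "lonely"}
        with pytest.warns(UserWarning, match="lonely"):
            result = es.simper(table, groups)
        assert "lonely" not in result.within
        assert "g1" in result.within


class TestDbrda:
    def test_planted_gradient_axis1_fitted(self):
        table, env = gradient_community(n_samples=30, n_taxa=8, seed=0)
        sim = es.bray_curtis(table)
        envz = (env - env.mean()) / env.std(ddof=1)
        result = es.dbrda(sim, envz[["gradient"]], selection="all")
        assert result.pct_fitted[0] == pytest.approx(100.0, abs=1e-6)
        assert result.r_squared > 0.5

    def test_permutation_collapses_fit(self):
        table, env = gradient_community(n_samples=30, n_taxa=8, seed=0)
        sim = es.bray_curtis(table)
        envz = (env - env.mean()) / env.std(ddof=1)
        true_fit = es.dbrda(sim, envz[["gradient"]], selection="all").r_squared
        rng = np.random.default_rng(1)
        permuted = envz.copy()
        permuted["gradient"] = rng.permutation(permuted["gradient"].to_numpy())
        null_fit = es.dbrda(sim, permuted[["gradient"]], selection="all").r_squared
        assert null_fit < 0.15
        assert true_fit > 4 * null_fit

    def test_noise_environment_explains_little(self):
        table, _ = gradient_community(n_samples=60, n_taxa=8, noise_sigma=0.3, seed=1)
        rng = np.random.default_rng(2)
        noise_env = pd.DataFrame(
            rng.standard_normal((60, 2)), index=table.index, columns=["a", "b"])
        result = es.dbrda(es.bray_curtis(table), noise_env, selection="all")
        assert result.r_squared * 100.0 < 5.0

    def test_axis_percentages_are_consistent(self):
        table, env = gradient_community(n_samples=25, n_taxa=6, noise_sigma=0.2, seed=3)
        envz = (env - env.mean()) / env.std(ddof=1)
        result = es.dbrda(es.bray_curtis(table), envz, selection="all")
        assert result.pct_fitted.sum() == pytest.approx(100.0, abs=1e-6)
        assert result.pct_total.sum() <= 100.0 + 1e-9
        np.testing.assert_allclose(
            result.pct_total.sum(), result.r_squared * 100.0, atol=1e-6)

    def test_forward_selection_finds_gradient_first(self):
        table, env = gradient_community(n_samples=30, n_taxa=8, seed=4)
        envz = (env - env.mean()) / env.std(ddof=1)
        result = es.dbrda(es.bray_curtis(table), envz, selection="forward-adjR2")
        assert result.selected[0] == "gradient"

    def test_collinear_env_rejected(self):
        table, env = gradient_community(n_samples=20, n_taxa=6, seed=5)
        env2 = env.copy()
        env2["copy"] = env2["gradient"] * 2.0
        envz = (env2 - env2.mean()) / env2.std(ddof=1)
        with pytest.raises(ValueError, match="collinear"):
            es.dbrda(es.bray_curtis(table), envz, selection="all")


class TestEnvMatrix:
    def test_zscore_columns(self):
        env = pd.DataFrame({
            "depth_m": [0.0, 5.0, 12.0, 23.5],
            "salinity_pct": [1.0, 1.2, 3.8, 4.2],
        }, index=list("abcd"))
        z = es.env_matrix(env, ("depth_m", "salinity_pct"))
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_missing_rows_dropped_with_warning(self):
        env = pd.DataFrame({
            "depth_m": [0.0, 5.0, np.nan, 23.5],
            "salinity_pct": [1.0, 1.2, 3.8, 4.2],
        }, index=list("abcd"))
        with pytest.warns(UserWarning, match="dropped 1"):
            z = es.env_matrix(env, ("depth_m", "salinity_pct"))
        assert list(z.index) == ["a", "b", "d"]


class TestPearsonAnova:
    def test_linear_relationship(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 6.0, 8.0]
        r, _ = es.pearson(x, y)
        slope, f, _ = es.anova_regression(x, y)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            es.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            es.anova_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_r_squared_equals_regression_r2(self):
        rng = np.random.default_rng(12)
        x = rng.random(20)
        y = 3.0 * x + rng.normal(0, 0.3, 20)
        r, p_r = es.pearson(x, y)
        slope, f, p_f = es.anova_regression(x, y)
        n = len(x)
        # F = r^2 (n-2) / (1 - r^2), the standard identity
        assert f == pytest.approx(r * r * (n - 2) / (1 - r * r), rel=1e-9)
        assert p_f == pytest.approx(p_r, rel=1e-9)
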