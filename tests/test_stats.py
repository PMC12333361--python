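"""Coarse-graining, trend fits, PCA and ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest

from cidnp_screen.records import FeatureTable
from cidnp_screen.stats import anova_tukey, coarse_grain, run_pca, trend_fit


class TestCoarseGrain:
    def test_site_level_is_identity(self, table):
        assert len(coarse_grain(table, "site")) == len(table)

    def test_molecule_level_keeps_max_sne_row_per_molecule(self, table):
        out = coarse_grain(table, "molecule")
        assert len(out) == table.n_molecules
        # oracle: group-wise max via pandas
        expected = table.frame.groupby("molecule_id")["sne"].max()
        got = out.frame.set_index("molecule_id")["sne"]
        pd.testing.assert_series_equal(got.sort_index(), expected.sort_index())

    def test_family_level_one_row_per_family_series_group(self, table):
        out = coarse_grain(table, "family")
        n_groups = table.frame.groupby(["family", "series"]).ngroups
        assert len(out) == n_groups

    def test_invalid_level(self, table):
        with pytest.raises(ValueError):
            coarse_grain(table, "galaxy")


def _table_from_xy(x, y):
    df = pd.DataFrame(
        {
            "molecule_id": [f"M{i}" for i in range(len(x))],
            "family": "indole",
            "series": "H",
            "site_id": "1",
            "ip": x, "nucleophilicity": 1.0, "lumo_homo": 1.0, "delta_g": 1.0,
            "a_iso": 1.0, "fukui": x, "q_value": 1.0, "log_p": 1.0,
            "sne": y,
        }
    )
    return FeatureTable(df)


class TestTrendFit:
    def test_noiseless_line_recovers_slope(self):
        x = np.arange(10, dtype=float)
        fit = trend_fit(_table_from_xy(x, 2 * x), "fukui")
        assert fit.coefficients["fukui"] == pytest.approx(2.0, abs=1e-10)
        assert fit.p_value < 1e-12

    def test_noiseless_parabola_recovers_quadratic_coefficient(self):
        x = np.linspace(-2, 2, 15)
        fit = trend_fit(_table_from_xy(x, 3 * x**2 + x + 5), "fukui", form="quadratic")
        assert fit.coefficients["fukui^2"] == pytest.approx(3.0, abs=1e-9)
        assert fit.coefficients["fukui"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            trend_fit(_table_from_xy(np.ones(10), np.arange(10.0)), "fukui")

    def test_monte_carlo_slope_bias_is_negligible(self):
        """Simulated y = x + N(0,1), n=100: mean slope estimate over 500
        replicates within 0.02 of the true slope."""
        rng = np.random.default_rng(8)
        slopes = []
        x = rng.uniform(0, 3, 100)
        for _ in range(500):
            y = x + rng.normal(0, 1, 100)
            slopes.append(trend_fit(_table_from_xy(x, y), "fukui").coefficients["fukui"])
        assert abs(np.mean(slopes) - 1.0) < 0.02


class TestRunPCA:
    def test_single_direction_data_puts_everything_on_pc1(self):
        t = np.linspace(0, 1, 30)
        df = _table_from_xy(t, np.ones(30)).frame
        for col in ("ip", "nucleophilicity", "lumo_homo", "a_iso"):
            df[col] = df["fukui"] * {"ip": 1.0, "nucleophilicity": -2.0, "lumo_homo": 0.5, "a_iso": 3.0}[col]
        # remaining features constant -> dropped with a warning
        with pytest.warns(UserWarning, match="zero-variance"):
            res = run_pca(FeatureTable(df), n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert set(res.dropped_features) == {"delta_g", "q_value", "log_p"}

    def test_explained_variance_matches_eigendecomposition_oracle(self, table):
        res = run_pca(table, n_components=3)
        X = table.features().to_numpy(dtype=float)
        Z = (X - X.mean(0)) / X.std(0, ddof=0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(Z, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_ratio, eigvals / eigvals.sum(), atol=1e-8
        )

    def test_ratio_invariants(self, table):
        res = run_pca(table, n_components=3)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.cumulative) >= -1e-12).all()
        assert ((0 <= res.explained_variance_ratio) & (res.explained_variance_ratio <= 1)).all()

    def test_invariant_to_row_order_and_feature_rescaling(self, table):
        res = run_pca(table, n_components=3)
        scaled = table.copy()
        scaled.frame["a_iso"] = scaled.frame["a_iso"] * 1e3 + 7.0
        shuffled = FeatureTable(scaled.frame.sample(frac=1.0, random_state=1))
        res2 = run_pca(shuffled, n_components=3)
        np.testing.assert_allclose(
            res.explained_variance_ratio, res2.explained_variance_ratio, atol=1e-10
        )


class TestAnovaTukey:
    def _class_table(self, means, n=20, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        x, labels = [], []
        for i, m in enumerate(means):
            x.append(rng.normal(m, sd, n))
            labels += [f"g{i}"] * n
        df = _table_from_xy(np.concatenate(x), np.concatenate(x)).frame
        df["sne_class"] = labels
        return FeatureTable(df)

    def test_identical_groups_give_f_near_zero(self):
        base = np.arange(20.0)
        df = _table_from_xy(np.tile(base, 2), np.tile(base, 2)).frame
        df["molecule_id"] = [f"M{i}" for i in range(len(df))]
        df["sne_class"] = ["a"] * 20 + ["b"] * 20
        anova, _ = anova_tukey(FeatureTable(df), "sne_class", "fukui")
        assert anova.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)
        assert anova.loc[0, "p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_detected_by_anova_and_tukey(self):
        t = self._class_table([0.0, 10.0], n=20, seed=1)
        anova, tukey = anova_tukey(t, "sne_class", "fukui")
        assert anova.loc[0, "p_value"] < 1e-6
        assert bool(tukey["reject"].iloc[0])

    def test_singleton_group_error_names_group(self):
        t = self._class_table([0.0, 1.0], n=2)
        t.frame = t.frame.iloc[:-1]
        with pytest.raises(ValueError, match="g1"):
            anova_tukey(t, "sne_class", "fukui")

    def test_null_groups_rarely_rejected(self):
        """Three groups from one distribution should usually give p > 0.05."""
        rejected = 0
        for seed in range(40):
            t = self._class_table([0.0, 0.0, 0.0], n=15, seed=seed)
            anova, _ = anova_tukey(t, "sne_class", "fukui")
            rejected += anova.loc[0, "p_value"] < 0.05
        assert rejected <= 6  # ~2 expected at the 5% level
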