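import itertools

import numpy as np
import pandas as pd
import pytest

from sanqitrace.chemometrics import (
    pca_fit,
    pearson_screen,
    plsr_fit,
    round_half_up,
    saponin_summary,
    select_n_components,
    vip_select,
    VIPResult,
)
from sanqitrace.synthetic import (
    BIO_VARS,
    EQUATION_COEFFICIENTS,
    SAPONINS,
    ClimateSimConfig,
    correlated_climate_table,
    simulate_climate_table,
)


class TestPearsonScreen:
    def test_collinear_pair_loses_one_member(self):
        df = pd.DataFrame(
            {"Bio1": [1.0, 2, 3, 4], "Bio2": [2.0, 4, 6, 8], "Bio3": [1.0, 0, 1, 0]}
        )
        retained, _ = pearson_screen(df, 0.8)
        assert "Bio3" in retained
        assert len({"Bio1", "Bio2"} & set(retained)) == 1

    def test_uncorrelated_input_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=[f"Bio{i}" for i in range(1, 5)])
        retained, _ = pearson_screen(df, 0.8)
        assert retained == [f"Bio{i}" for i in range(1, 5)]

    def test_no_retained_pair_exceeds_threshold(self):
        df = correlated_climate_table(
            ClimateSimConfig(n_samples=150, seed=21),
            [("Bio1", "Bio4", 0.95), ("Bio12", "Bio17", 0.9)],
        )
        retained, corr = pearson_screen(df, 0.8)
        sub = corr.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.8

    def test_greedy_rule_matches_exhaustive_simulation(self, rng):
        """Replay of the documented elimination rule by an independent
        brute-force implementation over the same correlation matrix."""
        df = correlated_climate_table(
            ClimateSimConfig(n_samples=120, seed=33),
            [("Bio1", "Bio4", 0.92), ("Bio14", "Bio17", 0.88)],
        )
        retained, corr = pearson_screen(df, 0.8)

        names = list(corr.columns)
        keep = list(names)
        while True:
            sub = corr.loc[keep, keep].abs().to_numpy()
            np.fill_diagonal(sub, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] <= 0.8:
                break
            mi = sub[i].sum() / (len(keep) - 1)
            mj = sub[j].sum() / (len(keep) - 1)
            if mi == mj:
                drop = max(keep[i], keep[j])
            else:
                drop = keep[i] if mi > mj else keep[j]
            keep.remove(drop)
        assert retained == keep

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame(
            {"Bio1": [1.0, 2, 3, 1], "Bio2": [5.0, 5, 5, 5], "Bio3": [0.0, 1, 0, 2]}
        )
        with pytest.warns(UserWarning, match="constant"):
            retained, corr = pearson_screen(df, 0.8)
        assert "Bio2" not in retained and "Bio2" not in corr.columns


class TestSaponinSummary:
    def test_reproduces_printed_totals(self, table1_groups):
        table, printed = table1_groups
        out = saponin_summary(table)
        assert out.loc["DDB", "total"] == 16.55
        assert out.loc["DZ", "total"] == 21.53
        assert out.loc["XC", "total"] == 32.78
        assert out.loc["QB", "total"] == 22.04

    def test_single_sample_group_flagged_sd_zero(self):
        df = pd.DataFrame(
            [{"group": "solo", "NG-R1": 1.0, "G-Rg1": 2.0, "G-Rb1": 3.0, "G-Rd": 4.0}]
        )
        out = saponin_summary(df)
        assert bool(out.loc["solo", "singleton"])
        assert out.loc["solo", "NG-R1_sd"] == 0.0
        assert out.loc["solo", "total"] == 2.5

    def test_matches_groupwise_oracle(self, rng):
        df = pd.DataFrame(
            {
                "group": rng.choice(list("abc"), size=30),
                **{s: rng.normal(10, 2, size=30) for s in SAPONINS},
            }
        )
        out = saponin_summary(df)
        for g in "abc":
            sub = df[df["group"] == g]
            for s in SAPONINS:
                assert np.isclose(out.loc[g, f"{s}_mean"], sub[s].mean())
                assert np.isclose(out.loc[g, f"{s}_sd"], sub[s].std(ddof=1))

    def test_row_order_permutation_invariant(self, rng, table1_groups):
        table, _ = table1_groups
        shuffled = table.sample(frac=1.0, random_state=5)
        a = saponin_summary(table).sort_index()
        b = saponin_summary(shuffled).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_empty_saponin_value_rejected(self):
        df = pd.DataFrame(
            [{"group": "g", "NG-R1": np.nan, "G-Rg1": 1.0, "G-Rb1": 1.0, "G-Rd": 1.0}]
        )
        with pytest.raises(ValueError, match="missing"):
            saponin_summary(df)


def test_round_half_up_boundary():
    assert round_half_up(22.0375, 2) == 22.04
    assert round_half_up(16.545, 2) == 16.55


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t + 1])
        res = pca_fit(X)
        assert res.explained_variance_pct[0] == pytest.approx(100.0)

    def test_loadings_orthonormal(self, rng):
        res = pca_fit(rng.normal(size=(25, 4)))
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-10)

    def test_matches_correlation_eigenvalue_oracle(self, rng):
        X = rng.normal(size=(20, 4)) @ rng.normal(size=(4, 4))
        res = pca_fit(X)
        eig = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_pct, 100 * eig / eig.sum(), atol=1e-8
        )
        assert np.all(np.diff(res.explained_variance_pct) <= 1e-12)
        assert res.explained_variance_pct.sum() == pytest.approx(100.0)

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            pca_fit(X)


class TestPLSR:
    @pytest.mark.parametrize("saponin", SAPONINS)
    def test_full_rank_fit_recovers_printed_equation(self, saponin, noiseless_climate):
        res = plsr_fit(noiseless_climate, saponin, n_components=7)
        np.testing.assert_allclose(
            res.coefficients, EQUATION_COEFFICIENTS[saponin], atol=1e-6
        )

    def test_full_rank_pls_equals_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(scale=0.3, size=40) + 2.0
        df = pd.DataFrame(X, columns=[f"Bio{i}" for i in range(1, 6)])
        df["y"] = y
        res = plsr_fit(df, "y", predictors=list(df.columns[:5]), n_components=5)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(40), X]), y, rcond=None
        )
        np.testing.assert_allclose(res.coefficients, beta, atol=1e-8)

    def test_vip_squares_sum_to_p(self, rng):
        for seed in range(5):
            df = simulate_climate_table(ClimateSimConfig(n_samples=50, seed=seed))
            res = plsr_fit(df, "NG-R1", n_components=3)
            assert np.all(res.vip >= 0)
            assert (res.vip**2).sum() == pytest.approx(7.0, abs=1e-8)

    def test_single_driver_gets_vip_sqrt_p(self, rng):
        # centered orthonormal X (so standardization preserves
        # orthogonality), response loads on predictor 1 only, 1 component
        a = rng.normal(size=(30, 4))
        q, _ = np.linalg.qr(a - a.mean(axis=0))
        df = pd.DataFrame(q, columns=["a", "b", "c", "d"])
        df["y"] = 3.0 * q[:, 0]
        res = plsr_fit(df, "y", predictors=["a", "b", "c", "d"], n_components=1)
        assert res.vip[0] == pytest.approx(2.0, abs=1e-6)
        assert np.all(res.vip[1:] < 0.05)

    def test_parameter_recovery_under_noise(self):
        # residual sd at 5% of the response sd, n=200
        base = simulate_climate_table(ClimateSimConfig(n_samples=200, noise_sd=0.0, seed=17))
        y_sd = base["NG-R1"].std()
        df = simulate_climate_table(
            ClimateSimConfig(n_samples=200, noise_sd=float(0.05 * y_sd), seed=17)
        )
        res = plsr_fit(df, "NG-R1", n_components=7)
        truth = np.array(EQUATION_COEFFICIENTS["NG-R1"][1:])
        rel = np.abs(res.coefficients[1:] - truth) / np.abs(truth)
        assert (rel <= 0.10).sum() >= 6

    def test_component_count_bounds_enforced(self, noiseless_climate):
        with pytest.raises(ValueError, match="n_components"):
            plsr_fit(noiseless_climate, "NG-R1", n_components=8)

    def test_rank_deficient_design_rejected(self):
        df = simulate_climate_table(ClimateSimConfig(n_samples=30, noise_sd=0.0, seed=1))
        df["Bio4"] = 2.0 * df["Bio1"]  # destroy full rank
        dup = ["Bio1", "Bio4"]
        with pytest.raises(ValueError, match="rank-deficient"):
            plsr_fit(df, "NG-R1", predictors=dup, n_components=2)

    def test_loo_component_selector_finds_low_dimension(self, rng):
        # one latent direction drives y: the selector should stop early
        X = rng.normal(size=(30, 5))
        y = X[:, 0] * 2.0
        k = select_n_components(X, y, max_components=5)
        assert k <= 2


class TestVipSelect:
    def test_threshold_rule(self):
        res = VIPResult("y", ["a", "b", "c"], np.zeros(4), np.array([1.4, 0.9, 0.6]), 1)
        assert vip_select(res) == ["a"]

    def test_boundary_is_strict(self):
        res = VIPResult("y", ["a", "b"], np.zeros(3), np.array([1.0, 1.0]), 1)
        assert vip_select(res) == []

    def test_planted_strong_predictors_selected_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 5))
            y = 3 * X[:, 0] - 3 * X[:, 1] + rng.normal(scale=0.5, size=60)
            df = pd.DataFrame(X, columns=list("abcde"))
            df["y"] = y
            res = plsr_fit(df, "y", predictors=list("abcde"), n_components=2)
            sel = vip_select(res)
            hits += {"a", "b"} <= set(sel)
        assert hits == 20
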