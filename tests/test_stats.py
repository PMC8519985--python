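"""Wilcoxon screen, logistic IRLS and backward elimination."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from oracles import brute_wilcoxon, newton_logistic

from dilkit.stats import (PARAM_NAMES, VoxelTable, backward_eliminate,
                          logistic_fit, screen_parameters,
                          wilcoxon_signed_rank)
from dilkit.synthetic import (class_medians_with_contrast,
                              simulate_voxel_table)


class TestWilcoxon:
    def test_all_zero_differences(self):
        assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0

    def test_five_positive_differences_exact(self):
        # all-positive n=5: most extreme of the 2^5 sign assignments
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(2 / 32)

    def test_two_sided_symmetry_under_sign_flip(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = rng.standard_normal(9)
            assert wilcoxon_signed_rank(d) == pytest.approx(
                wilcoxon_signed_rank(-d), abs=1e-14)

    def test_exact_distribution_matches_brute_enumeration(self):
        """DP-based exact p equals exhaustive sign permutation, n <= 12."""
        rng = np.random.default_rng(1)
        for trial in range(100):
            n = rng.integers(5, 13)
            d = np.round(rng.standard_normal(n), 1)  # induces ties and zeros
            assert wilcoxon_signed_rank(d) == pytest.approx(
                brute_wilcoxon(d), abs=1e-12), f"trial {trial}: {d}"

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = rng.standard_normal(10)  # continuous, no ties
            ref = scipy.stats.wilcoxon(d, method="exact").pvalue
            assert wilcoxon_signed_rank(d) == pytest.approx(ref, abs=1e-12)

    def test_large_sample_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(40) + 0.3
        ours = wilcoxon_signed_rank(d)
        ref = scipy.stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([])


def _table_from_features(dil_vals, non_vals, n_patients):
    """Tiny voxel table with one voxel per ROI per patient per feature."""
    rows = []
    for p in range(n_patients):
        for label, vals in ((1, dil_vals), (0, non_vals)):
            row = {"patient": f"P{p:02d}", "label": label}
            row.update({name: vals[name][p] for name in PARAM_NAMES})
            rows.append(row)
    return VoxelTable(df=pd.DataFrame(rows))


class TestScreen:
    def test_bonferroni_arithmetic(self):
        """Raw p of 0.003 passes at m=13 (0.039); raw 0.02 fails (0.26)."""
        assert min(1.0, 0.003 * 13) == pytest.approx(0.039)
        rng = np.random.default_rng(4)
        vt = simulate_voxel_table(n_patients=8, voxels_per_patient=60, seed=5)
        res = screen_parameters(vt)
        np.testing.assert_allclose(
            res.table["p_adjusted"],
            np.minimum(1.0, res.table["p_raw"] * 13))
        assert res.m == 13
        for name in res.passed:
            assert res.table.loc[name, "p_adjusted"] < 0.05

    def test_null_feature_fails_screen_in_most_seeded_runs(self):
        """A parameter with identical class medians should not survive."""
        med = class_medians_with_contrast(
            [n for n in PARAM_NAMES if n != "k2"])
        fails = 0
        for seed in range(20):
            vt = simulate_voxel_table(n_patients=15, voxels_per_patient=120,
                                      class_medians=med, seed=seed)
            if "k2" not in screen_parameters(vt).passed:
                fails += 1
        assert fails >= 18  # >= 90% of runs

    def test_patient_missing_one_roi_rejected(self):
        vt = simulate_voxel_table(n_patients=4, voxels_per_patient=50, seed=6)
        df = vt.df[~((vt.df["patient"] == "P01") & (vt.df["label"] == 1))]
        broken = VoxelTable.__new__(VoxelTable)  # skip both-labels validation
        broken.df = df.reset_index(drop=True)
        broken.features = PARAM_NAMES
        with pytest.raises(ValueError, match="missing one ROI"):
            screen_parameters(broken)


class TestVoxelTable:
    def test_missing_values_rejected(self):
        vt = simulate_voxel_table(n_patients=3, voxels_per_patient=20, seed=0)
        df = vt.df.copy()
        df.loc[0, "Ki"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            VoxelTable(df=df)

    def test_single_patient_rejected(self):
        vt = simulate_voxel_table(n_patients=3, voxels_per_patient=20, seed=0)
        with pytest.raises(ValueError, match="two patients"):
            VoxelTable(df=vt.df[vt.df["patient"] == "P00"])


class TestLogistic:
    def test_null_model_recovers_prevalence_in_intercept(self):
        rng = np.random.default_rng(7)
        n = 4000
        df = pd.DataFrame({
            "patient": np.repeat(["A", "B"], n // 2),
            "label": rng.random(n) < 0.25,
            "x1": rng.standard_normal(n),
            "x2": rng.standard_normal(n)})
        df["label"] = df["label"].astype(int)
        vt = VoxelTable(df=df, features=("x1", "x2"))
        m = logistic_fit(vt, ["x1", "x2"])
        prev = df["label"].mean()
        assert m.intercept == pytest.approx(np.log(prev / (1 - prev)), abs=0.1)
        assert (m.p_values > 0.01).all()  # pure-noise slopes

    def test_eight_row_table_matches_newton_oracle(self):
        """Coefficients agree with generic high-precision ML to 1e-6."""
        X = np.array([[0.2, 1.0], [0.5, -0.4], [-1.2, 0.3], [0.8, 0.8],
                      [-0.3, -1.5], [1.5, 0.2], [-0.7, -0.2], [0.1, 0.6]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)  # not separable
        df = pd.DataFrame({"patient": ["A"] * 4 + ["B"] * 4, "label": y,
                           "f1": X[:, 0], "f2": X[:, 1]})
        vt = VoxelTable(df=df, features=("f1", "f2"))
        m = logistic_fit(vt, ["f1", "f2"])
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        ref = newton_logistic(Z, y)
        assert m.intercept == pytest.approx(ref[0], abs=1e-6)
        np.testing.assert_allclose(m.coef, ref[1:], atol=1e-6)

    def test_score_equation_for_intercept(self):
        """Mean fitted probability equals class prevalence to 1e-8."""
        vt = simulate_voxel_table(n_patients=5, voxels_per_patient=200, seed=8)
        m = logistic_fit(vt, ["Ki", "k4", "BF"])
        assert m.predict_proba(vt.df).mean() == pytest.approx(
            vt.df["label"].mean(), abs=1e-8)

    def test_duplicated_feature_column_rejected(self):
        vt = simulate_voxel_table(n_patients=4, voxels_per_patient=50, seed=9)
        df = vt.df.copy()
        df["Ki_copy"] = df["Ki"]
        vt2 = VoxelTable(df=df, features=PARAM_NAMES + ("Ki_copy",))
        with pytest.raises(ValueError, match="rank"):
            logistic_fit(vt2, ["Ki", "Ki_copy"])

    def test_matches_statsmodels_on_simulated_table(self):
        """Independent IRLS implementation agrees with statsmodels Logit."""
        import statsmodels.api as sm
        vt = simulate_voxel_table(n_patients=6, voxels_per_patient=300, seed=12)
        feats = ["Ki", "k4", "BF"]
        m = logistic_fit(vt, feats)
        X = vt.df[feats].to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        ref = sm.Logit(vt.df["label"].to_numpy(),
                       sm.add_constant(Z)).fit(disp=0)
        assert m.intercept == pytest.approx(ref.params[0], abs=1e-6)
        np.testing.assert_allclose(m.coef, ref.params[1:], atol=1e-6)
        np.testing.assert_allclose(m.p_values.to_numpy(), ref.pvalues[1:],
                                   atol=1e-6)

    def test_complete_separation_triggers_declared_ridge(self):
        df = pd.DataFrame({
            "patient": ["A", "A", "B", "B"] * 6,
            "label": [0, 0, 1, 1] * 6,
            "x": np.r_[[-2.0, -1.0, 1.0, 2.0] * 6] + np.linspace(0, 0.1, 24)})
        vt = VoxelTable(df=df, features=("x",))
        m = logistic_fit(vt, ["x"])
        assert m.ridged
        assert np.isfinite(m.coef).all()
        assert np.all((m.predict_proba(df) > 0) & (m.predict_proba(df) < 1))


class TestBackwardElimination:
    def test_pure_noise_feature_removed(self):
        med = class_medians_with_contrast(["Ki"])
        removed = 0
        for seed in range(10):
            vt = simulate_voxel_table(n_patients=10, voxels_per_patient=200,
                                      class_medians=med, seed=seed)
            m = backward_eliminate(vt, ["Ki", "T0"])
            if m.features == ("Ki",):
                removed += 1
        assert removed == 10

    def test_all_noise_features_leave_single_survivor(self):
        rng = np.random.default_rng(10)
        n = 400
        df = pd.DataFrame({
            "patient": np.repeat(["A", "B", "C", "D"], n // 4),
            "label": rng.integers(0, 2, n),
            "a": rng.standard_normal(n), "b": rng.standard_normal(n),
            "c": rng.standard_normal(n)})
        vt = VoxelTable(df=df, features=("a", "b", "c"))
        m = backward_eliminate(vt, ["a", "b", "c"], p_remove=1e-6)
        assert len(m.features) == 1

    def test_final_model_significant_or_singleton(self):
        for seed in (0, 1, 2):
            vt = simulate_voxel_table(n_patients=8, voxels_per_patient=150,
                                      seed=seed)
            m = backward_eliminate(vt, list(PARAM_NAMES))
            assert len(m.features) == 1 or (m.p_values <= 0.05).all()

    def test_empty_candidates_rejected(self):
        vt = simulate_voxel_table(n_patients=4, voxels_per_patient=50, seed=1)
        with pytest.raises(ValueError):
            backward_eliminate(vt, [])

    def test_ki_k4_contrast_selected_smoke(self):
        med = class_medians_with_contrast(["Ki", "k4"])
        vt = simulate_voxel_table(n_patients=15, voxels_per_patient=400,
                                  class_medians=med, seed=3)
        survivors = screen_parameters(vt).passed
        m = backward_eliminate(vt, survivors)
        assert set(m.features) == {"Ki", "k4"}
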