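"""Univariate workflow, LDA pre-processing, pseudo-inverse LDA, shuffle null."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from phenolda.discriminant import (
    FeatureMatrix,
    cohens_d,
    filter_correlated,
    fit_lda,
    grubbs_test,
    preprocess,
    replace_class_outliers,
    shuffle_validate,
    shuffles_for_error,
    skew_screen,
    slope_reduce,
    two_group_compare,
    zscore_features,
)
from phenolda.synthetic import (
    CohortSpec,
    VariableSpec,
    default_cohort_spec,
    gen_feature_matrix,
)


def _fm(data: np.ndarray, labels=None, columns=None) -> FeatureMatrix:
    n = len(data)
    labels = labels if labels is not None else ["a"] * (n // 2) + ["b"] * (n - n // 2)
    df = pd.DataFrame(
        data, columns=columns or [f"v{i}" for i in range(data.shape[1])]
    )
    return FeatureMatrix(df, pd.Series(labels, index=df.index))


class TestGrubbs:
    def test_single_gross_outlier_flagged(self):
        idx, g, crit = grubbs_test(np.array([1.0, 1, 1, 1, 10]))
        assert idx == 4
        assert g == pytest.approx(1.7889, abs=1e-3)
        assert crit == pytest.approx(1.7150, abs=1e-3)

    def test_symmetric_small_sample_clean(self):
        idx, _, _ = grubbs_test(np.array([-1.0, 0.0, 1.0]))
        assert idx is None

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            grubbs_test(np.ones(5))

    def test_critical_value_matches_t_closed_form_across_n(self):
        from scipy import stats

        for n in (3, 5, 10, 30):
            _, _, crit = grubbs_test(np.arange(float(n)) ** 1.3, alpha=0.05)
            t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
            expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
            assert crit == pytest.approx(expected, rel=1e-12)


class TestTwoGroupCompare:
    def test_normal_groups_use_t_test(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 15)])
        g = np.repeat(["a", "b"], 15)
        res = two_group_compare(v, g)
        assert res.test == "t-test"

    def test_lognormal_groups_use_mann_whitney(self):
        rng = np.random.default_rng(1)
        v = np.exp(np.concatenate([rng.normal(0, 3, 15), rng.normal(1, 3, 15)]))
        g = np.repeat(["a", "b"], 15)
        res = two_group_compare(v, g)
        assert res.test == "mann-whitney"

    def test_identical_groups_have_zero_effect(self):
        rng = np.random.default_rng(2)
        half = rng.normal(0, 1, 15)
        v = np.concatenate([half, half])
        res = two_group_compare(v, np.repeat(["a", "b"], 15))
        assert res.cohens_d == pytest.approx(0.0)
        assert res.p_value > 0.9

    def test_repeated_design_routes_to_mixed_anova(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(12):
            group = "a" if i < 6 else "b"
            for s in range(5):
                rows.append((f"m{i}", group, s, rng.normal(1.0 if group == "b" else 0, 1)))
        df = pd.DataFrame(rows, columns=["subject", "group", "session", "value"])
        res = two_group_compare(
            df["value"], df["group"], design="repeated",
            subjects=df["subject"], sessions=df["session"],
        )
        assert res.test == "repeated-measures-anova"
        assert np.isfinite(res.statistic)

    def test_missing_points_route_to_mixed_model(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(12):
            group = "a" if i < 6 else "b"
            for s in range(5):
                value = rng.normal(1.0 if group == "b" else 0, 1)
                rows.append((f"m{i}", group, s, value))
        df = pd.DataFrame(rows, columns=["subject", "group", "session", "value"])
        df.loc[3, "value"] = np.nan
        res = two_group_compare(
            df["value"], df["group"], design="repeated_with_missing",
            subjects=df["subject"], sessions=df["session"],
        )
        assert res.test == "mixed-model"
        assert 0 <= res.p_value <= 1


class TestSlopeReduce:
    def test_arithmetic_progression(self):
        assert slope_reduce(np.array([2.0, 4, 6, 8, 10])) == pytest.approx(2.0)

    def test_constant_values(self):
        assert slope_reduce(np.full(5, 3.0)) == pytest.approx(0.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            y = rng.normal(0, 1, int(rng.integers(2, 10)))
            x = np.arange(1, len(y) + 1, dtype=float)
            oracle = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) ** 2).sum()
            assert slope_reduce(y) == pytest.approx(oracle, abs=1e-12)

    def test_nan_sessions_omitted(self):
        assert slope_reduce(np.array([1.0, np.nan, 3.0])) == pytest.approx(1.0)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            slope_reduce(np.array([1.0, np.nan]))


class TestZScore:
    def test_columns_standardized(self):
        rng = np.random.default_rng(6)
        fm = _fm(rng.normal(5, 3, (20, 3)))
        out, dropped = zscore_features(fm)
        assert not dropped
        assert np.allclose(out.data.mean(), 0, atol=1e-12)
        assert np.allclose(out.data.std(ddof=1), 1, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 20)
        fm = _fm(np.column_stack([x, 3.5 * x + 11.0]))
        out, _ = zscore_features(fm)
        assert np.allclose(out.data["v0"], out.data["v1"], atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        fm = _fm(rng.normal(0, 1, (20, 2)))
        once, _ = zscore_features(fm)
        twice, _ = zscore_features(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_zero_variance_column_dropped_with_report(self):
        rng = np.random.default_rng(9)
        data = np.column_stack([rng.normal(0, 1, 20), np.full(20, 7.0)])
        out, dropped = zscore_features(_fm(data))
        assert dropped == ["v1"]
        assert list(out.data.columns) == ["v0"]


class TestOutlierReplacement:
    def test_zero_mad_fallback_flags_deviant(self):
        # class {0,0,0,0,100}: MAD = 0, so any value off the median is
        # flagged and replaced by the non-outlier mean (0)
        data = np.array([[0.0], [0], [0], [0], [100], [1], [1], [1], [1], [1]])
        labels = ["a"] * 5 + ["b"] * 5
        fm = _fm(data, labels)
        out, repl = replace_class_outliers(fm)
        assert out.data["v0"].iloc[4] == pytest.approx(0.0)
        assert ("4", "v0", 100.0, 0.0) in [
            (s, v, o, r) for s, v, o, r in repl
        ]

    def test_regular_spread_not_flagged(self):
        # {1..5}: max |x - 3| = 2 < 3 * 1.4826 * 1 = 4.45
        data = np.array([[1.0], [2], [3], [4], [5], [1], [2], [3], [4], [5]])
        fm = _fm(data, ["a"] * 5 + ["b"] * 5)
        _, repl = replace_class_outliers(fm)
        assert repl == []

    def test_non_flagged_values_never_altered(self):
        rng = np.random.default_rng(10)
        data = rng.normal(0, 1, (30, 4))
        data[0, 0] = 50.0
        fm = _fm(data)
        out, repl = replace_class_outliers(fm)
        flagged = {(s, v) for s, v, _, _ in repl}
        for col in fm.data.columns:
            for subj in fm.data.index:
                if (str(subj), col) not in flagged:
                    assert out.data.loc[subj, col] == fm.data.loc[subj, col]

    def test_threshold_in_scaled_mad_units(self):
        # hand computation: class values 0..8 plus 9.0; median 4.5,
        # MAD = 2.5 -> scaled 3.7065, threshold 11.1; nothing flagged
        vals = np.concatenate([np.arange(9.0), [9.0]])
        fm = _fm(vals[:, None].repeat(2, axis=1), ["a"] * 5 + ["b"] * 5)
        _, repl = replace_class_outliers(fm)
        assert repl == []


class TestSkewScreen:
    def test_lognormal_variable_flagged(self):
        from scipy import stats

        # an ideal lognormal sample (quantile grid): skewed throughout the
        # distribution, not by any single point
        q = (np.arange(30) + 0.5) / 30
        lognorm = stats.lognorm.ppf(q, 1.5)
        data = np.column_stack([stats.norm.ppf(q), lognorm])
        flagged = skew_screen(_fm(data), threshold=2.0)
        assert "v1" in flagged and "v0" not in flagged

    def test_single_outlier_does_not_masquerade_as_skew(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 30)
        x[0] = 15.0  # one aberrant point, not a skewed distribution
        flagged = skew_screen(_fm(x[:, None]), threshold=2.0)
        assert flagged == {}


class TestCorrelationFilter:
    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 40)
        fm = _fm(np.column_stack([x, x, rng.normal(0, 1, 40)]))
        out, excl = filter_correlated(fm)
        assert len(excl) == 1
        assert excl[0][2] == pytest.approx(1.0)

    def test_independent_columns_survive(self):
        rng = np.random.default_rng(14)
        fm = _fm(rng.normal(0, 1, (100, 6)))
        out, excl = filter_correlated(fm)
        assert excl == []

    def test_speed_member_dropped_distance_kept(self):
        rng = np.random.default_rng(15)
        z = rng.normal(0, 1, 100)
        speed = 0.97 * z + np.sqrt(1 - 0.97**2) * rng.normal(0, 1, 100)
        fm = _fm(
            np.column_stack([z, speed]), columns=["OF distance", "OF speed"]
        )
        out, excl = filter_correlated(fm, drop_priority=("speed",))
        assert [e[0] for e in excl] == ["OF speed"]
        assert "OF distance" in out.data.columns

    def test_tag_metadata_drives_priority(self):
        rng = np.random.default_rng(16)
        z = rng.normal(0, 1, 100)
        df = pd.DataFrame({"alpha": z, "beta": z + 0.01 * rng.normal(size=100)})
        meta = pd.DataFrame(
            {"tag": ["speed", "distance"]}, index=["alpha", "beta"]
        )
        fm = FeatureMatrix(df, pd.Series(["a"] * 50 + ["b"] * 50), meta)
        _, excl = filter_correlated(fm)
        assert [e[0] for e in excl] == ["alpha"]


class TestFitLDA:
    def test_separated_spherical_classes_align_with_axis(self):
        # exactly spherical within-class scatter: cross pattern around each
        # class mean, so the Fisher direction is the mean-difference axis
        cross = np.array([[0.3, 0], [-0.3, 0], [0, 0.3], [0, -0.3]])
        a = cross
        b = cross + [5.0, 0.0]
        fm = _fm(np.vstack([a, b]), ["a"] * 4 + ["b"] * 4)
        model = fit_lda(fm)
        contrib = model.contributions["LD1"]
        assert contrib["v0"] == pytest.approx(100.0, abs=1e-9)
        assert contrib["v1"] == pytest.approx(0.0, abs=1e-9)

    def test_identical_class_means_give_null_eigenvalues(self):
        rng = np.random.default_rng(18)
        half = rng.normal(0, 1, (20, 3))
        fm = _fm(np.vstack([half, half]), ["a"] * 20 + ["b"] * 20)
        model = fit_lda(fm)
        assert np.all(np.abs(model.eigenvalues) < 1e-10)

    def test_ld1_collinear_with_generalized_eigen_oracle(self):
        rng = np.random.default_rng(19)
        for p in (2, 3, 4, 5, 6):
            X = rng.normal(0, 1, (40, p))
            X[20:] += rng.normal(0.8, 0.2, p)
            fm = _fm(X, ["a"] * 20 + ["b"] * 20)
            model = fit_lda(fm)
            w = model.axes["LD1"].to_numpy()
            # independent oracle: scipy generalized eigenproblem on (S_B, S_W)
            vals, vecs = linalg.eig(model.s_b, model.s_w)
            lead = vecs[:, np.argmax(np.abs(vals))].real
            cos = abs(w @ lead) / (np.linalg.norm(w) * np.linalg.norm(lead))
            assert np.arccos(min(cos, 1.0)) < 1e-6

    def test_contributions_sum_to_hundred_per_axis(self):
        fm, _ = gen_feature_matrix(default_cohort_spec(seed=3))
        fm2, _ = preprocess(fm, exclude_skewed=True)
        model = fit_lda(fm2)
        assert model.contributions["LD1"].sum() == pytest.approx(100.0)
        assert model.contributions["LD2"].sum() == pytest.approx(100.0)

    def test_axes_unit_norm_and_orthogonal_projection_residual(self):
        fm, _ = gen_feature_matrix(default_cohort_spec(seed=4))
        fm2, _ = preprocess(fm, exclude_skewed=True)
        model = fit_lda(fm2)
        assert np.linalg.norm(model.axes["LD1"]) == pytest.approx(1.0)
        assert np.linalg.norm(model.axes["LD2"]) == pytest.approx(1.0)
        assert abs(model.axes["LD1"] @ model.axes["LD2"]) < 1e-8
        assert 0 <= model.explained_pct["LD1"] <= 100
        assert 0 <= model.explained_pct["LD2"] <= 100

    def test_sklearn_direction_cross_check_when_invertible(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(20)
        X = rng.normal(0, 1, (60, 4))
        X[30:, 0] += 2.0
        fm = _fm(X, ["a"] * 30 + ["b"] * 30)
        w = fit_lda(fm).axes["LD1"].to_numpy()
        skl = LinearDiscriminantAnalysis(solver="eigen").fit(
            X, np.array([0] * 30 + [1] * 30)
        )
        v = skl.scalings_[:, 0]
        cos = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
        assert cos > 1 - 1e-9


class TestShuffleValidation:
    def _null_fm(self, seed=21):
        spec = CohortSpec(
            n_per_class=10,
            variable_specs=tuple(VariableSpec(f"v{i}") for i in range(5)),
            seed=seed,
        )
        fm, _ = gen_feature_matrix(spec)
        return zscore_features(fm)[0]

    def test_seed_determinism(self):
        fm = self._null_fm()
        a = shuffle_validate(fm, n_shuffles=500, seed=1)
        b = shuffle_validate(fm, n_shuffles=500, seed=1)
        assert a.rank_freq_pct.equals(b.rank_freq_pct)
        assert a.top2_joint_pct == b.top2_joint_pct

    def test_rank_frequencies_sum_to_hundred_per_rank(self):
        fm = self._null_fm()
        rep = shuffle_validate(fm, n_shuffles=500, seed=2)
        assert np.allclose(rep.rank_freq_pct.sum(axis=0), 100.0)

    def test_strong_effect_variable_rare_under_null(self):
        spec = CohortSpec(
            n_per_class=10,
            variable_specs=(
                VariableSpec("hit", effect_d=4.0),
                *(VariableSpec(f"v{i}") for i in range(7)),
            ),
            seed=22,
        )
        fm, _ = gen_feature_matrix(spec)
        fmz, _ = zscore_features(fm)
        rep = shuffle_validate(fmz, n_shuffles=2000, seed=3)
        assert rep.observed_top[0] == "hit"
        assert rep.rank_freq_pct.loc["hit", "rank1"] < 50.0

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            shuffle_validate(self._null_fm(), n_shuffles=0, seed=0)

    def test_odd_subject_count_rejected(self):
        fm = self._null_fm()
        trimmed = FeatureMatrix(
            fm.data.iloc[:-1], fm.labels.iloc[:-1], fm.var_meta
        )
        with pytest.raises(ValueError):
            shuffle_validate(trimmed, n_shuffles=10, seed=0)

    def test_shuffle_direction_matches_full_fit(self):
        # the fast path (pinv(S_W) d with S_T rank-one update) must rank
        # variables exactly as a fresh fit_lda on the shuffled labels
        fm = self._null_fm(seed=23)
        X = fm.data.to_numpy()
        rng = np.random.default_rng(5)
        for _ in range(10):
            sel = rng.permutation(len(X))[: len(X) // 2]
            labels = np.array(["b"] * len(X), dtype=object)
            labels[sel] = "a"
            fm2 = FeatureMatrix(fm.data, pd.Series(labels, index=fm.data.index))
            model = fit_lda(fm2)
            order_full = np.argsort(-model.contributions["LD1"].to_numpy())
            mu = X.mean(axis=0)
            d = 2.0 * (X[sel].mean(axis=0) - mu)
            s_t = (X - mu).T @ (X - mu)
            s_w = s_t - len(X) / 4.0 * np.outer(d, d)
            w = np.linalg.pinv(s_w, rcond=5 * np.finfo(float).eps) @ d
            order_fast = np.argsort(-np.abs(w))
            assert list(order_full[:3]) == list(order_fast[:3])

    def test_shuffles_for_error_formula(self):
        # n >= (1-p)/(p * rel^2): p = 0.002, rel = 0.05 -> 199,600
        assert shuffles_for_error(0.002, 0.05) == 199600
        with pytest.raises(ValueError):
            shuffles_for_error(0.0, 0.05)


class TestPreprocessPipeline:
    def test_default_cohort_shape_and_reports(self):
        fm, truth = gen_feature_matrix(default_cohort_spec(seed=1))
        fm2, report = preprocess(fm, exclude_skewed=True)
        assert len(report.slope_reduced) == 7  # rotarod + six ladder measures
        assert "YM reversal II" in report.skew_flagged
        assert {e[0] for e in report.correlation_excluded} <= {
            "OF speed", "EPM speed", "SI speed", "YM speed",
        }
        assert report.final_variables == fm2.data.shape[1]
        assert not fm2.data.isna().any().any()

    def test_exclusions_accounted_for(self):
        fm, _ = gen_feature_matrix(default_cohort_spec(seed=2))
        fm2, r = preprocess(fm, exclude_skewed=True)
        n_sessions_removed = sum(len(v) - 1 for v in r.slope_reduced.values())
        assert r.initial_variables - n_sessions_removed - len(r.skew_excluded) - len(
            r.zero_variance_excluded
        ) - len(r.correlation_excluded) == r.final_variables


def test_cohens_d_pooled_convention():
    a = np.array([1.0, 2, 3, 4, 5])
    b = a + 2.0
    assert cohens_d(b, a) == pytest.approx(2.0 / np.std(a, ddof=1))
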