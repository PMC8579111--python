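"""Generators: determinism, injected-structure recovery, protocol shapes."""

import numpy as np
import pytest
import shapely

from phenolda.arena import compute_kinematics, make_layout
from phenolda.discriminant import slope_reduce
from phenolda.synthetic import (
    CohortSpec,
    TrackingProfile,
    VariableSpec,
    default_cohort_spec,
    gen_feature_matrix,
    gen_grooming_log,
    gen_ladder_sessions,
    gen_tracking_series,
    gen_visuomotor_session,
    gen_ymaze_choices,
)


def _sample_d(fm, name):
    labels = fm.labels
    a = fm.data[name][labels == "class1"]
    b = fm.data[name][labels == "class2"]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    return (b.mean() - a.mean()) / pooled


class TestFeatureMatrix:
    def test_identical_seeds_bit_identical(self):
        spec = default_cohort_spec(seed=12)
        a, _ = gen_feature_matrix(spec)
        b, _ = gen_feature_matrix(spec)
        assert a.data.equals(b.data)
        assert a.labels.equals(b.labels)

    def test_adding_subjects_preserves_existing_rows(self):
        small, _ = gen_feature_matrix(default_cohort_spec(n_per_class=10, seed=5))
        large, _ = gen_feature_matrix(default_cohort_spec(n_per_class=15, seed=5))
        for cls, n_small in (("class1", 10), ("class2", 10)):
            s = small.data[small.labels == cls]
            l = large.data[large.labels == cls]
            assert np.allclose(s.to_numpy(), l.to_numpy()[:n_small], equal_nan=True)

    def test_row_count_and_session_columns(self):
        fm, _ = gen_feature_matrix(default_cohort_spec(seed=0))
        assert fm.data.shape[0] == 30
        el = [c for c in fm.data.columns if c.startswith("EL time on ladder")]
        assert len(el) == 5
        assert fm.var_meta.loc[el[0], "multi_session"]

    def test_null_spec_has_no_class_separation(self):
        spec = CohortSpec(
            n_per_class=15, variable_specs=(VariableSpec("v0"),), seed=42
        )
        fm, truth = gen_feature_matrix(spec)
        assert truth.effects["v0"] == 0
        assert abs(_sample_d(fm, "v0")) < 0.5  # Monte-Carlo-sized deviation only
        # and the deviation is pure sampling noise: it averages out over seeds
        ds = []
        for seed in range(20):
            fm_k, _ = gen_feature_matrix(
                CohortSpec(n_per_class=15, variable_specs=(VariableSpec("v0"),), seed=seed)
            )
            ds.append(_sample_d(fm_k, "v0"))
        assert abs(np.mean(ds)) < 0.25  # 3 sigma of the seed-mean

    def test_large_effect_recovered_within_sampling_band(self):
        spec = CohortSpec(
            n_per_class=50,
            variable_specs=(VariableSpec("hit", effect_d=3.0), VariableSpec("null")),
            seed=7,
        )
        fm, _ = gen_feature_matrix(spec)
        assert 2.4 <= _sample_d(fm, "hit") <= 3.6

    def test_slope_effect_recovered_on_multi_session_variable(self):
        spec = CohortSpec(
            n_per_class=50,
            variable_specs=(
                VariableSpec("learn", multi_session=True, n_sessions=5, effect_d=2.0),
            ),
            seed=8,
        )
        fm, _ = gen_feature_matrix(spec)
        cols = [f"learn::s{k}" for k in range(1, 6)]
        slopes = fm.data[cols].apply(lambda r: slope_reduce(r.to_numpy()), axis=1)
        a = slopes[fm.labels == "class1"]
        b = slopes[fm.labels == "class2"]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        d_hat = (b.mean() - a.mean()) / pooled
        assert 1.4 <= d_hat <= 2.6

    def test_correlated_block_reaches_filter_threshold(self):
        spec = CohortSpec(
            n_per_class=50,
            variable_specs=(VariableSpec("OF distance"), VariableSpec("OF speed")),
            correlated_blocks=((("OF distance", "OF speed"), 0.95),),
            seed=9,
        )
        fm, truth = gen_feature_matrix(spec)
        r = fm.data["OF distance"].corr(fm.data["OF speed"])
        assert r >= 0.86  # Fisher-z band at n=100 keeps 0.95 well above 0.86
        assert truth.correlations[("OF distance", "OF speed")] == 0.95

    def test_injected_outliers_recorded_and_extreme(self):
        spec = CohortSpec(
            n_per_class=30,
            variable_specs=tuple(VariableSpec(f"v{i}") for i in range(10)),
            outlier_rate=0.05,
            seed=10,
        )
        fm, truth = gen_feature_matrix(spec)
        assert truth.outliers
        for subject, var in truth.outliers:
            assert abs(fm.data.loc[subject, var]) > 4.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_class=1, variable_specs=(VariableSpec("v"),))
        with pytest.raises(ValueError):
            VariableSpec("v", sd=0.0)
        with pytest.raises(ValueError):
            CohortSpec(
                n_per_class=5,
                variable_specs=(VariableSpec("a"), VariableSpec("a")),
            )
        with pytest.raises(ValueError):
            CohortSpec(
                n_per_class=5,
                variable_specs=(VariableSpec("a"), VariableSpec("b")),
                correlated_blocks=((("a", "b"), 1.0),),
            )


class TestTracking:
    def test_stationary_profile_zero_distance(self):
        layout = make_layout("open_field")
        s = gen_tracking_series(
            layout, TrackingProfile(mean_speed=0.0, duration=10.0), seed=0
        )
        distance, _, _ = compute_kinematics(s)
        assert distance == 0.0

    def test_sample_count_is_duration_times_fps(self):
        layout = make_layout("open_field")
        s = gen_tracking_series(
            layout, TrackingProfile(duration=60.0, fps=25.0), seed=1
        )
        assert s.n_frames == 1500

    def test_positions_stay_inside_arena(self):
        layout = make_layout("open_field")
        s = gen_tracking_series(
            layout, TrackingProfile(duration=120.0, thigmotaxis=0.8), seed=2
        )
        pts = shapely.points(s.body_x, s.body_y)
        assert shapely.covers(layout.arena, pts).all()

    def test_mean_speed_within_ten_percent(self):
        layout = make_layout("open_field")
        profile = TrackingProfile(mean_speed=8.0, duration=300.0)
        s = gen_tracking_series(layout, profile, seed=3)
        _, _, mean_speed = compute_kinematics(s)
        assert abs(mean_speed - 8.0) / 8.0 < 0.10

    def _outer_fraction(self, series, layout):
        from phenolda.arena import roi_occupancy

        occ = roi_occupancy(series, layout)
        outer = sum(
            occ.roi_time[n]
            for n in occ.roi_time
            if layout.rois[n].role in {"outer", "corner"}
        )
        return outer / sum(occ.roi_time.values())

    def test_thigmotaxis_weight_orders_wall_occupancy(self):
        layout = make_layout("open_field")
        hug = gen_tracking_series(
            layout, TrackingProfile(duration=300.0, thigmotaxis=1.0), seed=4
        )
        roam = gen_tracking_series(
            layout, TrackingProfile(duration=300.0, thigmotaxis=0.0), seed=4
        )
        f_hug = self._outer_fraction(hug, layout)
        f_roam = self._outer_fraction(roam, layout)
        assert f_hug > f_roam
        assert f_hug >= 0.80


class TestGroomingGenerator:
    def test_zero_rate_empty_log(self):
        log, _ = gen_grooming_log(0.0, seed=0)
        assert log.bouts == []

    def test_bout_count_in_poisson_band(self):
        # rate 1/min over 30 min: Poisson(30), central 95% band [19, 41]
        inside = 0
        for seed in range(40):
            log, _ = gen_grooming_log(1.0, total_duration_s=1800.0, seed=seed)
            inside += 19 <= len(log.bouts) <= 41
        assert inside >= 37

    def test_pure_short_mixture_stays_below_threshold(self):
        log, _ = gen_grooming_log(
            2.0, mixture_weights=(1.0, 0.0), short_mean_s=4.0, seed=1
        )
        assert log.bouts
        assert all(b.duration < 10.0 for b in log.bouts)

    def test_bouts_sorted_and_non_overlapping(self):
        log, truth = gen_grooming_log(1.5, seed=2)
        for a, b in zip(log.bouts, log.bouts[1:]):
            assert b.start >= a.stop
        assert len(truth.bout_intervals) == len(log.bouts)

    def test_unpackable_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_grooming_log(10.0, mixture_weights=(0.0, 1.0), long_mean_s=30.0)


class TestLadderGenerator:
    def test_protocol_shape(self):
        model = [{"before_cue": 0.1, "light": 0.3, "air": 0.6}] * 5
        trials, _ = gen_ladder_sessions(model, seed=0)
        assert len(trials) == 5 * 42
        assert {t.session for t in trials} == {1, 2, 3, 4, 5}
        for t in trials:
            assert t.air_onset_s == pytest.approx(t.light_onset_s + 3.0)

    def test_determinism(self):
        model = [{"before_cue": 0.1, "light": 0.3, "air": 0.6}] * 5
        a, _ = gen_ladder_sessions(model, seed=3)
        b, _ = gen_ladder_sessions(model, seed=3)
        assert [(t.exit_time_s, t.steps) for t in a] == [
            (t.exit_time_s, t.steps) for t in b
        ]

    def test_malformed_probabilities_rejected(self):
        with pytest.raises(ValueError):
            gen_ladder_sessions([{"before_cue": 0.5, "light": 0.6, "air": 0.1}] * 5)


class TestYMazeGenerator:
    def test_protocol_counts(self):
        p = {"acquisition": [0.5] * 4, "test": [0.5], "reversal1": [0.5] * 5,
             "reversal2": [0.5] * 5}
        trials, _ = gen_ymaze_choices(p, seed=0)
        phases = {}
        for t in trials:
            phases.setdefault(t.phase, set()).add((t.session, t.trial))
        assert len(phases["acquisition"]) == 20
        assert len(phases["test"]) == 5
        assert len(phases["reversal1"]) == 25
        forced = [t for t in trials if t.forced]
        assert all(t.session == 5 for t in forced)
        assert len(forced) == 10

    def test_out_of_range_probability_rejected(self):
        p = {"acquisition": [1.5] * 4, "test": [1.0], "reversal1": [1.0] * 5,
             "reversal2": [1.0] * 5}
        with pytest.raises(ValueError):
            gen_ymaze_choices(p)


class TestVisuomotorGenerator:
    def test_determinism(self):
        a, ta = gen_visuomotor_session("anti_saccade", seed=6)
        b, tb = gen_visuomotor_session("anti_saccade", seed=6)
        assert ta.saccade_onsets_ms == tb.saccade_onsets_ms
        assert all(np.array_equal(x.gaze, y.gaze) for x, y in zip(a, b))

    def test_speed_profile_brackets_threshold(self):
        from phenolda.visuomotor import gaze_speed

        trials, truth = gen_visuomotor_session("pro_saccade", n_trials=8, seed=7)
        for i, trial in enumerate(trials):
            speed = gaze_speed(trial.gaze)
            t = trial.gaze[:-1, 0]
            onset = truth.saccade_onsets_ms[i]
            in_saccade = (t >= onset - 1e-9) & (t < onset + 5 * 1000 / 120.0)
            assert speed[in_saccade].max() > 50.0
            assert speed[~in_saccade].max() < 50.0
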