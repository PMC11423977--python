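"""Grid alignment, gap handling, normalization and windowing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cgmbench as cb
from cgmbench.preprocess import GriddedSeries, partition_segments


def _trace(times, values, pid="p"):
    return cb.GlucoseTrace(pid, "c", "adult", "F",
                           times=np.asarray(times), values=np.asarray(values, float))


class TestAlignToGrid:
    def test_regular_input_is_identity(self):
        g = cb.align_to_grid(_trace([0, 5, 10, 15], [100, 110, 120, 130]))
        np.testing.assert_array_equal(g.values, [100, 110, 120, 130])
        assert not g.missing.any()

    def test_interior_gap_marked_missing(self):
        g = cb.align_to_grid(_trace([0, 5, 15], [100, 110, 130]))
        assert len(g.values) == 4
        assert list(g.missing) == [False, False, True, False]

    def test_single_sample(self):
        g = cb.align_to_grid(_trace([7], [100]))
        assert len(g.values) == 1 and not g.missing.any()

    def test_off_grid_snaps_to_nearest_with_tie_toward_earlier(self):
        # offsets 0, 6, 12.5 -> slots 0, 1, 2 (12.5 is midway, earlier slot wins)
        g = cb.align_to_grid(_trace([0, 6, 12.5], [1, 2, 3]))
        np.testing.assert_array_equal(g.values, [1, 2, 3])

    def test_duplicate_timestamps_error_names_patient(self):
        with pytest.raises(ValueError, match="px"):
            cb.align_to_grid(_trace([0, 0, 5], [1, 2, 3], pid="px"))


class TestImputeAndSegment:
    def test_linear_interpolation_of_short_gap(self):
        g = cb.align_to_grid(_trace([0, 15], [100, 130]))
        segs = cb.impute_and_segment(g)
        assert len(segs) == 1
        np.testing.assert_allclose(segs[0].values, [100, 110, 120, 130])
        assert list(segs[0].imputed_mask) == [False, True, True, False]

    def test_gap_over_an_hour_splits_without_fabrication(self):
        # 13 missing slots = 65 min: strictly over an hour, so split
        values = np.full(30, np.nan)
        values[:8] = 100.0
        values[21:] = 150.0
        segs = cb.impute_and_segment(GriddedSeries("p", 0, values))
        assert len(segs) == 2
        assert len(segs[0]) == 8 and len(segs[1]) == 9
        assert sum(len(s) for s in segs) == 17      # none of the 13 slots kept

    def test_exactly_one_hour_gap_is_interpolated(self):
        values = np.full(20, np.nan)
        values[:4] = 100.0
        values[16:] = 160.0
        segs = cb.impute_and_segment(GriddedSeries("p", 0, values))
        assert len(segs) == 1 and len(segs[0]) == 20

    def test_fully_observed_is_noop(self):
        segs = cb.impute_and_segment(GriddedSeries("p", 0, np.arange(10.0)))
        assert len(segs) == 1 and not segs[0].imputed_mask.any()

    def test_leading_trailing_missing_dropped(self):
        values = np.full(10, np.nan)
        values[3:7] = 5.0
        segs = cb.impute_and_segment(GriddedSeries("p", 0, values))
        assert len(segs) == 1 and len(segs[0]) == 4
        assert segs[0].start_time == 15

    @given(slope=st.floats(-5, 5), intercept=st.floats(50, 300),
           gap_start=st.integers(2, 20), gap_len=st.integers(1, 12))
    @settings(max_examples=50, deadline=None)
    def test_affine_signals_interpolate_exactly(self, slope, intercept,
                                                gap_start, gap_len):
        """Linear interpolation is exact on any affine signal with interior gaps."""
        n = 40
        truth = intercept + slope * np.arange(n)
        values = truth.copy()
        values[gap_start:gap_start + gap_len] = np.nan
        segs = cb.impute_and_segment(GriddedSeries("p", 0, values))
        assert len(segs) == 1
        np.testing.assert_allclose(segs[0].values, truth, atol=1e-9)


class TestNormalizer:
    def test_hand_example(self):
        seg = cb.Segment("p", 0, np.array([100.0, 150.0, 200.0]), np.zeros(3, bool))
        params = cb.fit_normalizer([seg])
        assert params.mu == pytest.approx(150.0)
        assert params.sigma == pytest.approx(40.8248, abs=1e-4)
        assert cb.apply_normalizer(params, 190.0) == pytest.approx(0.9798, abs=1e-4)
        assert cb.apply_normalizer(params, params.mu) == pytest.approx(0.0)

    def test_round_trip(self, rng):
        seg = cb.Segment("p", 0, rng.uniform(60, 350, 100), np.zeros(100, bool))
        params = cb.fit_normalizer([seg])
        x = rng.uniform(40, 400, 50)
        np.testing.assert_allclose(
            cb.invert_normalizer(params, cb.apply_normalizer(params, x)), x,
            atol=1e-9)

    def test_training_data_standardized(self, small_datasets):
        params = small_datasets["params"]
        pooled = np.concatenate([s.values for s in small_datasets["segments"]["train"]])
        z = cb.apply_normalizer(params, pooled)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_training_data_rejected(self):
        seg = cb.Segment("p", 0, np.full(10, 120.0), np.zeros(10, bool))
        with pytest.raises(ValueError):
            cb.fit_normalizer([seg])


class TestSplit:
    def test_patient_partition_80_20(self, small_cohort):
        plan = cb.split_cohort(small_cohort, seed=0)
        assert len(plan.test_patients) == 2          # 20% of 8
        assert len(plan.train_patients) == 6
        assert not set(plan.train_patients) & set(plan.test_patients)

    def test_single_patient_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            cb.split_cohort(small_cohort[:1])

    def test_validation_is_chronological_tail(self):
        seg = cb.Segment("a", 0, np.arange(1000.0) + 100, np.zeros(1000, bool))
        other = cb.Segment("b", 0, np.arange(100.0) + 100, np.zeros(100, bool))
        plan = cb.SplitPlan(train_patients=["a"], test_patients=["b"])
        parts = partition_segments(plan, {"a": [seg], "b": [other]})
        assert sum(len(s) for s in parts["val"]) == 200
        assert parts["val"][0].start_time == 800 * 5
        assert parts["val"][0].values[0] == seg.values[800]

    def test_no_patient_leakage_into_test_windows(self, small_datasets):
        train_ids = set(small_datasets["windows"]["train"][6].patient_ids)
        test_ids = set(small_datasets["windows"]["test"][6].patient_ids)
        assert not train_ids & test_ids

    def test_ohio_mode_keeps_patients_in_both_sides(self, small_cohort):
        ds = cb.build_datasets(small_cohort, L=24, horizons=[6], seed=0,
                               ohio_mode=True)
        train_ids = set(ds["windows"]["train"][6].patient_ids)
        test_ids = set(ds["windows"]["test"][6].patient_ids)
        assert train_ids and train_ids == test_ids


class TestWindows:
    @pytest.mark.parametrize("n, L, p, expected", [
        (30, 24, 6, 1), (100, 24, 12, 65), (29, 24, 6, 0), (24, 24, 1, 0),
    ])
    def test_window_count_formula(self, n, L, p, expected):
        seg = cb.Segment("p", 0, np.linspace(80, 300, n), np.zeros(n, bool))
        ws = cb.make_windows([seg], L=L, horizons=[p])[p]
        assert ws.n_windows == expected

    @given(n=st.integers(1, 120), L=st.integers(1, 30), p=st.integers(1, 15))
    @settings(max_examples=60, deadline=None)
    def test_window_count_formula_randomized(self, n, L, p):
        seg = cb.Segment("s", 0, np.linspace(80, 300, n), np.zeros(n, bool))
        ws = cb.make_windows([seg], L=L, horizons=[p])[p]
        assert ws.n_windows == max(0, n - L - p + 1)

    def test_window_contents_align_with_segment(self):
        seg = cb.Segment("p", 0, np.arange(40.0) + 100, np.zeros(40, bool))
        ws = cb.make_windows([seg], L=24, horizons=[6])[6]
        np.testing.assert_allclose(ws.inputs[0], seg.values[:24])
        assert ws.targets[0] == seg.values[29]        # step t + p
        np.testing.assert_allclose(ws.inputs[-1], seg.values[10:34])
        assert ws.targets[-1] == seg.values[39]

    def test_windows_never_cross_segments(self):
        segs = [cb.Segment("p", 0, np.arange(30.0) + 100, np.zeros(30, bool)),
                cb.Segment("p", 500, np.arange(30.0) + 200, np.zeros(30, bool))]
        ws = cb.make_windows(segs, L=24, horizons=[6])[6]
        assert ws.n_windows == 2
        assert ws.inputs[0].max() < 200 and ws.inputs[1].min() >= 200

    def test_invalid_L_or_horizon(self):
        seg = cb.Segment("p", 0, np.arange(30.0), np.zeros(30, bool))
        with pytest.raises(ValueError):
            cb.make_windows([seg], L=0, horizons=[6])
        with pytest.raises(ValueError):
            cb.make_windows([seg], L=24, horizons=[0])


def test_count_conservation(small_cohort):
    """Observed samples = kept non-imputed samples + samples in dropped regions."""
    for trace in small_cohort:
        gridded = cb.align_to_grid(trace)
        segs = cb.impute_and_segment(gridded)
        kept_observed = sum(int((~s.imputed_mask).sum()) for s in segs)
        # every observed sample either lands in a segment or is dropped
        # with a long-gap / leading / trailing region
        n_observed = int((~gridded.missing).sum())
        assert kept_observed <= n_observed == len(trace)
        dropped = n_observed - kept_observed
        in_segments = sum(len(s) for s in segs)
        assert in_segments + dropped + int(gridded.missing.sum()) \
            - sum(int(s.imputed_mask.sum()) for s in segs) == len(gridded.values)
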