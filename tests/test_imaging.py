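"""Two-photon pipeline tests: registration, masks, dF/F, epochs, maps."""

import numpy as np
import pandas as pd
import pytest

from dnflight import imaging as img
from dnflight import synthetic as syn
from conftest import extract_dff_traces


def tiny_movie(T=40, H=16, W=32, seed=0, jitter=0):
    """Small two-arbor movie built directly (independent of the generator)."""
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[:H, :W]
    blob_l = np.exp(-0.5 * (((y - 8) / 2.0) ** 2 + ((x - 8) / 3.0) ** 2))
    blob_r = np.exp(-0.5 * (((y - 8) / 2.0) ** 2 + ((x - 24) / 3.0) ** 2))
    act = 1.0 + 0.5 * np.sin(np.arange(T))
    gcamp = 5.0 + 50.0 * act[:, None, None] * blob_l + 30.0 * blob_r
    tdtom = np.broadcast_to(5.0 + 80.0 * blob_l + 50.0 * blob_r, (T, H, W)).copy()
    if jitter:
        # zero-mean jitter: the trial-average reference then sits on the
        # unshifted grid and exact shift recovery is well defined
        half = rng.integers(-jitter, jitter + 1, (T // 2, 2))
        shifts = np.concatenate([half, -half])[rng.permutation(T)]
    else:
        shifts = np.zeros((T, 2), int)
    if jitter:
        for k in range(T):
            gcamp[k] = img._integer_shift(gcamp[k], *shifts[k], 5.0)
            tdtom[k] = img._integer_shift(tdtom[k], *shifts[k], 5.0)
    movie = img.TwoChannelMovie(gcamp=gcamp, tdtom=tdtom, frame_rate=10.0)
    return movie, shifts


class TestRegistration:
    def test_aligned_movie_zero_shifts(self):
        movie, _ = tiny_movie()
        _, shifts = img.register_to_reference(movie)
        assert np.all(shifts == 0)

    def test_recovers_injected_shifts_exactly(self):
        movie, injected = tiny_movie(jitter=3, seed=4)
        registered, shifts = img.register_to_reference(movie)
        np.testing.assert_array_equal(shifts, -injected)

    def test_idempotent(self):
        movie, _ = tiny_movie(jitter=3, seed=4)
        registered, _ = img.register_to_reference(movie)
        _, second = img.register_to_reference(registered)
        assert np.all(second == 0)

    def test_zero_contrast_frame_warns(self):
        movie, _ = tiny_movie()
        movie.tdtom[5] = 0.0
        with pytest.warns(UserWarning, match="no contrast"):
            _, shifts = img.register_to_reference(movie)
        assert tuple(shifts[5]) == (0, 0)

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            img.TwoChannelMovie(gcamp=np.zeros((4, 8, 8)), tdtom=np.zeros((4, 8, 6)),
                                frame_rate=10.0)


class TestMasks:
    def test_roi_sizes_floor_counts(self):
        movie, _ = tiny_movie()
        left, right = img.select_variable_rois(movie.gcamp)
        H, W = movie.gcamp.shape[1:]
        assert left.sum() == right.sum() == int(np.floor(0.2 * H * (W // 2)))
        assert not (left & right).any()
        assert not left[:, W // 2:].any() and not right[:, :W // 2].any()

    def test_fluctuating_blob_captured(self):
        movie, _ = tiny_movie()
        left, _ = img.select_variable_rois(movie.gcamp)
        # the left blob is the only fluctuating structure: selected pixels
        # must carry non-trivial blob weight
        y, x = np.mgrid[:16, :32]
        blob = np.exp(-0.5 * (((y - 8) / 2.0) ** 2 + ((x - 8) / 3.0) ** 2))
        assert blob[left].min() > blob[:, :16][~left[:, :16]].max() * 0.99

    def test_offset_invariance(self):
        movie, _ = tiny_movie()
        l1, r1 = img.select_variable_rois(movie.gcamp)
        l2, r2 = img.select_variable_rois(movie.gcamp + 123.0)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(r1, r2)

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError, match="variability"):
            img.select_variable_rois(np.ones((5, 8, 8)))

    def test_background_size_and_ties(self):
        stack = np.ones((3, 10, 10))
        bg = img.select_background(stack)
        assert bg.sum() == 20
        # uniform image: ties resolved in raster order
        np.testing.assert_array_equal(np.flatnonzero(bg.ravel()), np.arange(20))

    def test_dark_border_selected(self):
        stack = np.full((3, 10, 10), 100.0)
        stack[:, 0, :] = 1.0
        stack[:, -1, :] = 1.0
        bg = img.select_background(stack)
        assert bg[0].all() and bg[-1].all()


class TestTraces:
    def test_roi_equals_background_gives_zero(self):
        stack = np.random.default_rng(0).uniform(1, 2, (5, 6, 6))
        mask = np.zeros((6, 6), bool)
        mask[0, :3] = True
        same_vals = np.zeros((6, 6), bool)
        same_vals[0, :3] = True
        F = img.roi_fluorescence(stack, mask, same_vals)
        np.testing.assert_allclose(F, 0.0)

    def test_constant_levels(self):
        stack = np.full((4, 6, 6), 10.0)
        roi = np.zeros((6, 6), bool)
        roi[2:4, 2:4] = True
        stack[:, roi] = 100.0
        bg = np.zeros((6, 6), bool)
        bg[0, :] = True
        np.testing.assert_allclose(img.roi_fluorescence(stack, roi, bg), 90.0)

    def test_two_loop_oracle(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 50, (6, 8, 8))
        roi = rng.uniform(size=(8, 8)) > 0.6
        bg = ~roi
        F = img.roi_fluorescence(stack, roi, bg)
        for k in range(6):
            roi_sum = bg_sum = 0.0
            for i in range(8):
                for j in range(8):
                    if roi[i, j]:
                        roi_sum += stack[k, i, j]
                    else:
                        bg_sum += stack[k, i, j]
            assert F[k] == pytest.approx(roi_sum / roi.sum() - bg_sum / bg.sum(), rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            img.roi_fluorescence(np.ones((3, 4, 4)), np.zeros((4, 4), bool),
                                 np.ones((4, 4), bool))

    def test_ratio_constant_denominator(self):
        G = np.array([1.0, 2.0, 3.0])
        R = np.array([2.0, 2.0, 2.0])
        np.testing.assert_allclose(img.ratio_normalize(G, R), G / 2.0)

    def test_ratio_cancels_shared_gain(self):
        rng = np.random.default_rng(2)
        G = rng.uniform(1, 5, 50)
        R = rng.uniform(1, 5, 50)
        z = rng.uniform(0.8, 1.2, 50)  # z-drift multiplies both channels
        np.testing.assert_allclose(img.ratio_normalize(G * z, R * z),
                                   img.ratio_normalize(G, R), rtol=1e-12)

    def test_ratio_bad_denominator_rejected(self):
        with pytest.raises(ValueError, match="median"):
            img.ratio_normalize(np.ones(5), np.full(5, -1.0))

    def test_baseline_f0(self):
        assert img.baseline_f0(np.full(20, 7.0)) == 7.0
        assert img.baseline_f0(np.arange(1.0, 11.0)) == 1.0
        rng = np.random.default_rng(3)
        F = rng.normal(size=200)
        k = int(0.1 * 200)
        assert img.baseline_f0(F) == pytest.approx(np.mean(np.sort(F)[:k]), rel=1e-12)

    def test_dff_max_is_one_and_affine_invariance(self):
        rng = np.random.default_rng(4)
        F = rng.uniform(10, 50, 100)
        d1 = img.normalized_dff(F, img.baseline_f0(F))
        assert d1.max() == 1.0
        F2 = 3.7 * F + 11.0
        d2 = img.normalized_dff(F2, img.baseline_f0(F2))
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_dff_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            img.normalized_dff(np.full(10, 2.0), 2.0)


class TestLagCorrection:
    def test_zero_lag_identity(self):
        b = img.BehaviorTrace(t=np.arange(64) / 32.0, wba_left=np.arange(64.0),
                              wba_right=np.arange(64.0))
        c = img.lag_correct_behavior(b, 0.0)
        np.testing.assert_array_equal(c.wba_left, b.wba_left)
        assert c.lag_corrected

    def test_sinusoid_phase_advance(self):
        # 30 ms lag on a 1 Hz sinusoid: corrected(t) = reported(t + lag)
        t = np.arange(0, 20, 1 / 32.0)
        b = img.BehaviorTrace(t=t, wba_left=np.sin(2 * np.pi * t),
                              wba_right=np.cos(2 * np.pi * t))
        c = img.lag_correct_behavior(b, 0.030)
        interior = (t > 1) & (t < 19)
        np.testing.assert_allclose(c.wba_left[interior],
                                   np.sin(2 * np.pi * (t[interior] + 0.030)),
                                   atol=2e-3)

    def test_double_correction_rejected(self):
        b = img.BehaviorTrace(t=np.arange(64) / 32.0, wba_left=np.zeros(64),
                              wba_right=np.zeros(64))
        c = img.lag_correct_behavior(b)
        with pytest.raises(ValueError, match="already"):
            img.lag_correct_behavior(c)


class TestEpochAverage:
    def _protocol(self):
        return img.StimulusProtocol(epochs=pd.DataFrame({
            "pattern_id": ["YR", "YL", "YR"],
            "onset_s": [5.0, 15.0, 25.0],
            "duration_s": [3.0, 3.0, 3.0]}))

    def test_identical_epochs_zero_ci_width(self):
        t = np.arange(0, 35, 0.1)
        sig = np.zeros_like(t)
        for onset in (5.0, 25.0):
            sig[(t >= onset) & (t < onset + 3)] = 2.0
        avg = img.epoch_average(sig, t, self._protocol(), "YR", n_boot=200, seed=0)
        assert avg.n == 2
        np.testing.assert_allclose(avg.ci_hi - avg.ci_lo, 0.0, atol=1e-12)

    def test_constant_shift_moves_mean_not_ci_width(self):
        t = np.arange(0, 35, 0.1)
        rng = np.random.default_rng(0)
        sig = rng.normal(size=t.size)
        a1 = img.epoch_average(sig, t, self._protocol(), "YR", n_boot=200, seed=1)
        a2 = img.epoch_average(sig + 10.0, t, self._protocol(), "YR", n_boot=200, seed=1)
        # per-epoch baseline subtraction removes the shift entirely
        np.testing.assert_allclose(a1.mean, a2.mean, atol=1e-12)
        np.testing.assert_allclose(a1.ci_hi - a1.ci_lo, a2.ci_hi - a2.ci_lo, atol=1e-12)

    def test_absent_pattern_rejected(self):
        t = np.arange(0, 35, 0.1)
        with pytest.raises(ValueError, match="absent"):
            img.epoch_average(np.zeros_like(t), t, self._protocol(), "PU")

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(7)
        samples = rng.normal(size=(20, 30))
        m1, lo1, hi1 = img.bootstrap_mean_ci(samples, n_boot=500, seed=42)
        m2, lo2, hi2 = img.bootstrap_mean_ci(samples, n_boot=500, seed=42)
        np.testing.assert_array_equal(lo1, lo2)
        np.testing.assert_array_equal(hi1, hi2)


class TestTuningCurve:
    def test_positive_coupling_monotone(self):
        rng = np.random.default_rng(0)
        dff = rng.uniform(0, 1, 4000)
        wba = 150.0 + 20.0 * dff + rng.normal(0, 1.0, 4000)
        curve = img.tuning_curve(dff, wba, n_bins=8, seed=0)
        assert np.all(np.diff(curve.mean) > 0)
        assert curve.n_per_bin.sum() == 4000

    def test_independent_signals_flat(self):
        rng = np.random.default_rng(1)
        dff = rng.uniform(0, 1, 4000)
        wba = rng.normal(150, 5, 4000)
        curve = img.tuning_curve(dff, wba, n_bins=8, seed=0)
        inside = (curve.ci_lo <= 0) & (0 <= curve.ci_hi)
        assert inside.sum() >= 6  # most bins contain the null mean

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="z-score"):
            img.tuning_curve(np.ones(100), np.random.default_rng(0).normal(size=100))


class TestPixelCorrelation:
    def test_perfect_pixel_correlations(self):
        rng = np.random.default_rng(0)
        wba_l = rng.normal(150, 5, 50)
        wba_r = rng.normal(150, 5, 50)
        stack = rng.normal(size=(50, 4, 4))
        stack[:, 0, 0] = wba_l          # pixel equal to left amplitude
        stack[:, 1, 1] = -wba_r         # pixel equal to minus right amplitude
        stack[:, 2, 2] = 3.0            # zero-variance pixel
        maps = img.pixel_correlation_map(stack, wba_l, wba_r)
        assert maps.r_left[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert maps.r_right[1, 1] == pytest.approx(-1.0, abs=1e-12)
        assert maps.r_left[2, 2] == 0.0 and not maps.valid[2, 2]
        assert np.all(np.abs(maps.r_left) <= 1.0) and np.all(np.abs(maps.r_right) <= 1.0)

    def test_contralateral_sign_structure(self, noiseless_session):
        movie, behavior, protocol, truth = noiseless_session
        corrected = img.lag_correct_behavior(behavior)
        beh = img.resample_behavior_to_frames(corrected, movie.frame_times)
        maps = img.pixel_correlation_map(movie.gcamp, beh["wba_left"].to_numpy(),
                                         beh["wba_right"].to_numpy())
        W = movie.shape[2]
        # right-hemisphere cells drive the LEFT wing: right-side pixels are
        # positive in the left-wing map and negative in the right-wing map
        right_active = maps.valid.copy()
        right_active[:, :W // 2] = False
        strong = right_active & (np.abs(maps.r_left) > 0.2)
        assert np.median(maps.r_left[strong]) > 0.5
        assert np.median(maps.r_right[strong]) < 0.0


class TestBilateralSummary:
    def test_generator_sign_structure(self, noiseless_session):
        movie, behavior, protocol, truth = noiseless_session
        _, _, left, right = extract_dff_traces(movie)
        corrected = img.lag_correct_behavior(behavior)
        beh = img.resample_behavior_to_frames(corrected, movie.frame_times)
        table = img.bilateral_summary(left, right, beh["wba_left"].to_numpy(),
                                      beh["wba_right"].to_numpy())
        by = {(r.signal, r.wing): r.r for r in table.itertuples()}
        assert by[("dff_left", "right")] > 0.5      # contralateral positive
        assert by[("dff_right", "left")] > 0.5
        assert by[("dff_left", "left")] < by[("dff_left", "right")]
        assert by[("dff_right", "right")] < by[("dff_right", "left")]

    def test_permuted_behavior_decorrelates(self, noiseless_session):
        movie, behavior, protocol, truth = noiseless_session
        _, _, left, right = extract_dff_traces(movie)
        rng = np.random.default_rng(0)
        wl = rng.permutation(np.interp(movie.frame_times, behavior.t, behavior.wba_left))
        wr = rng.permutation(np.interp(movie.frame_times, behavior.t, behavior.wba_right))
        table = img.bilateral_summary(left, right, wl, wr)
        assert np.abs(table["r"].head(4)).max() < 0.1

    def test_constant_input_rejected(self):
        tr = img.SideTrace(side="left", F_t=np.arange(10.0), F0=0.0,
                           dff=np.linspace(0, 1, 10))
        flat = img.SideTrace(side="right", F_t=np.ones(10), F0=0.0, dff=np.ones(10))
        with pytest.raises(ValueError, match="constant"):
            img.bilateral_summary(tr, flat, np.arange(10.0), np.arange(10.0))


class TestFullPipelineRecovery:
    def test_noiseless_recovery(self, noiseless_session):
        movie, behavior, protocol, truth = noiseless_session
        _, shifts, left, right = extract_dff_traces(movie)
        assert np.all(shifts == 0)
        assert np.corrcoef(left.dff, truth.activity_left_frames)[0, 1] >= 0.99
        assert np.corrcoef(right.dff, truth.activity_right_frames)[0, 1] >= 0.99

    def test_moderate_noise_recovery(self, moderate_session):
        movie, behavior, protocol, truth = moderate_session
        _, shifts, left, right = extract_dff_traces(movie)
        np.testing.assert_array_equal(shifts, -truth.shifts)
        assert np.corrcoef(left.dff, truth.activity_left_frames)[0, 1] >= 0.9
        assert np.corrcoef(right.dff, truth.activity_right_frames)[0, 1] >= 0.9
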