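"""Biosensor analytics: tracking, ratio series, smoothing, registration,
kymographs, peak scoring, growth classification and cohort summaries."""

import dataclasses

import numpy as np
import pytest

from adhesio import biosensor as bsn
from adhesio import morphometrics as mo
from adhesio import synthetic as syn
from adhesio import validation as V
from adhesio.morphometrics import FocalAdhesion


def _fa(x, y, label=1, major=2.0, minor=1.0, theta=0.0):
    return FocalAdhesion(
        label=label, area_um2=np.pi * major * minor / 4,
        aspect_ratio=major / minor, centroid_xy_um=(x, y),
        orientation_rad=theta, major_um=major, minor_um=minor,
    )


def _analyzed_movie(mspec):
    movie, truths = syn.generate_ratio_movie(mspec)
    movie = bsn.subtract_movie_background(movie)
    frame_fas, label_frames = [], []
    for t in range(movie.n_frames):
        labels, fas = mo.segment_fas(movie.frame("den", t), mo.SegmentationParams())
        frame_fas.append(fas)
        label_frames.append(labels)
    tracks = bsn.track_fas(frame_fas)
    return movie, truths, tracks, np.stack(label_frames)


class TestTracking:
    def test_static_fas_one_full_track_each(self):
        frames = [[_fa(2, 2, 1), _fa(8, 8, 2)] for _ in range(5)]
        tracks = bsn.track_fas(frames)
        assert len(tracks) == 2
        assert all(tr.n_frames == 5 for tr in tracks)

    def test_gap_bridged_by_interpolation(self):
        frames = [[_fa(2, 2)], [_fa(2.1, 2)], [], [_fa(2.3, 2)]]
        tracks = bsn.track_fas(frames)
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.frames == [0, 1, 2, 3]
        gap = tr.points[2]
        assert gap.interpolated and gap.label is None
        assert gap.centroid_xy_um[0] == pytest.approx((2.1 + 2.3) / 2)

    def test_large_jumps_terminate_instead_of_swapping(self):
        # two FAs 6 um apart vanish and "reappear" swapped: linking either
        # would need a 6-um jump, far beyond the 1-um/frame gate
        frames = [
            [_fa(2, 2, 1), _fa(8, 2, 2)],
            [_fa(8, 2, 1), _fa(2, 2, 2)],
        ]
        tracks = bsn.track_fas(frames)
        # greedy matching keeps the stationary interpretation: each track
        # stays at its position (zero displacement beats any swap)
        assert len(tracks) == 2
        for tr in tracks:
            xs = [p.centroid_xy_um[0] for p in tr.points]
            assert max(xs) - min(xs) < 1e-9

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            bsn.track_fas([[_fa(1, 1)]])


class TestBoxcar:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([1, 2, 3], [1.5, 2, 2.5]),
            ([5, 5, 5, 5], [5, 5, 5, 5]),
            ([0, 0, 3, 0, 0], [0, 1, 1, 1, 0]),
            ([7], [7]),
        ],
    )
    def test_window_arithmetic(self, series, expected):
        np.testing.assert_allclose(bsn.boxcar_smooth(series), expected)

    def test_smoothed_within_raw_window_bounds(self, rng):
        x = rng.random(50)
        sm = bsn.boxcar_smooth(x)
        for i in range(50):
            w = x[max(i - 1, 0) : i + 2]
            assert w.min() - 1e-12 <= sm[i] <= w.max() + 1e-12

    def test_nan_frames_stay_undefined(self):
        out = bsn.boxcar_smooth([1.0, np.nan, 3.0])
        assert np.isnan(out[1])
        assert out[0] == 1.0 and out[2] == 3.0


class TestRatioSeries:
    def test_doubled_numerator_gives_two(self, single_fa_movie_spec):
        movie, _, tracks, labels = _analyzed_movie(single_fa_movie_spec)
        tr = tracks[0]
        from adhesio.images import Movie

        m2 = Movie(
            {"num": 2.0 * movie.channels["den"], "den": movie.channels["den"]},
            movie.pixel_size_um,
            movie.frame_interval_s,
        )
        rs = bsn.compute_ratio_series(m2, tr, labels)
        np.testing.assert_allclose(rs.raw_ratio, 2.0, rtol=1e-12)

    def test_gain_invariance(self, single_fa_movie_spec):
        movie, _, tracks, labels = _analyzed_movie(single_fa_movie_spec)
        from adhesio.images import Movie

        tr = tracks[0]
        rs1 = bsn.compute_ratio_series(movie, tr, labels)
        scaled = Movie(
            {k: 3.7 * v for k, v in movie.channels.items()},
            movie.pixel_size_um, movie.frame_interval_s,
        )
        rs2 = bsn.compute_ratio_series(scaled, tr, labels)
        np.testing.assert_allclose(rs1.raw_ratio, rs2.raw_ratio, rtol=1e-12)

    def test_planted_step_recovered_within_five_percent(self):
        res = V.inhibitor_step_recovery(ratio_drop=0.5, seed=8)
        assert res["measured_ratio_factor"] == pytest.approx(0.5, rel=0.05)

    def test_smoothed_series_present_and_aligned(self, single_fa_movie_spec):
        movie, _, tracks, labels = _analyzed_movie(single_fa_movie_spec)
        rs = bsn.compute_ratio_series(movie, tracks[0], labels)
        assert rs.smoothed_ratio.shape == rs.raw_ratio.shape
        assert np.all(np.diff(rs.times_s) > 0)


class TestRegistrationAndKymograph:
    def test_distal_hotspot_lands_in_top_third(self, single_fa_movie_spec):
        mspec = dataclasses.replace(
            single_fa_movie_spec, activity_patterns=("distal_hotspot",)
        )
        movie, _, tracks, labels = _analyzed_movie(mspec)
        tr = tracks[0]
        patches, dens = bsn.register_fa_patch(
            movie, tr, mspec.scene.cell_center_px
        )
        h = patches.shape[1]
        for t in range(patches.shape[0]):
            # restrict to the FA footprint: ratios over near-zero denominator
            # pixels at the boundary are noise-amplified
            core = np.where(dens[t] > 0.3 * dens[t].max(), patches[t], np.nan)
            flat = np.nanargmax(core)
            row = flat // patches.shape[2]
            assert row < h / 2.5

    def test_registered_axis_vertical(self, single_fa_movie_spec):
        movie, _, tracks, labels = _analyzed_movie(single_fa_movie_spec)
        tr = tracks[0]
        patches, dens = bsn.register_fa_patch(
            movie, tr, single_fa_movie_spec.scene.cell_center_px
        )
        fa = mo.compute_shape_descriptors(
            dens[0] > 0.2 * dens[0].max(), movie.pixel_size_um
        )
        # vertical in the patch frame means orientation +/- pi/2
        assert abs(abs(fa.orientation_rad) - np.pi / 2) < np.deg2rad(3)

    def test_uniform_activity_flat_kymograph(self, single_fa_movie_spec):
        scene = dataclasses.replace(
            single_fa_movie_spec.scene, noise_sigma=0.0, psf_sigma_px=0.0,
            background_level=0.0,
        )
        mspec = dataclasses.replace(single_fa_movie_spec, scene=scene)
        movie, truths, tracks, labels = _analyzed_movie(mspec)
        tr = tracks[0]
        rs = bsn.compute_ratio_series(movie, tr, labels)
        patches, dens = bsn.register_fa_patch(movie, tr, scene.cell_center_px)
        kym = bsn.build_kymograph(patches, dens, rs.times_s)
        defined = ~np.isnan(kym.matrix)
        np.testing.assert_allclose(kym.matrix[defined], 1.0, atol=0.02)

    def test_kymograph_mean_conserves_fa_ratio(self, single_fa_movie_spec):
        movie, _, tracks, labels = _analyzed_movie(single_fa_movie_spec)
        tr = tracks[0]
        rs = bsn.compute_ratio_series(movie, tr, labels)
        patches, dens = bsn.register_fa_patch(
            movie, tr, single_fa_movie_spec.scene.cell_center_px
        )
        kym = bsn.build_kymograph(patches, dens, rs.times_s)
        for t in range(kym.matrix.shape[1]):
            col = kym.matrix[:, t]
            assert np.nanmean(col) == pytest.approx(rs.raw_ratio[t], rel=0.05)

    def test_near_circular_first_frame_rejected(self):
        scene = syn.SceneSpec(
            image_size_px=(96, 96), cell_radius_um=6.5,
            fa_specs=(syn.FaSpec(0.5, 0.5, 1.0, 0.95, 0.0, 100.0),),
            noise_sigma=0.0, psf_sigma_px=0.0, seed=2,
        )
        mspec = syn.MovieSpec(scene=scene, n_frames=3, frame_interval_s=20.0)
        movie, _, tracks, _ = _analyzed_movie(mspec)
        with pytest.raises(ValueError, match="near-circular"):
            bsn.register_fa_patch(movie, tracks[0], scene.cell_center_px)


class TestPeakScoring:
    def _kym(self, matrix):
        m = np.asarray(matrix, dtype=float)
        return bsn.Kymograph(
            track_id=0,
            positions=np.linspace(0, 1, m.shape[0]),
            times_s=np.arange(m.shape[1], dtype=float),
            matrix=m,
        )

    def test_thirds_mapping(self):
        m = np.ones((9, 3))
        m[8, 1] = 5.0
        assert bsn.score_peak_location(self._kym(m)) == "distal"
        m = np.ones((9, 3))
        m[4, 0] = 5.0
        assert bsn.score_peak_location(self._kym(m)) == "central"
        m = np.ones((9, 3))
        m[0, 2] = 5.0
        assert bsn.score_peak_location(self._kym(m)) == "medial"

    def test_matches_brute_force_argmax(self, rng):
        for _ in range(20):
            m = rng.random((15, 10))
            kym = self._kym(m)
            i, j = np.unravel_index(np.argmax(m), m.shape)
            assert bsn.score_peak_location(kym) == bsn._third(kym.positions[i])

    def test_tie_broken_by_earliest_time_then_distal(self):
        m = np.zeros((9, 4))
        m[0, 2] = 1.0  # medial, later
        m[8, 1] = 1.0  # distal, earlier
        assert bsn.score_peak_location(self._kym(m)) == "distal"
        m = np.zeros((9, 4))
        m[2, 1] = 1.0  # medial third, same time
        m[4, 1] = 1.0  # central third, same time: larger position wins
        assert bsn.score_peak_location(self._kym(m)) == "central"

    def test_planted_cohort_fraction_recovered(self):
        res = V.distal_cohort_recovery(n_fa=60, frac_distal=0.6, seed=7)
        ci = 1.96 * np.sqrt(0.6 * 0.4 / res["n_scored"])
        assert res["n_scored"] >= 55
        assert abs(res["scored_distal_fraction"] - 0.6) <= ci + 0.05


class TestGrowthClassification:
    @pytest.mark.parametrize(
        "rate,state",
        [(0.05, "Growing"), (0.0, "Stable"), (-0.05, "Shrinking")],
    )
    def test_noise_free_single_segment(self, rate, state):
        t, lengths, _ = syn.generate_length_trajectory(rate, 10.0, 1 / 3, 0.0, 0)
        gs = bsn.classify_growth_series(t, lengths)
        assert len(gs.segments) == 1
        seg = gs.segments[0]
        assert seg.state == state
        assert seg.t_start_min == 0.0 and seg.t_end_min == pytest.approx(10.0)
        assert seg.rate_um_per_min == pytest.approx(rate, abs=1e-9)

    def test_transition_contributes_both_behaviors(self):
        t = np.arange(0, 12.01, 1 / 3)
        lengths = 2 + 0.05 * np.minimum(t, 6) - 0.05 * np.maximum(t - 6, 0)
        gs = bsn.classify_growth_series(t, lengths)
        states = [s.state for s in gs.segments]
        assert states[0] == "Growing" and states[-1] == "Shrinking"
        for seg in gs.segments:
            assert seg.t_end_min - seg.t_start_min >= 5.0 - 1e-9

    def test_short_track_yields_no_segments(self):
        t = np.arange(0, 3.0, 1 / 3)
        gs = bsn.classify_growth_series(t, 2.0 + 0.1 * t)
        assert gs.segments == ()

    def test_zero_noise_accuracy_is_perfect(self):
        res = V.growth_classifier_accuracy(n_trajectories=60, seed=5)
        assert res["accuracy_noise_free"] == 1.0

    def test_noisy_accuracy_above_ninety_percent(self):
        res = V.growth_classifier_accuracy(
            n_trajectories=150, noise_sigma_um=0.05, seed=6
        )
        assert res["accuracy_noisy"] >= 0.9


class TestCohortSummary:
    def test_identical_series_anova_p_near_one(self):
        t_min = np.arange(0, 10.01, 1 / 3)
        pairs = []
        for i, rate in enumerate([0.05, 0.05, 0.0, 0.0, -0.05, -0.05]):
            raw = np.full(t_min.size, 1.3)
            rs = bsn.RatioSeries(i, t_min * 60, raw, bsn.boxcar_smooth(raw))
            gs = bsn.classify_growth_series(t_min, 2 + rate * t_min, i)
            pairs.append((rs, gs))
        summary = bsn.summarize_activity_by_state(pairs)
        means = summary.segments.groupby("state")["mean"].mean()
        assert means.nunique() == 1
        assert summary.anova["mean"][1] == pytest.approx(1.0)

    def test_stable_offset_detected(self):
        res = V.state_offset_detection(stable_offset=0.2, seed=3)
        assert res["anova_p_mean"] < 0.05
        assert res["stable_exceeds_others"]

    def test_planted_rate_correlation_recovered(self):
        res = V.ratio_rate_correlation_recovery(slope=5.0, seed=4)
        assert res["slope"] > 0
        assert res["p_value"] < 0.05
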