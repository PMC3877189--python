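import numpy as np
import pytest

from snoredetect.audio_io import AudioSignal, FrameSpec, frame_energy
from snoredetect.event_detection import (
    AudioEvent,
    compute_thresholds,
    detect_candidates,
    duration_filter,
    fragmentation_merge,
    refine_edges,
    section_threshold,
    segment_night,
    smooth_thresholds,
)


def brute_force_threshold(section_db, bin_width=1.0, fallback=6.0):
    """Independent linear histogram scan used as an oracle."""
    lo = np.floor(min(section_db) / bin_width) * bin_width
    hi = np.ceil(max(section_db) / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts = [np.sum((section_db >= a) & (section_db < b)) for a, b in zip(edges[:-1], edges[1:])]
    mode = int(np.argmax(counts))
    centers = [0.5 * (a + b) for a, b in zip(edges[:-1], edges[1:])]
    for j in range(mode + 1, len(counts)):
        if counts[j] <= counts[mode] / 10.0:
            return centers[mode], centers[j]
    return centers[mode], centers[mode] + fallback


class TestSectionThreshold:
    def test_bimodal_section(self):
        section = np.concatenate([np.full(900, -50.0), np.full(30, -10.0)])
        e_max, e_th = section_threshold(section, 1.0)
        assert e_max == pytest.approx(-49.5)  # bin [-50, -49) center
        assert e_th == pytest.approx(-48.5)  # first bin above the mode with count <= 90

    def test_constant_section_uses_fallback(self):
        e_max, e_th = section_threshold(np.full(100, -40.0), 1.0, fallback_offset_db=6.0)
        assert e_th == pytest.approx(e_max + 6.0)

    def test_matches_linear_scan_oracle_on_random_sections(self, rng):
        for _ in range(300):
            n = rng.integers(20, 400)
            section = rng.normal(rng.uniform(-60, -20), rng.uniform(0.5, 8.0), n)
            got = section_threshold(section, 1.0)
            want = brute_force_threshold(section, 1.0)
            assert got == pytest.approx(want)

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            section_threshold(np.zeros(5))


class TestSmoothThresholds:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_thresholds(np.full(10, -30.0)), -30.0)

    def test_single_outlier_removed(self):
        v = np.array([-30.0, -30.0, 0.0, -30.0, -30.0])
        assert smooth_thresholds(v)[2] == pytest.approx(-30.0)

    def test_short_vectors(self):
        np.testing.assert_allclose(smooth_thresholds(np.array([-25.0])), [-25.0])
        out = smooth_thresholds(np.array([1.0, 2.0, 9.0]))
        assert out[1] == pytest.approx(2.0)  # median of all three


class TestDetectCandidates:
    def test_single_run(self, make_track):
        track = make_track([-50, -50, -10, -10, -10, -50] + [-50] * 10)
        th = compute_thresholds(track)
        th.e_th[:] = -30.0
        events = detect_candidates(track, th)
        assert [(e.start_frame, e.end_frame) for e in events] == [(2, 4)]

    def test_all_below_threshold(self, make_track):
        track = make_track(np.full(50, -50.0))
        th = compute_thresholds(track)
        th.e_th[:] = -30.0
        assert detect_candidates(track, th) == []

    def test_matches_run_length_oracle(self, make_track, rng):
        for _ in range(200):
            db = rng.choice([-50.0, -10.0], size=rng.integers(10, 200))
            track = make_track(db)
            th = compute_thresholds(track)
            th.e_th[:] = -30.0
            events = detect_candidates(track, th)
            # independent run-length encoding
            above = db > -30.0
            runs = []
            i = 0
            while i < above.size:
                if above[i]:
                    j = i
                    while j + 1 < above.size and above[j + 1]:
                        j += 1
                    runs.append((i, j))
                    i = j + 1
                else:
                    i += 1
            assert [(e.start_frame, e.end_frame) for e in events] == runs


class TestRefineEdges:
    def test_triangular_pulse_expands_to_base(self, make_track, rng):
        floor = -50.0
        ramp_up = np.linspace(floor, -10, 30)
        ramp_dn = np.linspace(-10, floor, 30)
        db = np.concatenate([np.full(100, floor), ramp_up, ramp_dn, np.full(100, floor)])
        db += rng.normal(0, 0.1, db.size)
        track = make_track(db)
        ev = AudioEvent(start_frame=115, end_frame=145)  # thresholded core of the pulse
        refined = refine_edges(track, ev)
        # the slope deadband stops the search once the fit window is about
        # half background, so the recovered base is within ~half a window
        assert abs(refined.start_frame - 100) <= 6
        assert abs(refined.end_frame - 160) <= 6

    def test_event_at_local_minima_unchanged(self, make_track, rng):
        db = np.full(200, -50.0) + rng.normal(0, 0.05, 200)
        db[90:110] = -10.0
        track = make_track(db)
        ev = AudioEvent(start_frame=90, end_frame=109)
        refined = refine_edges(track, ev)
        assert refined.start_frame >= 85 and refined.end_frame <= 114

    def test_monotone_ramp_runs_to_guard(self, make_track):
        db = np.concatenate([np.full(50, -50.0), np.linspace(-50, 350, 400)])
        track = make_track(db)
        ev = AudioEvent(start_frame=300, end_frame=310)
        refined = refine_edges(track, ev, max_extend_s=0.5)
        # right edge keeps extending up the ramp until the runaway guard
        assert refined.end_frame - 310 >= 30

    def test_never_shrinks(self, make_track, rng):
        for _ in range(50):
            db = rng.normal(-40, 3, 300)
            track = make_track(db)
            ev = AudioEvent(start_frame=100, end_frame=150)
            refined = refine_edges(track, ev)
            assert refined.start_frame <= 100
            assert refined.end_frame >= 150

    def test_track_boundary_stops_search(self, make_track):
        db = np.linspace(0, -50, 100)  # falling from the very start
        track = make_track(db)
        refined = refine_edges(track, AudioEvent(start_frame=2, end_frame=10))
        assert refined.start_frame >= 0


class TestFragmentationMerge:
    def _night_with_gap(self, gap_s, second_kind="same", fs=16000):
        from snoredetect.synthetic import generate_noise_event, generate_snore_event

        rng = np.random.default_rng(0)
        part1 = generate_snore_event(0.5, 60.0, rng=np.random.default_rng(1), fs=fs)
        if second_kind == "same":
            part2 = generate_snore_event(0.5, 60.0, rng=np.random.default_rng(1), fs=fs)
        else:
            part2 = generate_noise_event("cough", 60.0, rng=np.random.default_rng(2), fs=fs)
        noise = rng.standard_normal(fs * 4) * 1e-4
        gap = int(gap_s * fs)
        i1 = fs
        i2 = i1 + part1.size + gap
        noise[i1 : i1 + part1.size] += part1
        noise[i2 : i2 + part2.size] += part2
        sig = AudioSignal(np.clip(noise, -1, 1), fs)
        track = frame_energy(sig, FrameSpec())
        fr = track.frame_rate
        ev1 = AudioEvent(int(i1 / fs * fr), int((i1 + part1.size) / fs * fr) - 1)
        ev2 = AudioEvent(int(i2 / fs * fr), int((i2 + part2.size) / fs * fr) - 1)
        return sig, track, [ev1, ev2]

    def test_split_snore_merged(self):
        sig, track, events = self._night_with_gap(0.12, "same")
        merged = fragmentation_merge(sig, track, events)
        assert len(merged) == 1
        assert merged[0].start_frame == events[0].start_frame
        assert merged[0].end_frame == events[1].end_frame

    def test_dissimilar_pair_not_merged(self):
        sig, track, events = self._night_with_gap(0.12, "different")
        assert len(fragmentation_merge(sig, track, events)) == 2

    def test_gap_rule_first(self):
        sig, track, events = self._night_with_gap(0.30, "same")
        assert len(fragmentation_merge(sig, track, events)) == 2

    def test_empty_input(self, make_track):
        sig = AudioSignal(np.zeros(16000), 16000)
        assert fragmentation_merge(sig, frame_energy(sig, FrameSpec()), []) == []


class TestDurationFilter:
    def _event(self, dur):
        return AudioEvent(0, 0, start_s=10.0, end_s=10.0 + dur)

    def test_bounds(self, make_track):
        track = make_track(np.zeros(100))
        events = [self._event(d) for d in (0.1, 1.0, 4.0)]
        kept = duration_filter(track, events)
        assert [e.end_s - e.start_s for e in kept] == [1.0]

    def test_inclusive_boundaries(self, make_track):
        track = make_track(np.zeros(100))
        kept = duration_filter(track, [self._event(0.2), self._event(3.5)])
        assert len(kept) == 2

    def test_empty(self, make_track):
        assert duration_filter(make_track(np.zeros(100)), []) == []


class TestSegmentNight:
    def test_single_planted_event(self):
        from snoredetect.config import PipelineConfig
        from snoredetect.pipeline import enhance_signal
        from snoredetect.synthetic import NightSpec, SnoreBlock, generate_night

        spec = NightSpec(
            duration_s=40.0,
            snore_blocks=[SnoreBlock(count=1, period_mean_s=10.0, duration_range_s=(1.0, 1.0), intensity_range_db=(60, 60))],
            noise_events=[],
            seed=21,
        )
        sig, truth = generate_night(spec)
        clean = enhance_signal(sig, PipelineConfig())
        events, track = segment_night(clean)
        assert len(events) == 1
        assert abs(events[0].start_s - truth[0].onset_s) <= 0.06
        assert abs(events[0].end_s - truth[0].offset_s) <= 0.06
        assert np.isfinite(events[0].intensity_db)
        assert np.isfinite(events[0].snr_db)

    def test_detected_events_never_overlap(self):
        from snoredetect.config import PipelineConfig
        from snoredetect.pipeline import enhance_signal
        from snoredetect.synthetic import NightSpec, SnoreBlock, generate_night

        spec = NightSpec(
            duration_s=120.0,
            snore_blocks=[SnoreBlock(count=25, period_mean_s=3.5, duration_range_s=(0.5, 1.2))],
            noise_events=[],
            seed=22,
        )
        sig, _ = generate_night(spec)
        clean = enhance_signal(sig, PipelineConfig())
        events, track = segment_night(clean)
        for a, b in zip(events, events[1:]):
            assert a.end_frame < b.start_frame
            assert a.end_s <= b.start_s + 1e-9
        for ev in events:
            assert 0 <= ev.start_frame <= ev.end_frame < track.n_frames
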