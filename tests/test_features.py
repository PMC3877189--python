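import math

import numpy as np
import pytest
from scipy.signal import lfilter

from snoredetect.audio_io import AudioSignal, FrameSpec, frame_energy
from snoredetect.event_detection import AudioEvent
from snoredetect.features import (
    CATEGORY_SIZES,
    FEATURE_NAMES,
    FeatureVector,
    bio_frequencies,
    duration_features,
    dynamic_frequency_features,
    energy_features,
    extract_all,
    feature_manifest,
    levinson_lpc,
    logistic_energy,
    periodicity_features,
    relative_prior_energy,
    spectral_parameterization,
)


def make_event(track, start_s, end_s):
    fr = track.frame_rate
    return AudioEvent(
        start_frame=int(start_s * fr),
        end_frame=int(end_s * fr),
        start_s=start_s,
        end_s=end_s,
        intensity_db=60.0,
        peak_db=63.0,
        snr_db=25.0,
    )


def signal_event(samples, fs=16000):
    sig = AudioSignal(np.clip(samples, -1, 1), fs)
    ev = AudioEvent(0, 0, start_s=0.0, end_s=len(samples) / fs, intensity_db=60, peak_db=63, snr_db=20)
    return sig, ev


class TestManifest:
    def test_counts_match_taxonomy(self):
        manifest = feature_manifest()
        assert len(manifest) == 127
        by_cat = {}
        for entry in manifest:
            by_cat[entry["category"]] = by_cat.get(entry["category"], 0) + 1
        assert by_cat == CATEGORY_SIZES

    def test_feature_vector_requires_all_slots(self):
        with pytest.raises(ValueError):
            FeatureVector({"Ta_ep": 1.0})


class TestLogisticEnergy:
    def test_midpoint_maps_to_half(self):
        seg = np.array([30.0, 40.0, 50.0])
        out = logistic_energy(seg, mu=40.0, s=5.0)
        assert out[1] == pytest.approx(0.5)

    def test_saturation(self):
        out = logistic_energy(np.array([0.0, 1000.0, -1000.0]), mu=0.0, s=1.0)
        assert out[1] == pytest.approx(1.0, abs=1e-6)
        assert out[2] == pytest.approx(0.0, abs=1e-6)

    def test_bimodal_segment_near_binary(self, rng):
        # snore/silence duty cycle ~25%: the median sits in the silence mode
        seg = np.concatenate([rng.normal(30, 0.5, 750), rng.normal(60, 0.5, 250)])
        rng.shuffle(seg)
        out = logistic_energy(seg)
        frac_extreme = np.mean((out < 0.1) | (out > 0.9))
        assert frac_extreme > 0.9

    def test_zero_iqr_floor(self):
        out = logistic_energy(np.full(10, 42.0))
        assert np.all(np.isfinite(out))


class TestPeriodicity:
    def _periodic_track(self, make_track, period_s, n_s=40, duty_s=1.0, rng=None):
        fr = 1000.0 / 15.0
        n = int(n_s * fr)
        db = np.full(n, 30.0)
        if rng is not None:
            db += rng.normal(0, 0.5, n)
        t = 0.5
        while t + duty_s < n_s:
            db[int(t * fr) : int((t + duty_s) * fr)] = 60.0
            t += period_s
        return make_track(db)

    def test_periodic_train_recovers_period(self, make_track, rng):
        track = self._periodic_track(make_track, 4.0, rng=rng)
        ev = make_event(track, 20.5, 21.5)
        f = periodicity_features(track, ev)
        assert f["Ta_period_left"] == pytest.approx(4.0, abs=0.1)
        assert f["Ta_period_right"] == pytest.approx(4.0, abs=0.1)
        assert f["Ta_ri_combined"] > 0

    def test_shuffled_events_lower_ri(self, make_track):
        fr = 1000.0 / 15.0
        rng = np.random.default_rng(7)
        ri_periodic, ri_shuffled = [], []
        for trial in range(20):
            r = np.random.default_rng(trial)
            periodic = self._periodic_track(make_track, 4.0, rng=r)
            n = periodic.n_frames
            db = np.full(n, 30.0) + r.normal(0, 0.5, n)
            # same number of bursts at random (non-overlapping) times
            starts = np.sort(r.uniform(0.5, 38.0, 9))
            for s in starts:
                db[int(s * fr) : int((s + 1.0) * fr)] = 60.0
            shuffled = periodic.__class__(
                energies=10.0 ** (db / 10.0),
                frame_length=960,
                hop_length=240,
                sample_rate=16000,
                calibration_offset_db=0.0,
            )
            ev_p = make_event(periodic, 20.5, 21.5)
            ev_s = make_event(shuffled, 20.5, 21.5)
            rp = periodicity_features(periodic, ev_p)["Ta_ri_combined"]
            rs = periodicity_features(shuffled, ev_s)["Ta_ri_combined"]
            ri_periodic.append(rp if np.isfinite(rp) else 0.0)
            ri_shuffled.append(rs if np.isfinite(rs) else 0.0)
        assert np.median(ri_periodic) > np.median(ri_shuffled)

    def test_constant_segment_flags_missing(self, make_track):
        track = make_track(np.full(4000, 40.0))
        ev = make_event(track, 25.0, 26.0)
        f = periodicity_features(track, ev)
        assert math.isnan(f["Ta_period_left"])
        assert math.isnan(f["Ta_ri_left"])

    def test_ri_matches_trapezoid_oracle(self, make_track, rng):
        from scipy.signal import find_peaks

        from snoredetect.features import _autocorr_context

        fr = 1000.0 / 15.0
        for _ in range(30):
            track = self._periodic_track(make_track, rng.uniform(2.5, 6.0), rng=rng)
            db = track.db[: int(24 * fr)]
            ctx = _autocorr_context(db, fr)
            if not np.isfinite(ctx.tau_p):
                continue
            # independent brute-force: recompute R, chord, trapezoidal area
            x = logistic_energy(db)
            x = x - x.mean()
            r = np.correlate(x, x, "full")[x.size - 1 :]
            r = r / r[0]
            r = np.convolve(r, np.ones(5) / 5, "same")
            r = r / r[0]
            p = int(round(ctx.tau_p * fr))
            taus = np.arange(p + 1) / fr
            a = (r[p] - 1.0) / ctx.tau_p
            integrand = (r[: p + 1] - (a * taus + 1.0)) ** 2
            area = np.trapezoid(integrand, taus) / ctx.tau_p
            assert ctx.area == pytest.approx(area, abs=1e-6)
            assert ctx.ri == pytest.approx(r[p] * area, abs=1e-6)


class TestRelativePriorEnergy:
    def test_zero_prior(self, make_track):
        track = make_track(np.full(2000, -100.0))
        track.energies[:] = 0.0
        track.energies[1000:1050] = 1.0
        ev = AudioEvent(1000, 1049)
        assert relative_prior_energy(track, ev) == pytest.approx(0.0)

    def test_four_copies_gives_four(self, make_track):
        fr = 1000.0 / 15.0
        n = int(30 * fr)
        track = make_track(np.full(n, 0.0))
        track.energies[:] = 0.0
        w = int(10 * fr)
        event = (1400, 1400 + 49)
        track.energies[event[0] : event[1] + 1] = 2.0
        # exactly 4 copies of the event inside the prior 10 s window
        for k in range(4):
            s = event[0] - w + 50 + k * 150
            track.energies[s : s + 50] = 2.0
        ev = AudioEvent(event[0], event[1])
        assert relative_prior_energy(track, ev) == pytest.approx(4.0, rel=1e-9)

    def test_matches_two_sum_oracle_on_random_tracks(self, make_track, rng):
        fr = 1000.0 / 15.0
        w = int(round(10 * fr))
        for _ in range(1000):
            n = rng.integers(w + 100, w + 500)
            track = make_track(rng.uniform(-60, -10, n))
            a = int(rng.integers(w, n - 60))
            b = a + int(rng.integers(10, 50))
            got = relative_prior_energy(track, AudioEvent(a, b))
            want = np.sum(track.energies[a - w : a]) / np.sum(track.energies[a : b + 1])
            assert got == pytest.approx(want, rel=1e-9)

    def test_truncated_window_renormalized(self, make_track):
        fr = 1000.0 / 15.0
        track = make_track(np.full(1000, 0.0))
        track.energies[:] = 1.0
        ev = AudioEvent(200, 249)  # only 200 prior frames of the 667-frame window
        w = int(round(10 * fr))
        expected = (200.0 * (w / 200.0)) / 50.0
        assert relative_prior_energy(track, ev) == pytest.approx(expected, rel=1e-9)


class TestDurationFeatures:
    def test_rectangular_profile(self):
        fs = 16000
        samples = np.zeros(fs * 2)
        samples[fs // 2 : fs // 2 + fs] = 0.1  # 1.0 s rectangle
        sig = AudioSignal(samples, fs)
        ev = AudioEvent(0, 0, start_s=0.5, end_s=1.5)
        f = duration_features(sig, ev)
        assert f["Tb_duration"] == pytest.approx(1.0)
        assert f["Tb_duration95"] == pytest.approx(0.95, abs=0.01)

    def test_impulse_concentration(self):
        fs = 16000
        samples = np.zeros(fs)
        samples[8000:8010] = 0.5
        sig = AudioSignal(samples, fs)
        ev = AudioEvent(0, 0, start_s=0.0, end_s=1.0)
        f = duration_features(sig, ev)
        assert f["Tb_duration95"] < 0.05
        assert f["Tb_duration_ratio"] < 0.05

    def test_long_tail_matches_cumulative_scan(self, rng):
        fs = 16000
        env = np.exp(-np.arange(fs * 3) / (fs * 0.4))
        samples = env * rng.standard_normal(fs * 3) * 0.1
        sig = AudioSignal(samples, fs)
        ev = AudioEvent(0, 0, start_s=0.0, end_s=3.0)
        f = duration_features(sig, ev)
        # brute-force cumulative scan
        e = samples**2
        cum = np.cumsum(e) / e.sum()
        lo = np.searchsorted(cum, 0.025) / fs
        hi = np.searchsorted(cum, 0.975) / fs
        assert f["Tb_duration95"] == pytest.approx(hi - lo, abs=1e-9)
        assert f["Tb_duration95"] < 2.0


class TestEnergyFeatures:
    def test_symmetric_envelope_zero_skew(self, make_track):
        db = np.full(300, -40.0)
        track = make_track(db)
        track.energies[100:151] = np.concatenate([np.linspace(0, 1, 25), [1.05], np.linspace(1, 0, 25)])
        ev = AudioEvent(100, 150, intensity_db=50, peak_db=55, snr_db=20)
        f = energy_features(track, ev)
        assert abs(f["Tc_env_skew"]) < 0.05
        assert f["Tc_env_centroid"] == pytest.approx(0.5, abs=0.02)

    def test_shape_slots_gain_invariant(self, make_track, rng):
        db = rng.uniform(-50, -20, 80)
        track1 = make_track(db)
        track2 = make_track(db + 17.0)  # global gain
        ev = AudioEvent(10, 69)
        f1 = energy_features(track1, ev)
        f2 = energy_features(track2, ev)
        for slot in ("Tc_rise_time", "Tc_fall_time", "Tc_env_centroid", "Tc_env_skew",
                     "Tc_env_kurt", "Tc_crest", "Tc_mod_depth", "Tc_energy_fill"):
            assert f1[slot] == pytest.approx(f2[slot], abs=1e-6)


class TestSpectralParameterization:
    def test_white_noise_flat_subbands(self, rng):
        sig, ev = signal_event(rng.standard_normal(16000) * 0.05)
        f = spectral_parameterization(sig, ev)
        for i in range(8):
            assert f[f"Sa_subband_mean_{i+1}"] == pytest.approx(0.125, abs=0.03)

    def test_pure_tone_concentrated(self):
        t = np.arange(8000) / 16000
        sig, ev = signal_event(0.1 * np.sin(2 * np.pi * 500 * t))
        f = spectral_parameterization(sig, ev)
        assert f["Sa_subband_mean_1"] > 0.95
        assert f["Sa_centroid_mean"] == pytest.approx(500, abs=50)

    def test_repeated_frame_zero_variance(self):
        block = np.sin(2 * np.pi * 250 * np.arange(640) / 16000)
        sig, ev = signal_event(np.tile(block, 20) * 0.1)
        f = spectral_parameterization(sig, ev)
        assert f["Sa_mfcc_std_1"] == pytest.approx(0.0, abs=1e-9)
        assert f["Sa_centroid_var"] == pytest.approx(0.0, abs=1e-6)

    def test_single_frame_flags_moments_missing(self, rng):
        sig, ev = signal_event(rng.standard_normal(400) * 0.05)
        f = spectral_parameterization(sig, ev)
        assert np.isfinite(f["Sa_mfcc_mean_1"])
        assert math.isnan(f["Sa_mfcc_std_1"])

    def test_levinson_recovers_ar_coefficients(self, rng):
        # AR(2) process: x[n] = 1.0*x[n-1] - 0.5*x[n-2] + e[n]
        e = rng.standard_normal(50000)
        x = lfilter([1.0], [1.0, -1.0, 0.5], e)
        a = levinson_lpc(x, 2)
        assert a[0] == pytest.approx(-1.0, abs=0.02)
        assert a[1] == pytest.approx(0.5, abs=0.02)


class TestBioFrequencies:
    def test_formants_recovered(self, rng):
        fs = 16000
        e = rng.standard_normal(16000) * 0.01
        y = e
        for f0, bw in ((500, 80), (1500, 90), (2500, 100)):
            r = math.exp(-math.pi * bw / fs)
            th = 2 * math.pi * f0 / fs
            y = lfilter([1 - r], [1, -2 * r * math.cos(th), r * r], y)
        sig, ev = signal_event(y * 5)
        f = bio_frequencies(sig, ev)
        assert f["Sb_formant1"] == pytest.approx(500, abs=75)
        assert f["Sb_formant2"] == pytest.approx(1500, abs=75)
        assert f["Sb_formant3"] == pytest.approx(2500, abs=75)

    def test_pulse_train_pitch(self):
        fs = 16000
        x = np.zeros(fs)
        x[::160] = 1.0  # 100 Hz
        r = 0.97
        x = lfilter([1 - r], [1, -2 * r * math.cos(2 * math.pi * 600 / fs), r * r], x)
        sig, ev = signal_event(x)
        f = bio_frequencies(sig, ev)
        assert f["Sb_pitch"] == pytest.approx(100, abs=2)
        assert f["Sb_voiced_fraction"] > 0.9
        assert f["Sb_pitch_present"] == 1.0

    def test_white_noise_unvoiced(self, rng):
        sig, ev = signal_event(rng.standard_normal(16000) * 0.05)
        f = bio_frequencies(sig, ev)
        assert math.isnan(f["Sb_pitch"])
        assert f["Sb_pitch_present"] == 0.0
        assert f["Sb_voiced_fraction"] == 0.0


class TestDynamicFrequencies:
    def test_repeated_spectrum_zero_flux(self):
        block = np.sin(2 * np.pi * 300 * np.arange(640) / 16000)
        sig, ev = signal_event(np.tile(block, 25) * 0.1)
        f = dynamic_frequency_features(sig, ev)
        assert f["Sc_flux_mean"] == pytest.approx(0.0, abs=1e-6)
        assert f["Sc_corr_mean"] == pytest.approx(1.0, abs=1e-6)

    def test_stationary_snore_flux_below_sweep(self, rng):
        fs = 16000
        stationary = lfilter([0.1], [1, -0.9], rng.standard_normal(fs))
        t = np.arange(fs) / fs
        sweep = np.sin(2 * np.pi * (300 + 2000 * t) * t)
        rms = np.sqrt(np.mean(stationary**2))
        sweep = sweep / np.sqrt(np.mean(sweep**2)) * rms
        s1, e1 = signal_event(stationary * 0.1)
        s2, e2 = signal_event(sweep * 0.1)
        assert dynamic_frequency_features(s1, e1)["Sc_flux_mean"] < dynamic_frequency_features(s2, e2)["Sc_flux_mean"]

    def test_too_short_flags_missing(self, rng):
        sig, ev = signal_event(rng.standard_normal(700) * 0.05)
        f = dynamic_frequency_features(sig, ev)
        assert math.isnan(f["Sc_flux_mean"])


class TestExtractAll:
    @pytest.fixture(scope="class")
    def night_event(self):
        from snoredetect.synthetic import generate_snore_event

        rng = np.random.default_rng(9)
        fs = 16000
        snippet = generate_snore_event(1.0, 60.0, rng=np.random.default_rng(3))
        samples = rng.standard_normal(fs * 30) * 1e-3
        i0 = fs * 15
        samples[i0 : i0 + snippet.size] += snippet
        sig = AudioSignal(np.clip(samples, -1, 1), fs)
        track = frame_energy(sig, FrameSpec())
        fr = track.frame_rate
        ev = AudioEvent(int(15 * fr), int(16 * fr), start_s=15.0, end_s=16.0,
                        intensity_db=60.0, peak_db=63.0, snr_db=25.0)
        return ev, sig, track

    def test_exactly_127_slots_with_category_counts(self, night_event):
        ev, sig, track = night_event
        fv = extract_all(ev, sig, track)
        assert list(fv.values.keys()) == FEATURE_NAMES
        counts = {}
        for name in fv.values:
            counts[name.split("_")[0]] = counts.get(name.split("_")[0], 0) + 1
        assert counts == CATEGORY_SIZES

    def test_deterministic(self, night_event):
        ev, sig, track = night_event
        a = extract_all(ev, sig, track).to_array()
        b = extract_all(ev, sig, track).to_array()
        np.testing.assert_array_equal(a, b)

    def test_event_at_recording_start_truncates_ep(self):
        from snoredetect.synthetic import generate_snore_event

        fs = 16000
        rng = np.random.default_rng(5)
        snippet = generate_snore_event(1.0, 60.0, rng=np.random.default_rng(4))
        samples = rng.standard_normal(fs * 8) * 1e-3
        samples[fs : fs + snippet.size] += snippet
        sig = AudioSignal(np.clip(samples, -1, 1), fs)
        track = frame_energy(sig, FrameSpec())
        fr = track.frame_rate
        ev = AudioEvent(int(fr), int(2 * fr), start_s=1.0, end_s=2.0,
                        intensity_db=60.0, peak_db=63.0, snr_db=25.0)
        fv = extract_all(ev, sig, track)
        assert np.isfinite(fv.values["Ta_ep"])
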