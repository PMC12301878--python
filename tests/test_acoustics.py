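"""Acoustic feature extraction checked against the synthesis cycle ledger."""

import math

import numpy as np
import pytest

from lespeech.acoustics import (
    AcousticConfig,
    Waveform,
    cpp,
    envelope_sd,
    extract_features,
    f0_track,
    formant_stats,
    hnr,
    jitter_local,
    measure_cycles,
    pitch_stats,
    shimmer_local,
)
from lespeech.synth import VoiceSpec, gen_transcript, gen_voice


def make_tone(freq=200.0, dur=1.0, fs=16000, am_depth=0.0, am_freq=4.0):
    t = np.arange(int(dur * fs)) / fs
    env = 1.0 + am_depth * np.sin(2 * np.pi * am_freq * t)
    return Waveform(0.5 * env * np.sin(2 * np.pi * freq * t) / (1 + am_depth), fs)


class TestF0Track:
    def test_pulse_train_pitch(self, clean_voice):
        mean, sd = pitch_stats(f0_track(clean_voice.waveform))
        assert abs(mean - 150.0) < 2.0
        assert sd < 2.0

    def test_white_noise_mostly_unvoiced(self, white_noise_waveform):
        track = f0_track(white_noise_waveform)
        assert np.mean(track.voiced) <= 0.10

    def test_silence_all_unvoiced(self):
        track = f0_track(Waveform(np.zeros(16000), 16000))
        assert not track.voiced.any()

    def test_bad_band_rejected(self, clean_voice):
        with pytest.raises(ValueError):
            f0_track(clean_voice.waveform, AcousticConfig(fmin_hz=500, fmax_hz=75))


class TestPitchStats:
    def test_population_sd_convention(self):
        from lespeech.acoustics import F0Track

        track = F0Track(
            times_s=np.array([0.0, 0.1]),
            f0_hz=np.array([100.0, 200.0]),
            voiced=np.array([True, True]),
            corr=np.ones(2),
        )
        mean, sd = pitch_stats(track)
        assert mean == 150.0 and sd == 50.0

    def test_empty_track_missing(self):
        from lespeech.acoustics import F0Track

        track = F0Track(np.zeros(0), np.zeros(0), np.zeros(0, dtype=bool), np.zeros(0))
        mean, sd = pitch_stats(track)
        assert math.isnan(mean) and math.isnan(sd)


class TestFormants:
    def test_resonator_recovery(self, typical_voice):
        f1m, f1s, f2m, f2s = formant_stats(typical_voice.waveform)
        assert abs(f1m - 500) / 500 < 0.10
        assert abs(f2m - 1500) / 1500 < 0.10

    def test_unvoiced_noise_missing(self, white_noise_waveform):
        f1m, *_ = formant_stats(white_noise_waveform)
        assert math.isnan(f1m)

    def test_deterministic(self, typical_voice):
        a = formant_stats(typical_voice.waveform)
        b = formant_stats(typical_voice.waveform)
        assert a == b


class TestEnvelope:
    def test_constant_tone_near_zero(self):
        assert envelope_sd(make_tone()) < 0.02

    def test_monotone_in_am_depth(self):
        vals = [envelope_sd(make_tone(am_depth=m)) for m in (0.0, 0.2, 0.5, 0.8)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_gain_invariance(self):
        w = make_tone(am_depth=0.4)
        scaled = Waveform(0.4 * w.samples, w.sample_rate_hz)
        assert envelope_sd(scaled) == pytest.approx(envelope_sd(w), rel=1e-9)

    def test_silence_missing(self):
        assert math.isnan(envelope_sd(Waveform(np.zeros(16000), 16000)))


class TestHNR:
    def test_clean_pulse_train_high(self, clean_voice):
        assert hnr(clean_voice.waveform) >= 30.0

    def test_tracks_set_snr(self):
        for snr in (10.0, 20.0, 30.0):
            v = gen_voice(
                VoiceSpec(f0_hz=120, jitter_pct=0.2, shimmer_pct=0.5, snr_db=snr),
                seed=21,
            )
            assert abs(hnr(v.waveform) - snr) <= 3.0

    def test_white_noise_low(self, white_noise_waveform):
        val = hnr(white_noise_waveform)
        assert math.isnan(val) or val <= 0.0


class TestJitterShimmerArithmetic:
    def test_constant_periods_zero(self):
        assert jitter_local([0.010, 0.010, 0.010]) == 0.0

    def test_alternating_periods(self):
        assert jitter_local([0.0099, 0.0101] * 5) == pytest.approx(0.2 / 10, rel=1e-6)

    def test_scale_invariance(self):
        p = [0.009, 0.011, 0.010, 0.0105]
        assert jitter_local(p) == pytest.approx(jitter_local([2 * x for x in p]))

    def test_constant_amplitudes_zero(self):
        assert shimmer_local([1.0, 1.0, 1.0]) == 0.0

    def test_alternating_amplitudes(self):
        assert shimmer_local([0.95, 1.05] * 5) == pytest.approx(0.10, rel=1e-6)

    def test_too_few_missing(self):
        assert math.isnan(jitter_local([0.01]))
        assert math.isnan(shimmer_local([1.0]))


class TestJitterRecovery:
    def test_monotone_and_within_band(self):
        measured = []
        for jp in (0.0, 1.0, 2.0, 4.0):
            vals = []
            for seed in range(3):
                v = gen_voice(
                    VoiceSpec(f0_hz=120, jitter_pct=jp, shimmer_pct=0.0, snr_db=None),
                    seed=seed,
                )
                periods, _ = measure_cycles(v.waveform)
                vals.append(jitter_local(periods))
            measured.append(np.mean(vals))
        assert all(a < b for a, b in zip(measured, measured[1:]))
        for jp, m in zip((1.0, 2.0, 4.0), measured[1:]):
            assert abs(m - jp / 100) / (jp / 100) <= 0.25


class TestCPP:
    def test_periodic_above_noise(self, clean_voice, white_noise_waveform):
        assert cpp(clean_voice.waveform) > cpp(white_noise_waveform)

    def test_monotone_degradation_with_noise(self):
        vals = []
        for snr in (30.0, 20.0, 10.0, 0.0):
            v = gen_voice(
                VoiceSpec(f0_hz=120, jitter_pct=0.3, shimmer_pct=1.0, snr_db=snr),
                seed=8,
            )
            vals.append(cpp(v.waveform))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_silence_missing(self):
        assert math.isnan(cpp(Waveform(np.zeros(16000), 16000)))


class TestGainInvariance:
    def test_all_features_gain_invariant(self, typical_voice):
        w = typical_voice.waveform
        scaled = Waveform(0.5 * w.samples, w.sample_rate_hz)
        for fn in (hnr, envelope_sd, cpp):
            assert fn(scaled) == pytest.approx(fn(w), rel=1e-6, abs=1e-9)
        assert pitch_stats(f0_track(scaled))[0] == pytest.approx(
            pitch_stats(f0_track(w))[0], rel=1e-6
        )
        pj, aj = measure_cycles(w)
        ps, as_ = measure_cycles(scaled)
        assert jitter_local(ps) == pytest.approx(jitter_local(pj), rel=1e-6)
        assert shimmer_local(as_) == pytest.approx(shimmer_local(aj), rel=1e-6)


class TestExtractFeatures:
    def test_clean_recording_fully_populated(self, typical_voice):
        t = gen_transcript("one two three four five six seven", 140.0, seed=5)
        fv = extract_features(typical_voice.waveform, t)
        vals = fv.as_dict()
        assert all(np.isfinite(v) for v in vals.values()), vals

    def test_silent_audio_acoustics_missing_rate_present(self):
        t = gen_transcript("one two three four five six seven", 140.0, seed=5)
        fv = extract_features(Waveform(np.zeros(16000), 16000), t)
        assert math.isnan(fv.pitch_mean_hz) and math.isnan(fv.hnr_db)
        assert np.isfinite(fv.speaking_rate_wpm)

    def test_deterministic(self, typical_voice):
        t = gen_transcript("one two three four five six seven", 140.0, seed=5)
        a = extract_features(typical_voice.waveform, t).as_dict()
        b = extract_features(typical_voice.waveform, t).as_dict()
        assert a == b
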