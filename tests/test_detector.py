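import numpy as np
import pytest
from scipy.stats import skew

from hfokit.core.config import DetectorConfig
from hfokit.core.model import Band, ChannelInfo, Condition, Recording
from hfokit.detect import (
    analytic_envelope,
    bandpass_fir,
    detect_all,
    detect_channel,
    extract_events,
    skewness_threshold,
    smooth_normalize,
)
from hfokit.synth import SimulationSpec, gabor_atom, plant_events, score_detections, simulate_background

RATE = 2000.0


def _sine(freq, duration=10.0, amplitude=1.0):
    t = np.arange(0, duration, 1 / RATE)
    return amplitude * np.cos(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_gain_near_unity(self):
        out = bandpass_fir(_sine(120.0), RATE, Band.BROAD_HFO)
        env = analytic_envelope(out, RATE).a_t[2000:-2000]
        assert np.median(env) == pytest.approx(1.0, abs=0.05)

    def test_stopband_rejection(self):
        out = bandpass_fir(_sine(20.0), RATE, Band.BROAD_HFO)
        assert np.abs(out[2000:-2000]).max() < 0.01

    def test_dc_rejected(self):
        # DC leakage bounded by the window-method stopband floor
        out = bandpass_fir(np.full(30_000, 7.5), RATE, Band.BROAD_HFO)
        assert np.abs(out[2000:-2000]).max() < 1e-3 * 7.5

    def test_fast_ripple_band_excludes_ripple(self):
        out = bandpass_fir(_sine(120.0), RATE, Band.FAST_RIPPLE)
        assert np.abs(out[2000:-2000]).max() < 0.01

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="filter order"):
            bandpass_fir(np.zeros(500), RATE, Band.BROAD_HFO)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_fir(np.zeros(5000), 1150.0, Band.BROAD_HFO)

    def test_zero_phase_no_shift(self):
        # a symmetric burst stays centred after filtering
        atom = gabor_atom(RATE, 140.0, 8, 1.0)
        x = np.zeros(10_000)
        x[5000 - len(atom) // 2 : 5000 + len(atom) // 2 + 1] = atom
        out = bandpass_fir(x, RATE, Band.BROAD_HFO)
        assert abs(int(np.argmax(np.abs(out))) - 5000) <= 2


class TestEnvelope:
    def test_zero_signal_zero_envelope(self):
        env = analytic_envelope(np.zeros(4000), RATE)
        assert np.all(env.a_t == 0.0)

    def test_pure_sine_closed_form(self):
        # envelope of A cos(2 pi 140 t) is A
        env = analytic_envelope(_sine(140.0, amplitude=10.0), RATE)
        core = env.a_t[2000:-2000]
        assert np.median(core) == pytest.approx(10.0, rel=0.02)

    def test_gabor_peak_matches_amplitude(self):
        atom = gabor_atom(RATE, 140.0, 10, 25.0)
        x = np.concatenate([np.zeros(2000), atom, np.zeros(2000)])
        env = analytic_envelope(x, RATE)
        assert env.a_t.max() == pytest.approx(25.0, rel=0.05)

    def test_phase_present(self):
        env = analytic_envelope(_sine(100.0), RATE)
        assert env.phi_t.shape == env.a_t.shape


class TestSmoothNormalize:
    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        z = smooth_normalize(np.abs(rng.normal(0, 1, 50_000)), 40.0, RATE)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_envelope_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="constant envelope"):
            z = smooth_normalize(np.full(10_000, 3.3), 40.0, RATE)
        assert np.all(z == 0.0)

    def test_moving_average_variance_reduction(self):
        # white noise smoothed by an 81-sample window: variance / ~81
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 2_000_000)
        n_win = 81
        from scipy.ndimage import uniform_filter1d

        smoothed = uniform_filter1d(x, size=n_win, mode="reflect")
        assert x.var() / smoothed.var() == pytest.approx(n_win, rel=0.05)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="longer than series"):
            smooth_normalize(np.zeros(10), 40.0, RATE)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.normal(0, 1, 20_000))
        z1 = smooth_normalize(a, 40.0, RATE)
        z2 = smooth_normalize(7.3 * a, 40.0, RATE)
        np.testing.assert_allclose(z1, z2, atol=1e-9)


class TestSkewnessThreshold:
    def test_symmetric_series_gives_base(self):
        x = np.concatenate([np.linspace(-1, 1, 10_001)])
        assert skewness_threshold(x) == pytest.approx(3.0)

    def test_affine_mapping_at_skew_two(self):
        # construct a series with sample skewness == 2 via a scaled exponential
        rng = np.random.default_rng(3)
        x = rng.exponential(1.0, 2_000_000)  # skewness -> 2
        assert skew(x) == pytest.approx(2.0, abs=0.02)
        assert skewness_threshold(x, ceiling=6.0) == pytest.approx(4.0, abs=0.02)

    def test_negative_skew_clamped_to_floor(self):
        rng = np.random.default_rng(4)
        x = -rng.exponential(1.0, 100_000)
        assert skewness_threshold(x) == 3.0

    def test_rayleigh_envelope_closed_form(self):
        # skewness of a Rayleigh envelope: 2 sqrt(pi) (pi - 3) / (4 - pi)^1.5
        expected_skew = 2 * np.sqrt(np.pi) * (np.pi - 3) / (4 - np.pi) ** 1.5
        rng = np.random.default_rng(5)
        env = np.abs(rng.normal(size=1_000_000) + 1j * rng.normal(size=1_000_000))
        assert skew(env) == pytest.approx(expected_skew, abs=0.01)
        threshold = skewness_threshold(env, ceiling=6.0)
        assert threshold == pytest.approx(3.0 + 0.5 * expected_skew, abs=0.05)

    def test_monotone_in_skewness(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 100_000)
        thresholds = [
            skewness_threshold(base + s * rng.exponential(1.0, 100_000), ceiling=6.0)
            for s in (0.0, 0.5, 1.0, 2.0)
        ]
        assert thresholds == sorted(thresholds)


class TestExtractEvents:
    def test_subthreshold_envelope_gives_nothing(self):
        z = np.zeros(40_000)
        assert extract_events(z, 3.0, Band.BROAD_HFO, RATE) == []

    def test_merge_rule(self):
        # two suprathreshold runs separated by < merge gap -> one event
        z = np.zeros(10_000)
        z[1000:1060] = 5.0
        z[1070:1130] = 5.0  # 5 ms gap
        events = extract_events(z, 3.0, Band.BROAD_HFO, RATE, DetectorConfig())
        assert len(events) == 1

    def test_separate_beyond_gap(self):
        z = np.zeros(10_000)
        z[1000:1060] = 5.0
        z[1200:1260] = 5.0  # 70 ms gap
        events = extract_events(z, 3.0, Band.BROAD_HFO, RATE, DetectorConfig())
        assert len(events) == 2

    def test_minimum_duration_gates_core_run(self):
        z = np.zeros(10_000)
        z[1000:1020] = 5.0  # 10 ms: below the 20 ms broad-band floor
        assert extract_events(z, 3.0, Band.BROAD_HFO, RATE, DetectorConfig()) == []
        assert len(extract_events(z, 3.0, Band.FAST_RIPPLE, RATE, DetectorConfig())) == 1

    def test_boundary_walkout_to_half_threshold(self):
        z = np.zeros(10_000)
        z[900:1000] = 2.0  # above half threshold only
        z[1000:1100] = 5.0
        events = extract_events(z, 3.0, Band.BROAD_HFO, RATE, DetectorConfig())
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(900 / RATE, abs=2 / RATE)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            extract_events(np.zeros(100), 0.0, Band.BROAD_HFO, RATE)


class TestDetectChannel:
    def test_single_strong_atom_exactly_one_event(self, default_spec):
        rng = np.random.default_rng(11)
        bg = simulate_background(
            30.0, RATE, Condition.INTRAOP, default_spec, n_channels=1, rng=rng
        ).samples[0]
        # scale the atom to 12x the in-band background SD
        inband_sd = bandpass_fir(bg, RATE, Band.BROAD_HFO).std()
        atom = gabor_atom(RATE, 140.0, 10, 12.0 * inband_sd * np.sqrt(2))
        onset = int(15.0 * RATE)
        sig = bg.copy()
        sig[onset : onset + len(atom)] += atom
        events = detect_channel(sig, RATE, DetectorConfig(), Band.BROAD_HFO, "c")
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(15.0, abs=0.010)

    def test_amplitude_equivariance(self, planted_channel):
        recording, _ = planted_channel
        signal = recording.samples[0][: int(60 * RATE)]
        cfg = DetectorConfig()
        a = detect_channel(signal, RATE, cfg, Band.BROAD_HFO, "c")
        b = detect_channel(4.2 * signal, RATE, cfg, Band.BROAD_HFO, "c")
        assert [(e.onset_s, e.offset_s) for e in a] == [(e.onset_s, e.offset_s) for e in b]


class TestDetectAll:
    def test_zero_recording_no_candidates(self):
        rec = Recording(
            samples=np.zeros((2, int(30 * RATE))),
            rate_hz=RATE,
            channel_ids=("a", "b"),
        )
        infos = [ChannelInfo(channel_id=c, patient_id="p") for c in rec.channel_ids]
        assert detect_all(rec, infos, DetectorConfig()) == []

    def test_deterministic(self, planted_channel):
        recording, _ = planted_channel
        infos = [ChannelInfo(channel_id=c, patient_id="p") for c in recording.channel_ids]
        a = detect_all(recording, infos, DetectorConfig())
        b = detect_all(recording, infos, DetectorConfig())
        assert a == b

    def test_recall_and_precision_on_planted_channel(self, planted_channel):
        recording, truth = planted_channel
        infos = [ChannelInfo(channel_id=c, patient_id="p") for c in recording.channel_ids]
        scores = score_detections(detect_all(recording, infos, DetectorConfig()), truth)
        assert scores["recall"] >= 0.9
        assert scores["precision"] >= 0.8

    def test_recall_monotone_in_snr(self, default_spec):
        rng = np.random.default_rng(21)
        recalls = []
        for amp in (25.0, 45.0, 80.0):
            spec = SimulationSpec(
                seed=1,
                event_amplitude_uv=amp,
                spike_amplitude_uv=4 * amp,
                base_rates_per_min={"RonO": 3.0, "RonS": 0, "fRonO": 2.0, "fRonS": 0, "SharpSpike": 0},
            )
            bg = simulate_background(
                120.0, RATE, Condition.INTRAOP, spec, n_channels=1,
                rng=np.random.default_rng(33),
            )
            rec, truth = plant_events(bg, spec, seed=5)
            infos = [ChannelInfo(channel_id=c, patient_id="p") for c in rec.channel_ids]
            scores = score_detections(detect_all(rec, infos, DetectorConfig()), truth)
            recalls.append(scores["recall"])
        assert recalls[0] <= recalls[1] + 0.05
        assert recalls[1] <= recalls[2] + 0.05
        assert recalls[2] >= 0.9

    def test_bipolar_candidates_deduplicated(self, default_spec):
        rng = np.random.default_rng(8)
        bg = simulate_background(
            30.0, RATE, Condition.INTRAOP, default_spec, n_channels=2, rng=rng
        )
        sig = bg.samples.copy()
        atom = gabor_atom(RATE, 140.0, 10, 90.0)
        onset = int(12.0 * RATE)
        sig[0, onset : onset + len(atom)] += atom  # only channel 0 sees the event
        rec = Recording(samples=sig, rate_hz=RATE, channel_ids=bg.channel_ids)
        infos = [
            ChannelInfo(
                channel_id=bg.channel_ids[0], patient_id="p",
                montage_partner=bg.channel_ids[1],
            ),
            ChannelInfo(channel_id=bg.channel_ids[1], patient_id="p"),
        ]
        candidates = detect_all(rec, infos, DetectorConfig())
        hits = [
            c for c in candidates
            if c.channel_id == bg.channel_ids[0] and abs(c.onset_s - 12.0) < 0.05
        ]
        assert len(hits) == 1  # referential + bipolar + both bands -> one kept
        assert hits[0].montage.value == "referential"
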