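import numpy as np
import pytest

from ethoarena import synth
from ethoarena.acoustics import (AudioBlock, DegenerateArrayError,
                                 DetectorParams, MicArray, bandpass_filter,
                                 compute_snr, detect_events, estimate_toads,
                                 jackknife_error, localize_events,
                                 localize_source, pick_loudest_channel,
                                 select_channels, toads_from_position)

FS = 100_000.0


def tone(freq, duration=0.1, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


@pytest.fixture
def default_array(arena_config):
    return arena_config.mic_array()


@pytest.fixture
def bounds(arena_config):
    return np.vstack([arena_config.box_min, arena_config.box_max])


class TestBandpass:
    def test_passband_preserves_amplitude(self):
        audio = AudioBlock(tone(2000.0), FS)
        out = bandpass_filter(audio, 1000.0, 4000.0)
        mid = slice(2000, -2000)
        ratio = (np.sqrt(np.mean(out.samples[0, mid] ** 2))
                 / np.sqrt(np.mean(audio.samples[0, mid] ** 2)))
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuation(self):
        audio = AudioBlock(tone(10_000.0), FS)
        out = bandpass_filter(audio, 1000.0, 4000.0)
        mid = slice(2000, -2000)
        atten = 20 * np.log10(
            np.sqrt(np.mean(audio.samples[0, mid] ** 2))
            / max(np.sqrt(np.mean(out.samples[0, mid] ** 2)), 1e-30))
        assert atten >= 40.0

    def test_low_zero_is_lowpass(self):
        audio = AudioBlock(tone(2000.0), FS)
        out = bandpass_filter(audio, 0.0, 4000.0)
        assert out.n_samples == audio.n_samples
        mid = slice(2000, -2000)
        ratio = (np.sqrt(np.mean(out.samples[0, mid] ** 2))
                 / np.sqrt(np.mean(audio.samples[0, mid] ** 2)))
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_invalid_band(self):
        audio = AudioBlock(tone(2000.0), FS)
        with pytest.raises(ValueError):
            bandpass_filter(audio, 4000.0, 1000.0)
        with pytest.raises(ValueError):
            bandpass_filter(audio, 100.0, 60_000.0)

    def test_length_preserved(self):
        audio = AudioBlock(tone(2000.0), FS)
        assert bandpass_filter(audio, 500.0, 5000.0).n_samples == \
            audio.n_samples


class TestDetect:
    def test_pure_noise_low_false_positives(self, rng):
        # 60 s of seeded noise, k=8: expect under one false event per minute
        noise = rng.normal(0, 1.0, size=int(60 * 10_000))
        audio = AudioBlock(noise, 10_000.0)
        events = detect_events(audio, 0, DetectorParams(threshold_k=8.0))
        assert len(events) < 2

    def test_single_call_detected(self, small_config):
        scene = synth.simulate_scene(small_config, 1, 1.0,
                                     calls_per_individual=1, snr_db=20.0)
        assert len(scene.events) == 1
        truth = scene.events[0]
        events = detect_events(scene.audio, 0)
        assert len(events) == 1
        t0, t1 = events[0]
        # detection bounds near truth (allowing propagation delay)
        assert abs(t0 - truth.t_emit_s) < 0.05
        assert t1 > t0

    def test_merge_gap_fuses_close_events(self):
        fs = 10_000.0
        x = np.zeros(int(fs))
        w = tone(1000.0, 0.02, fs)
        x[1000:1000 + len(w)] += w
        gap = int(0.005 * fs)
        x[1000 + len(w) + gap:1000 + 2 * len(w) + gap] += w
        audio = AudioBlock(x + 1e-4 * np.random.default_rng(0).normal(
            size=len(x)), fs)
        fused = detect_events(audio, 0, DetectorParams(merge_gap_s=0.01))
        assert len(fused) == 1
        split = detect_events(audio, 0, DetectorParams(
            envelope_window_s=0.001, merge_gap_s=0.001))
        assert len(split) == 2

    def test_empty_audio(self):
        audio = AudioBlock(np.zeros((1, 0)), FS)
        assert detect_events(audio, 0) == []


class TestChannelSelection:
    def test_noiseless_render_selects_all(self, small_config):
        scene = synth.simulate_scene(small_config, 1, 1.0,
                                     calls_per_individual=1, snr_db=None)
        ev = scene.events[0]
        sel = select_channels(scene.audio, (ev.t_emit_s, ev.t_emit_s + 0.12),
                              min_snr_db=6.0, min_channels=4)
        assert sel == list(range(small_config.n_mics))

    def test_nearest_mics_rank_first(self, small_config):
        scene = synth.simulate_scene(small_config, 1, 1.0,
                                     calls_per_individual=1, snr_db=15.0)
        ev = scene.events[0]
        mics = small_config.mic_array()
        dists = np.linalg.norm(mics.positions - ev.position, axis=1)
        window = (ev.t_emit_s + dists.min() / 343.0,
                  ev.t_emit_s + dists.min() / 343.0 + 0.12)
        snrs = [compute_snr(scene.audio, window, ch)
                for ch in range(len(mics))]
        # SNR ordering should broadly follow inverse distance
        from scipy.stats import spearmanr
        rho, _ = spearmanr(snrs, -dists)
        assert rho > 0.7

    def test_min_channels_topup(self, rng):
        # only one loud channel, but min_channels forces 4
        x = rng.normal(0, 1e-3, size=(6, 5000))
        x[2, 2000:3000] += tone(1000.0, 0.01, FS)[:1000] * 5
        audio = AudioBlock(x, FS)
        sel = select_channels(audio, (0.02, 0.03), min_snr_db=6.0,
                              min_channels=4)
        assert len(sel) == 4
        assert 2 in sel


class TestEstimateToads:
    def test_integer_shift_exact(self):
        rng = np.random.default_rng(5)
        sig = rng.normal(size=4000)
        shift = 25
        x = np.zeros((2, 5000))
        x[0, 100:100 + len(sig)] = sig
        x[1, 100 + shift:100 + shift + len(sig)] = sig
        audio = AudioBlock(x, FS)
        taus = estimate_toads(audio, (0.0, 0.05), [0, 1], ref_channel=0)
        assert taus[0] == 0.0
        assert taus[1] == pytest.approx(shift / FS, abs=1e-7)

    def test_rendered_event_matches_geometry(self, small_config):
        scene = synth.simulate_scene(small_config, 1, 1.0,
                                     calls_per_individual=1, snr_db=None)
        ev = scene.events[0]
        mics = small_config.mic_array()
        audio = scene.audio
        channels = list(range(len(mics)))
        taus = estimate_toads(audio, (ev.t_emit_s, ev.t_emit_s + 0.14),
                              channels, ref_channel=0)
        truth = toads_from_position(ev.position, mics, ref=0)
        assert np.max(np.abs(taus - truth)) <= 1.0 / audio.fs_hz

    def test_swap_ref_negates(self):
        rng = np.random.default_rng(6)
        sig = rng.normal(size=4000)
        x = np.zeros((2, 5000))
        x[0, 100:4100] = sig
        x[1, 140:4140] = sig
        audio = AudioBlock(x, FS)
        t01 = estimate_toads(audio, (0.0, 0.05), [0, 1], ref_channel=0)
        t10 = estimate_toads(audio, (0.0, 0.05), [0, 1], ref_channel=1)
        assert t01[1] == pytest.approx(-t10[0], abs=1e-7)

    def test_flat_correlation_errors(self):
        audio = AudioBlock(np.zeros((2, 1000)), FS)
        with pytest.raises(ValueError, match="flat"):
            estimate_toads(audio, (0.0, 0.01), [0, 1], ref_channel=0)


class TestLocalize:
    def test_exact_toads_center(self, default_array, bounds, arena_config):
        src = np.array([arena_config.length_m / 2,
                        arena_config.width_m / 2, 1.5])
        taus = toads_from_position(src, default_array, ref=0)
        res = localize_source(taus, default_array, bounds=bounds, ref=0)
        assert np.linalg.norm(res.position - src) < 1e-3

    def test_forward_inverse_random_interior(self, default_array, bounds,
                                             rng):
        for _ in range(20):
            src = rng.uniform([0.5, 0.5, 0.2], [14.0, 6.0, 3.3])
            taus = toads_from_position(src, default_array, ref=0)
            res = localize_source(taus, default_array, bounds=bounds, ref=0)
            assert np.linalg.norm(res.position - src) < 1e-3

    def test_zero_toads_symmetric_square(self):
        mics = MicArray(["a", "b", "c", "d"],
                        [[-1, -1, 2], [1, -1, 2], [1, 1, 2], [-1, 1, 2]])
        res = localize_source(np.zeros(4), mics,
                              bounds=np.array([[-2, -2, 0], [2, 2, 2]]))
        assert abs(res.position[0]) < 1e-6
        assert abs(res.position[1]) < 1e-6

    def test_residual_optimality(self, default_array, bounds, rng):
        src = rng.uniform([1, 1, 0.5], [13, 5.5, 3.0])
        taus = toads_from_position(src, default_array, ref=0)
        taus += rng.normal(0, 2e-5, size=len(taus))
        taus[0] = 0.0
        res = localize_source(taus, default_array, bounds=bounds, ref=0)
        c = default_array.speed_of_sound_m_s
        d_true = np.linalg.norm(default_array.positions - src, axis=1)
        resid_true = (d_true - d_true[0]) / c - taus
        assert (res.residual_rms_s ** 2
                <= np.mean(resid_true ** 2) + 1e-12)

    def test_error_monotone_in_noise(self, default_array, bounds):
        rng = np.random.default_rng(11)
        sigmas = [0.0, 2e-5, 1e-4]
        medians = []
        srcs = rng.uniform([1, 1, 0.3], [13, 5.5, 3.2], size=(25, 3))
        for sigma in sigmas:
            errs = []
            for src in srcs:
                taus = toads_from_position(src, default_array, ref=0)
                taus = taus + rng.normal(0, sigma, size=len(taus))
                taus[0] = 0.0
                res = localize_source(taus, default_array, bounds=bounds,
                                      ref=0)
                errs.append(np.linalg.norm(res.position - src))
            medians.append(np.median(errs))
        assert medians[0] < medians[1] < medians[2]

    def test_no_solution_above_mic_plane(self, default_array, bounds):
        rng = np.random.default_rng(12)
        for _ in range(10):
            src = rng.uniform([1, 1, 0.3], [13, 5.5, 3.2])
            taus = toads_from_position(src, default_array, ref=0)
            taus = taus + rng.normal(0, 1e-4, size=len(taus))
            taus[0] = 0.0
            res = localize_source(taus, default_array, bounds=bounds, ref=0)
            assert res.position[2] <= bounds[1][2] + 1e-9

    def test_too_few_receivers(self):
        mics = MicArray(["a", "b", "c"], [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.raises(DegenerateArrayError):
            localize_source(np.zeros(3), mics)


class TestJackknife:
    def test_exact_toads_tiny_spread(self, default_array, bounds):
        src = np.array([5.0, 3.0, 1.5])
        taus = toads_from_position(src, default_array, ref=0)
        spread = jackknife_error(taus, default_array, bounds=bounds, ref=0)
        assert spread < 1e-3

    def test_corrupted_toad_increases_spread(self, default_array, bounds):
        src = np.array([5.0, 3.0, 1.5])
        taus = toads_from_position(src, default_array, ref=0)
        clean = jackknife_error(taus, default_array, bounds=bounds, ref=0)
        bad = taus.copy()
        bad[7] += 10 / 100_000.0
        corrupted = jackknife_error(bad, default_array, bounds=bounds, ref=0)
        assert corrupted > clean

    def test_spread_tracks_true_error(self, arena_config, bounds):
        # use a sparse 10-mic array so each leave-one-out solve is fast
        mics = arena_config.mic_array().subset(range(0, 30, 3))
        rng = np.random.default_rng(21)
        spreads, errors = [], []
        for _ in range(40):
            src = rng.uniform([1, 1, 0.3], [13, 5.5, 3.2])
            taus = toads_from_position(src, mics, ref=0)
            taus = taus + rng.normal(0, rng.uniform(0, 2e-4), size=len(taus))
            taus[0] = 0.0
            res = localize_source(taus, mics, bounds=bounds, ref=0)
            spreads.append(jackknife_error(taus, mics, bounds=bounds, ref=0))
            errors.append(np.linalg.norm(res.position - src))
        from scipy.stats import spearmanr
        rho, _ = spearmanr(spreads, errors)
        assert rho > 0.5

    def test_degenerate(self):
        mics = MicArray(list("abcd"),
                        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(DegenerateArrayError):
            jackknife_error(np.zeros(4), mics)


class TestSnr:
    def test_amplitude_ratio_10x(self, rng):
        fs = 10_000.0
        noise = rng.normal(0, 0.1, size=int(fs))
        x = noise.copy()
        sig = rng.normal(0, 1.0, size=2000)
        x[5000:7000] += sig
        audio = AudioBlock(x, fs)
        snr = compute_snr(audio, (0.5, 0.7), 0)
        assert snr == pytest.approx(20.0, abs=1.0)

    def test_identical_windows_zero_db(self, rng):
        fs = 10_000.0
        x = np.tile(rng.normal(size=1000), 4)
        audio = AudioBlock(x, fs)
        assert compute_snr(audio, (0.1, 0.2), 0) == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_monotone_in_amplitude(self, small_config):
        snrs = []
        for amp_db in (10.0, 20.0, 30.0):
            scene = synth.simulate_scene(small_config, 1, 1.0,
                                         calls_per_individual=1,
                                         snr_db=amp_db)
            ev = scene.events[0]
            mics = small_config.mic_array()
            d = np.linalg.norm(mics.positions - ev.position, axis=1)
            ch = int(np.argmin(d))
            t0 = ev.t_emit_s + d[ch] / 343.0
            snrs.append(compute_snr(scene.audio, (t0, t0 + 0.12), ch))
        assert snrs[0] < snrs[1] < snrs[2]

    def test_zero_noise_errors(self):
        audio = AudioBlock(np.concatenate([np.zeros(1000),
                                           np.ones(1000)]), FS)
        with pytest.raises(ValueError):
            compute_snr(audio, (0.01, 0.02), 0)


class TestLoudestChannel:
    def test_nearest_mic_is_loudest(self, small_config):
        scene = synth.simulate_scene(small_config, 1, 1.0,
                                     calls_per_individual=1, snr_db=None)
        ev = scene.events[0]
        mics = small_config.mic_array()
        nearest = int(np.argmin(np.linalg.norm(
            mics.positions - ev.position, axis=1)))
        ch = pick_loudest_channel(scene.audio,
                                  (ev.t_emit_s, ev.t_emit_s + 0.14))
        assert ch == nearest

    def test_tie_gives_lowest_index(self):
        audio = AudioBlock(np.ones((3, 100)), FS)
        assert pick_loudest_channel(audio, (0.0, 0.0005)) == 0


class TestPipeline:
    def test_localize_events_recovers_truth(self, small_config):
        scene = synth.simulate_scene(small_config, 2, 3.0,
                                     calls_per_individual=2, snr_db=25.0)
        bounds = np.vstack([small_config.box_min, small_config.box_max])
        events = localize_events(scene.audio, small_config.mic_array(),
                                 band=(300.0, 15_000.0), bounds=bounds,
                                 min_channels=6)
        located = [e for e in events if e.est_position is not None]
        assert len(located) == len(scene.events)
        for truth in scene.events:
            best = min(located,
                       key=lambda e: abs(e.t_start_s - truth.t_emit_s))
            assert np.linalg.norm(best.est_position - truth.position) < 0.15
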