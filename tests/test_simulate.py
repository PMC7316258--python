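import numpy as np
import pytest

import poolloc as pl
from poolloc.simulate import (
    MultiChannelRecording,
    SimulationConfig,
    build_image_sources,
    dataset_manifest,
    iter_synthetic_recordings,
    simulate_propagation,
)

SRC = (15.33, -5.03, -4.27)   # the deep mid-pool source station


@pytest.fixture(scope="module")
def short_tonal(env, example_spec):
    return pl.synthesize_tonal(example_spec, env.sampling_rate)


class TestImageSources:
    def test_order_zero_is_just_the_source(self, env):
        sim = SimulationConfig(max_reflection_order=0)
        imgs = build_image_sources(SRC, env, sim)
        assert len(imgs) == 1
        assert imgs[0].order == 0 and imgs[0].gain == 1.0
        assert np.allclose(imgs[0].position, SRC)

    def test_surface_mirror_formula(self, env):
        sim = SimulationConfig(max_reflection_order=1)
        imgs = build_image_sources(SRC, env, sim)
        surf = [im for im in imgs if im.order == 1
                and np.isclose(im.position[0], SRC[0])
                and im.position[2] > env.surface_z]
        assert surf, "no surface image found"
        assert surf[0].position[2] == pytest.approx(
            2 * env.surface_z - SRC[2]
        )
        assert surf[0].gain == pytest.approx(sim.surface_coeff)

    def test_image_count_nondecreasing_in_order(self, env):
        counts = [
            len(build_image_sources(
                SRC, env, SimulationConfig(max_reflection_order=k,
                                           n_wall_facets=8)))
            for k in range(4)
        ]
        assert counts == sorted(counts)

    def test_outside_pool_rejected(self, env):
        with pytest.raises(ValueError):
            build_image_sources((100.0, 0.0, 0.0), env, SimulationConfig())

    def test_gain_magnitudes_bounded(self, env):
        sim = SimulationConfig(max_reflection_order=2, n_wall_facets=8)
        for im in build_image_sources(SRC, env, sim):
            assert abs(im.gain) <= 1.0 + 1e-12


class TestPropagation:
    def test_anechoic_xcorr_peak_at_expected_lag(self, env, geometry,
                                                 short_tonal):
        sim = SimulationConfig(max_reflection_order=0, noise_rms=0.0)
        rec = simulate_propagation(short_tonal, SRC, geometry, env, sim)
        tau = pl.expected_tdoas(SRC, geometry, env.sound_speed)
        fs = env.sampling_rate
        for (i, j), t in [((1, 13), tau[11]), ((5, 9), None)]:
            a, b = rec.data[i - 1], rec.data[j - 1]
            n = a.size
            r = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), n)
            k = np.argmax(r)
            lag = k if k <= n // 2 else k - n
            expected = pl.expected_tdoas(SRC, geometry, env.sound_speed)
            pair_idx = pl.canonical_pairs().index((i, j))
            assert abs(lag - expected[pair_idx] * fs) <= 1.0

    def test_anechoic_amplitude_inverse_distance(self, env, geometry,
                                                 short_tonal):
        sim = SimulationConfig(max_reflection_order=0, noise_rms=0.0)
        rec = simulate_propagation(short_tonal, SRC, geometry, env, sim)
        d = np.linalg.norm(geometry.positions - np.asarray(SRC), axis=1)
        peaks = np.max(np.abs(rec.data), axis=1)
        ratios = peaks * d
        assert np.std(ratios) / np.mean(ratios) < 0.02

    def test_reverb_overlaps_arrivals(self, env, geometry, short_tonal):
        """With order >= 2, energy keeps arriving after the dry tonal has
        ended (overlapping multipath arrivals); anechoic output does not."""
        fs = env.sampling_rate
        d0 = np.linalg.norm(np.asarray(SRC) - geometry.positions[0])
        cutoff = int((d0 / env.sound_speed + short_tonal.duration) * fs
                     + 0.005 * fs)

        def tail_fraction(order):
            sim = SimulationConfig(max_reflection_order=order,
                                   noise_rms=0.0, n_wall_facets=16)
            x = simulate_propagation(
                short_tonal, SRC, geometry, env, sim).data[0]
            e = np.asarray(x, dtype=np.float64) ** 2
            return e[cutoff:].sum() / e.sum()

        assert tail_fraction(0) < 1e-8
        assert tail_fraction(2) > 1e-5

    def test_noise_rms_doubling_costs_6db(self, env, geometry, short_tonal):
        clean = simulate_propagation(
            short_tonal, SRC, geometry, env,
            SimulationConfig(max_reflection_order=0, noise_rms=0.0))
        snrs = []
        for rms in (0.1, 0.2):
            sim = SimulationConfig(max_reflection_order=0, noise_rms=rms,
                                   rng_seed=9)
            rec = simulate_propagation(short_tonal, SRC, geometry, env, sim)
            noise = rec.data - clean.data
            snr = 10 * np.log10(np.mean(clean.data.astype(np.float64) ** 2)
                                / np.mean(noise.astype(np.float64) ** 2))
            snrs.append(snr)
        assert snrs[0] - snrs[1] == pytest.approx(6.0, abs=0.3)

    def test_fs_mismatch_rejected(self, env, short_tonal):
        bad = pl.Waveform(short_tonal.samples, 48000.0)
        with pytest.raises(ValueError):
            simulate_propagation(bad, SRC, env=env)


class TestDatasetGeneration:
    def test_manifest_combinatorics(self, tonal_grid):
        man = dataset_manifest(tonal_grid, list(pl.DEFAULT_SOURCE_LOCATIONS))
        assert len(man) == 14 * 128

    def test_same_seed_bit_identical(self, tonal_grid):
        locs = list(pl.DEFAULT_SOURCE_LOCATIONS)[:2]
        sim = SimulationConfig(rng_seed=42)
        a = dataset_manifest(tonal_grid[:4], locs, sim)
        b = dataset_manifest(tonal_grid[:4], locs, sim)
        assert a.equals(b)

    def test_sway_within_radius(self, tonal_grid):
        man = dataset_manifest(tonal_grid[:16],
                               list(pl.DEFAULT_SOURCE_LOCATIONS))
        d = np.hypot(man["x"] - man["nominal_x"],
                     man["y"] - man["nominal_y"])
        assert np.all(d <= 1 / 3 + 1e-12)
        assert np.all(man["z"] == man["nominal_z"])

    def test_generate_dataset_writes_wavs_and_manifest(
        self, env, example_spec, tmp_path, locations_by_id
    ):
        from poolloc.simulate import generate_synthetic_dataset
        sim = SimulationConfig(max_reflection_order=0, noise_rms=0.0,
                               rng_seed=1, n_wall_facets=8)
        man = generate_synthetic_dataset(
            [example_spec], [locations_by_id["P6"]], env, sim,
            out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        wav = tmp_path / man.iloc[0]["file"]
        assert wav.exists()
        back = MultiChannelRecording.from_wav(wav)
        assert back.data.shape[0] == 16

    def test_recording_determinism_and_wav_roundtrip(
        self, env, example_spec, tmp_path, locations_by_id
    ):
        sim = SimulationConfig(max_reflection_order=1, noise_rms=0.05,
                               rng_seed=3, n_wall_facets=8)
        man = dataset_manifest([example_spec], [locations_by_id["P6"]], sim)
        _, rec1 = next(iter_synthetic_recordings(
            man, [example_spec], None, env, sim))
        _, rec2 = next(iter_synthetic_recordings(
            man, [example_spec], None, env, sim))
        assert np.array_equal(rec1.data, rec2.data)
        path = tmp_path / "rec.wav"
        rec1.to_wav(path)
        back = MultiChannelRecording.from_wav(path)
        assert back.fs == env.sampling_rate
        assert np.array_equal(back.data, rec1.data.astype(np.float32))
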