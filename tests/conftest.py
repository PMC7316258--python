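import numpy as np
import pytest

import poolloc as pl
from poolloc.simulate import SimulationConfig, iter_synthetic_recordings


@pytest.fixture(scope="session")
def env():
    return pl.EnvironmentConfig()


@pytest.fixture(scope="session")
def geometry():
    return pl.DEFAULT_HYDROPHONES


@pytest.fixture(scope="session")
def locations_by_id():
    return {loc.id: loc for loc in pl.DEFAULT_SOURCE_LOCATIONS}


@pytest.fixture(scope="session")
def tonal_grid():
    return pl.build_parameter_grid()


@pytest.fixture(scope="session")
def example_spec(tonal_grid):
    """The worked-example tonal: 0.3 s, 2 cycles, 10.5 kHz +- 2 kHz,
    phase -pi/2, onset fraction 0.1, sinusoid."""
    matches = [
        s for s in tonal_grid
        if s.duration == 0.3 and s.n_cycles == 2
        and s.center_freq == 10500.0 and s.cycle_amp == 2000.0
        and s.phase_start < 0 and s.onset_fraction == 0.1
        and s.waveform_kind == "sinusoid"
    ]
    assert len(matches) == 1
    return matches[0]


@pytest.fixture(scope="session")
def anechoic_p10(env, example_spec, locations_by_id):
    """One anechoic, noiseless playback of the example tonal from a swayed
    P10 source, carried through leader detection, windowing and
    band-passing.  Returns (snippet, true swayed source xyz)."""
    sim = SimulationConfig(max_reflection_order=0, noise_rms=0.0, rng_seed=0)
    manifest = pl.dataset_manifest([example_spec],
                                   [locations_by_id["P10"]], sim)
    row, rec = next(
        iter_synthetic_recordings(manifest, [example_spec], None, env, sim)
    )
    onsets = pl.detect_leader_tones(rec)
    assert len(onsets) == 1
    snip = pl.extract_snippet(rec, onsets[0], example_spec, "P10",
                              (row["x"], row["y"], row["z"]))
    return pl.bandpass_snippet(snip, example_spec), \
        np.array([row["x"], row["y"], row["z"]])
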