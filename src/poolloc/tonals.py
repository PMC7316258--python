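"""Synthesis of whistle-like FM tonals.

Each tonal is defined by a sinusoidal instantaneous-frequency trace

    f(t) = Fc + A_cyc * sin(2*pi*n_cycles*t/X + alpha),

whose phase Phi(t) = 2*pi * integral of f is rendered either as a plain
sinusoid y = A(t)*sin(Phi) or, via the arcsine heuristic,
y = A(t)*arcsin(m*sin(Phi))/arcsin(m), which makes the waveform more
triangular and stacks odd harmonics above the fundamental.  A(t) is a
sin^2 onset/decay envelope covering a fraction P of the duration at each
end.  The default grid of parameter values spans published bottlenose
whistle ranges and yields 64 parameter permutations x 2 waveform kinds =
128 unique tonals.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.io import wavfile

__all__ = [
    "TonalSpec",
    "Waveform",
    "TABLE_GRID",
    "build_parameter_grid",
    "instantaneous_frequency",
    "synthesize_tonal",
    "make_playback_track",
    "LEADER_FREQ",
    "LEADER_DURATION",
    "LEADER_TO_TONAL_GAP",
]

#: Default tonal parameter value sets (two values per parameter).
TABLE_GRID: dict[str, tuple[float, float]] = {
    "duration": (0.3, 1.0),                  # s
    "n_cycles": (1, 2),
    "center_freq": (6000.0, 10500.0),        # Hz
    "cycle_amp": (2000.0, 5000.0),           # Hz
    "phase_start": (-math.pi / 2, math.pi / 2),
    "onset_fraction": (0.1, 0.25),
}

LEADER_FREQ = 2000.0        # Hz
LEADER_DURATION = 0.25      # s
LEADER_TO_TONAL_GAP = 2.0   # s, leader onset -> tonal onset


@dataclass(frozen=True)
class TonalSpec:
    """Parameters fully determining one synthetic whistle-like tonal."""

    duration: float            # X, s
    n_cycles: float            # frequency-trace cycles over the duration
    center_freq: float         # Fc, Hz
    cycle_amp: float           # A_cyc, Hz
    phase_start: float         # alpha, rad (phase of the FM sinusoid)
    onset_fraction: float      # P, fraction of duration for onset/decay
    waveform_kind: str = "sinusoid"     # "sinusoid" | "triangular"
    m: float = 0.8             # triangularity, only used when triangular
    tonal_id: str = ""

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 0 < self.onset_fraction < 0.5:
            raise ValueError("onset_fraction must be in (0, 0.5)")
        if self.center_freq - self.cycle_amp <= 0:
            raise ValueError("center_freq - cycle_amp must stay > 0")
        if self.waveform_kind not in ("sinusoid", "triangular"):
            raise ValueError(f"unknown waveform_kind {self.waveform_kind!r}")
        if self.waveform_kind == "triangular" and not 0 < self.m < 1:
            raise ValueError("m must be in (0, 1) for triangular tonals")

    @property
    def sibling_group(self) -> str:
        """Identifier shared by the sinusoid/triangular pair of a
        parameter permutation (used to co-assign them in partitions)."""
        return self.tonal_id.rsplit("-", 1)[0] if self.tonal_id else ""

    @property
    def band(self) -> tuple[float, float]:
        """Analysis band (Hz): frequency extent plus 0.5 kHz margins."""
        return (self.center_freq - self.cycle_amp - 500.0,
                self.center_freq + self.cycle_amp + 500.0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )
        if self.samples.size and np.max(np.abs(self.samples)) > 1 + 1e-9:
            raise ValueError("waveform samples must lie in [-1, 1]")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def to_wav(self, path) -> None:
        """Write a mono float32 WAV plus a TonalSpec sidecar is written by
        callers that have the spec; here just the audio."""
        wavfile.write(path, int(self.fs), self.samples.astype(np.float32))


def build_parameter_grid(table: dict | None = None) -> list[TonalSpec]:
    """Cartesian product of parameter value sets x {sinusoid, triangular}.

    Ordering is the product order of the table's parameters (duration
    slowest, onset fraction fastest) with the sinusoid sibling before the
    triangular one; ids are stable across runs.
    """
    table = dict(TABLE_GRID if table is None else table)
    for key in TABLE_GRID:
        if key not in table or len(tuple(table[key])) == 0:
            raise ValueError(f"parameter {key!r} needs at least one value")
    specs = []
    combos = itertools.product(*(tuple(table[k]) for k in TABLE_GRID))
    for gi, (dur, ncyc, fc, amp, alpha, pfrac) in enumerate(combos):
        for kind, suffix in (("sinusoid", "sin"), ("triangular", "tri")):
            specs.append(TonalSpec(
                duration=dur, n_cycles=ncyc, center_freq=fc, cycle_amp=amp,
                phase_start=alpha, onset_fraction=pfrac, waveform_kind=kind,
                tonal_id=f"T{gi:03d}-{suffix}",
            ))
    return specs


def instantaneous_frequency(spec: TonalSpec, t) -> np.ndarray:
    """f(t) in Hz at time(s) t in [0, duration]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > spec.duration):
        raise ValueError("t must lie within [0, duration]")
    return spec.center_freq + spec.cycle_amp * np.sin(
        2 * np.pi * spec.n_cycles * t / spec.duration + spec.phase_start
    )


def _envelope(spec: TonalSpec, t: np.ndarray) -> np.ndarray:
    X, P = spec.duration, spec.onset_fraction
    ramp = X * P
    onset = np.where(t < ramp, np.sin(t * 2 * np.pi / (4 * ramp)) ** 2, 1.0)
    decay = np.where(
        t > X - ramp, np.sin((X - t) * 2 * np.pi / (4 * ramp)) ** 2, 1.0
    )
    # If the ramps overlap (2XP > X) the two windows multiply; the default
    # grid never triggers this.
    return onset * decay


def synthesize_tonal(
    spec: TonalSpec, fs: float = 192_000.0, carrier_phase_offset: bool = False
) -> Waveform:
    """Render a tonal to samples at rate fs.

    The phase is integrated numerically (trapezoidal cumulative sum) so
    arbitrary frequency traces can be swapped in.  `carrier_phase_offset`
    additionally adds `phase_start` to the carrier phase (a literal reading
    of y = A sin(Phi + alpha)); by default alpha acts only inside f(t),
    which is what makes the tonals' traces distinct.
    """
    if fs < 2 * (spec.center_freq + spec.cycle_amp):
        raise ValueError(
            f"fs={fs} violates Nyquist for band up to "
            f"{spec.center_freq + spec.cycle_amp} Hz"
        )
    n = round(spec.duration * fs)
    t = np.arange(n) / fs
    f = instantaneous_frequency(spec, t)
    phi = 2 * np.pi * cumulative_trapezoid(f, t, initial=0.0)
    if carrier_phase_offset:
        phi = phi + spec.phase_start
    env = _envelope(spec, t)
    if spec.waveform_kind == "sinusoid":
        y = env * np.sin(phi)
    else:
        y = env * np.arcsin(spec.m * np.sin(phi)) / np.arcsin(spec.m)
    return Waveform(y, fs)


def make_playback_track(
    tonal: Waveform,
    fs: float | None = None,
    leader_amplitude: float = 0.7,
    tail: float = 1.75,
) -> tuple[Waveform, float]:
    """Assemble [leader tone | gap | tonal | tail padding].

    The 0.25-s, 2-kHz leader starts at t = 0 and precedes the tonal onset
    by exactly 2 s.  Returns (track, leader_onset_seconds); the tail keeps
    the track long enough for the snippet window (leader + 3.5 s).

    The leader gets a 5-ms cosine taper at both ends to avoid clicks.
    """
    fs = tonal.fs if fs is None else fs
    if fs != tonal.fs:
        raise ValueError("track fs must match the tonal's fs")
    n_leader = round(LEADER_DURATION * fs)
    t = np.arange(n_leader) / fs
    leader = leader_amplitude * np.sin(2 * np.pi * LEADER_FREQ * t)
    n_taper = max(1, round(0.005 * fs))
    w = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
    leader[:n_taper] *= w
    leader[-n_taper:] *= w[::-1]

    tonal_start = round(LEADER_TO_TONAL_GAP * fs)
    total = max(
        tonal_start + tonal.samples.size + round(tail * fs),
        round(3.6 * fs),
    )
    track = np.zeros(total)
    track[:n_leader] = leader
    track[tonal_start:tonal_start + tonal.samples.size] = tonal.samples
    return Waveform(track, fs), 0.0
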