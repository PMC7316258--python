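"""Snippet extraction and partitioning.

A playback session is a long 16-channel recording in which every tonal is
preceded, 2 s earlier, by a 0.25-s 2-kHz leader tone.  Leaders are found
by normalized matched filtering on one designated channel; each snippet
is the 2-s window starting 1.5 s after a leader onset, so a tonal played
2 s after the leader (duration <= 1 s) sits fully inside it.  Snippets
are band-passed around their tonal's known frequency extent with 0.5-kHz
margins, and partitioned ~90/10 into train/test, stratified per source
location with sinusoid/triangular sibling tonals co-assigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, fftconvolve, sosfiltfilt

from .simulate import MultiChannelRecording
from .tonals import LEADER_DURATION, LEADER_FREQ, TonalSpec

__all__ = [
    "Snippet",
    "Partition",
    "SNIPPET_DURATION",
    "detect_leader_tones",
    "extract_snippet",
    "bandpass_snippet",
    "split_train_test",
]

SNIPPET_DURATION = 2.0          # s
WINDOW_OFFSET = 1.5             # s after leader onset
BANDPASS_ORDER = 6              # Butterworth sections; zero-phase doubles it


@dataclass(frozen=True)
class Snippet:
    """A 2-s, 16-channel block with source labels (labels may be None for
    field recordings)."""

    recording: MultiChannelRecording
    tonal_id: str | None = None
    location_id: str | None = None
    source_coords: tuple[float, float, float] | None = None
    band: tuple[float, float] | None = None

    def __post_init__(self):
        n_expected = round(SNIPPET_DURATION * self.recording.fs)
        if self.recording.n_samples != n_expected:
            raise ValueError(
                f"snippet must be exactly {SNIPPET_DURATION} s "
                f"({n_expected} samples at fs={self.recording.fs})"
            )

    @property
    def data(self) -> np.ndarray:
        return self.recording.data

    @property
    def fs(self) -> float:
        return self.recording.fs


def detect_leader_tones(
    recording: MultiChannelRecording,
    channel: int = 1,
    threshold: float = 0.2,
    min_separation: float = 1.0,
) -> list[float]:
    """Onset times (s) of 2-kHz leader tones on one channel.

    Uses a normalized matched filter: correlation with the leader template
    divided by the local signal energy, so the statistic is ~1 for a clean
    leader and small for noise regardless of level.  Peaks above
    `threshold` separated by at least `min_separation` seconds are kept,
    in increasing time order.  No detection returns an empty list.

    The default threshold sits far above the noise floor of the statistic
    (~1/sqrt(template length) ~ 0.005) while tolerating the partial phase
    cancellation multipath can inflict on the received leader.
    """
    fs = recording.fs
    x = np.asarray(recording.data[channel - 1], dtype=np.float64)
    n_t = round(LEADER_DURATION * fs)
    t = np.arange(n_t) / fs
    template = np.sin(2 * np.pi * LEADER_FREQ * t)
    template /= np.linalg.norm(template)

    corr = fftconvolve(x, template[::-1], mode="valid")
    local_energy = fftconvolve(x * x, np.ones(n_t), mode="valid")
    stat = np.abs(corr) / np.sqrt(np.maximum(local_energy, 1e-30))
    # ignore windows with negligible energy (pure silence)
    stat[local_energy < 1e-12 * max(local_energy.max(), 1e-30)] = 0.0

    min_sep = round(min_separation * fs)
    onsets = []
    above = stat > threshold
    idx = 0
    while idx < stat.size:
        if above[idx]:
            seg_end = min(idx + min_sep, stat.size)
            peak = idx + int(np.argmax(stat[idx:seg_end]))
            onsets.append(peak / fs)
            idx = peak + min_sep
        else:
            idx += 1
    return onsets


def extract_snippet(
    recording: MultiChannelRecording,
    leader_onset: float,
    spec: TonalSpec | None = None,
    location_id: str | None = None,
    source_coords=None,
) -> Snippet:
    """The 2-s, 16-channel window starting 1.5 s after a leader onset."""
    fs = recording.fs
    start = round((leader_onset + WINDOW_OFFSET) * fs)
    stop = start + round(SNIPPET_DURATION * fs)
    if start < 0 or stop > recording.n_samples:
        raise ValueError(
            f"recording too short: need samples [{start}, {stop}) "
            f"but have {recording.n_samples}"
        )
    window = MultiChannelRecording(recording.data[:, start:stop], fs)
    return Snippet(
        window,
        tonal_id=spec.tonal_id if spec else None,
        location_id=location_id,
        source_coords=tuple(source_coords) if source_coords is not None
        else None,
    )


def bandpass_snippet(snippet: Snippet, spec: TonalSpec) -> Snippet:
    """Zero-phase band-pass around the tonal's frequency extent.

    Passband [Fc - A - 0.5 kHz, Fc + A + 0.5 kHz]; forward-backward
    Butterworth so all channels are filtered identically with no phase
    distortion (phase matters: the features are cross-correlations).
    """
    lo, hi = spec.band
    nyq = snippet.fs / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"invalid band ({lo}, {hi}) Hz for fs={snippet.fs}")
    sos = butter(BANDPASS_ORDER, [lo, hi], btype="bandpass", fs=snippet.fs,
                 output="sos")
    filtered = sosfiltfilt(sos, snippet.data, axis=1).astype(
        snippet.data.dtype
    )
    return Snippet(
        MultiChannelRecording(filtered, snippet.fs),
        tonal_id=snippet.tonal_id,
        location_id=snippet.location_id,
        source_coords=snippet.source_coords,
        band=(lo, hi),
    )


# --------------------------------------------------------------------------
# Train/test partition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids must be disjoint")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"train": list(self.train_ids),
                       "test": list(self.test_ids),
                       "seed": self.seed}, fh)

    @classmethod
    def from_json(cls, path) -> "Partition":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["train"]), tuple(d["test"]), int(d["seed"]))


def _sibling_group(tonal_id: str) -> str:
    return tonal_id.rsplit("-", 1)[0]


def split_train_test(
    manifest: pd.DataFrame, test_fraction: float = 0.10, seed: int = 0
) -> Partition:
    """Semi-random 90/10 split, stratified by source location with
    sinusoid/triangular sibling tonals co-assigned.

    Rows are identified by their `file` column.  Per location the number
    of test sibling groups is max(1, round(test_fraction * n_groups)), so
    every location contributes test snippets proportionally.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    required = {"file", "tonal_id", "location_id"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    test_files: list[str] = []
    train_files: list[str] = []
    for loc, sub in manifest.groupby("location_id", sort=True):
        groups = sorted(set(sub["tonal_id"].map(_sibling_group)))
        if len(groups) < 2:
            raise ValueError(
                f"location {loc!r} has {len(groups)} sibling group(s); "
                "need >= 2 to split"
            )
        n_test = max(1, round(test_fraction * len(groups)))
        chosen = set(
            rng.choice(groups, size=n_test, replace=False).tolist()
        )
        for _, row in sub.iterrows():
            dest = (test_files
                    if _sibling_group(row["tonal_id"]) in chosen
                    else train_files)
            dest.append(row["file"])
    return Partition(tuple(train_files), tuple(test_files), seed)
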