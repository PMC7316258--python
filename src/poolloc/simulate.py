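"""Synthetic-data generator: image-source reverberation in the half pool.

Sound from an in-pool source reaches each hydrophone directly and via
reflections off the water surface (pressure-release, negative
coefficient), the floor, the straight dividing wall and the curved wall.
Reflections are modeled with the image-source method; the curved wall is
approximated by tangent planar facets (exact curved-surface imaging has no
closed form, and facets converge as their count grows while keeping the
simulator desk-fast).  Each image contributes a 1/r-attenuated,
fractionally-delayed copy of the source waveform; ambient noise is
seeded Gaussian.

The dataset generator emulates a playback calibration session: for every
(source location x tonal) it draws a horizontally swayed source point
(rope-suspended speaker), simulates the full leader+tonal playback track
at all 16 channels, and records the true swayed coordinates in a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft
from scipy.io import wavfile

from .geometry import (
    EnvironmentConfig,
    HydrophoneGeometry,
    DEFAULT_HYDROPHONES,
    SourceLocation,
    in_pool,
)
from .tonals import TonalSpec, Waveform, synthesize_tonal, make_playback_track

__all__ = [
    "ImageSource",
    "SimulationConfig",
    "MultiChannelRecording",
    "build_image_sources",
    "valid_image_mask",
    "simulate_propagation",
    "dataset_manifest",
    "iter_synthetic_recordings",
    "generate_synthetic_dataset",
]

_SINC_HALF = 16  # windowed-sinc fractional-delay interpolator half-width


@dataclass(frozen=True)
class ImageSource:
    position: np.ndarray        # xyz, m
    gain: float                 # product of reflection coefficients
    order: int                  # number of reflections
    plane_seq: tuple[int, ...] = ()   # reflecting plane indices, in order


@dataclass(frozen=True)
class SimulationConfig:
    """Reverberation and noise settings for the synthetic pool.

    `noise_rms` is the ambient-noise RMS relative to each channel's clean
    (reverberant) signal RMS, so SNR_dB = -20*log10(noise_rms); 0.1 gives
    20 dB.  `sway_radius` is the horizontal speaker sway about the nominal
    location (rope suspension, ~1/3 m).
    """

    max_reflection_order: int = 2
    surface_coeff: float = -0.95
    floor_coeff: float = 0.7
    wall_coeff: float = 0.8
    n_wall_facets: int = 32
    noise_rms: float = 0.1
    sway_radius: float = 1.0 / 3.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("surface_coeff", "floor_coeff", "wall_coeff"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"|{name}| must be <= 1")
        if self.sway_radius < 0:
            raise ValueError("sway_radius must be >= 0")
        if self.max_reflection_order < 0:
            raise ValueError("max_reflection_order must be >= 0")


@dataclass(frozen=True)
class MultiChannelRecording:
    """16 aligned channels sharing one clock; channel order = channel index."""

    data: np.ndarray            # (16, n_samples)
    fs: float

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != 2 or d.shape[0] != 16:
            raise ValueError("data must have shape (16, n_samples)")
        object.__setattr__(self, "data", d)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_wav(self, path) -> None:
        wavfile.write(path, int(self.fs), self.data.T.astype(np.float32))

    @classmethod
    def from_wav(cls, path) -> "MultiChannelRecording":
        fs, data = wavfile.read(path)
        return cls(np.asarray(data, dtype=np.float32).T, float(fs))


def _pool_planes(env: EnvironmentConfig, sim: SimulationConfig):
    """(point, unit normal, coefficient) for every reflecting plane."""
    cx, cy = env.pool_center_xy
    planes = [
        (np.array([cx, cy, env.surface_z]), np.array([0.0, 0.0, 1.0]),
         sim.surface_coeff),
        (np.array([cx, cy, env.floor_z]), np.array([0.0, 0.0, 1.0]),
         sim.floor_coeff),
        # straight dividing wall along the circle's diameter
        (np.array([cx, cy, 0.0]), np.array([0.0, 1.0, 0.0]),
         sim.wall_coeff),
    ]
    # tangent facets along the lower semicircular arc
    k = np.arange(sim.n_wall_facets)
    theta = np.pi + (k + 0.5) * np.pi / sim.n_wall_facets
    for th in theta:
        n = np.array([np.cos(th), np.sin(th), 0.0])
        p0 = np.array([cx, cy, 0.0]) + env.pool_radius * n
        planes.append((p0, n, sim.wall_coeff))
    return planes


def build_image_sources(
    source, env: EnvironmentConfig, sim: SimulationConfig
) -> list[ImageSource]:
    """Order-0 source plus mirror images up to max_reflection_order.

    Gains multiply per bounce; immediate re-reflection across the plane
    just used is skipped (it would undo itself).
    """
    src = np.asarray(source, dtype=float)
    if not in_pool(src, env):
        raise ValueError(f"source {src.tolist()} is outside the pool")
    planes = _pool_planes(env, sim)
    images = [ImageSource(src, 1.0, 0)]
    frontier = [(src, 1.0, ())]  # (position, gain, plane sequence)
    for order in range(1, sim.max_reflection_order + 1):
        nxt = []
        for pos, gain, seq in frontier:
            for pi, (p0, n, coeff) in enumerate(planes):
                if seq and pi == seq[-1]:
                    continue
                mirrored = pos - 2.0 * np.dot(pos - p0, n) * n
                g = gain * coeff
                images.append(ImageSource(mirrored, g, order, seq + (pi,)))
                nxt.append((mirrored, g, seq + (pi,)))
        frontier = nxt
    return images


def _on_plane_extent(q: np.ndarray, pids: np.ndarray,
                     env: EnvironmentConfig, sim: SimulationConfig
                     ) -> np.ndarray:
    """Whether points q (m, 3) lie on the physical extent of their
    reflecting surface (plane index per row).  Plane 0/1 = surface/floor
    (pool footprint), 2 = straight dividing wall, 3.. = curved-wall
    facets (angular sector x depth strip)."""
    cx, cy = env.pool_center_xy
    R = env.pool_radius
    eps = 1e-9
    ok = np.zeros(q.shape[0], dtype=bool)

    flat = pids < 2
    if flat.any():
        p = q[flat]
        ok[flat] = (
            (p[:, 1] <= cy + eps)
            & ((p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 <= R ** 2 + eps)
        )
    chord = pids == 2
    if chord.any():
        p = q[chord]
        ok[chord] = (
            (np.abs(p[:, 0] - cx) <= R + eps)
            & (p[:, 2] >= env.floor_z - eps)
            & (p[:, 2] <= env.surface_z + eps)
        )
    facet = pids >= 3
    if facet.any():
        p = q[facet]
        k = pids[facet] - 3
        theta_k = np.pi + (k + 0.5) * np.pi / sim.n_wall_facets
        ang = np.mod(np.arctan2(p[:, 1] - cy, p[:, 0] - cx), 2 * np.pi)
        dang = np.abs(np.mod(ang - theta_k + np.pi, 2 * np.pi) - np.pi)
        half = np.pi / (2 * sim.n_wall_facets)
        ok[facet] = (
            (dang <= half + eps)
            & (p[:, 2] >= env.floor_z - eps)
            & (p[:, 2] <= env.surface_z + eps)
        )
    return ok


def valid_image_mask(
    images: list[ImageSource],
    receiver,
    env: EnvironmentConfig,
    sim: SimulationConfig,
) -> np.ndarray:
    """Specular-path validity of every image for one receiver.

    An image contributes only if the unfolded reflection path actually
    meets each reflecting surface within its physical extent: the segment
    from the receiver to the image must cross the last reflecting plane
    on the wall itself, and so on back to the source.  Without this check
    the faceted curved wall would contribute one bogus arrival per facet
    and the approximation would diverge as facets are added.
    """
    planes = _pool_planes(env, sim)
    normals = np.array([n for _, n, _ in planes])
    points = np.array([p0 for p0, _, _ in planes])
    recv = np.asarray(receiver, dtype=float)

    # prefix images: position of the source after the first j reflections
    prefix_pos: dict[tuple[int, ...], np.ndarray] = {}
    for im in images:
        prefix_pos[im.plane_seq] = im.position

    mask = np.ones(len(images), dtype=bool)
    by_order: dict[int, list[int]] = {}
    for i, im in enumerate(images):
        by_order.setdefault(im.order, []).append(i)

    for order, idxs in by_order.items():
        if order == 0:
            continue
        idxs = np.array(idxs)
        targets = np.array([images[i].position for i in idxs])
        start = np.tile(recv, (len(idxs), 1))
        alive = np.ones(len(idxs), dtype=bool)
        for step in range(order - 1, -1, -1):
            pids = np.array([images[i].plane_seq[step] for i in idxs])
            n = normals[pids]
            p0 = points[pids]
            d = targets - start
            denom = np.einsum("ij,ij->i", n, d)
            num = np.einsum("ij,ij->i", n, p0 - start)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = num / denom
            hit = np.isfinite(t) & (t > 1e-9) & (t < 1 - 1e-9)
            q = start + t[:, None] * d
            hit &= _on_plane_extent(q, pids, env, sim)
            alive &= hit
            # walk back: next segment runs from the wall point toward the
            # image one reflection shallower
            start = q
            targets = np.array([
                prefix_pos[images[i].plane_seq[:step]] for i in idxs
            ])
        mask[idxs] = alive
    return mask


def _impulse_response(delays: np.ndarray, gains: np.ndarray,
                      ir_len: int) -> np.ndarray:
    """Sum of windowed-sinc impulses (gain at fractional delay) into one IR.

    Order-32 Hann-windowed sinc interpolation, so time differences of
    arrival are not quantized to integer samples.  All delays must leave
    the 33-tap stencil inside [0, ir_len)."""
    centers = np.floor(delays).astype(np.int64)
    fracs = delays - centers
    k = np.arange(-_SINC_HALF, _SINC_HALF + 1)
    window = np.hanning(2 * _SINC_HALF + 3)[1:-1]
    taps = np.sinc(k[None, :] - fracs[:, None]) * window[None, :]
    taps *= gains[:, None]
    idx = centers[:, None] + k[None, :]
    ir = np.zeros(ir_len)
    np.add.at(ir, idx.ravel(), taps.ravel())
    return ir


def simulate_propagation(
    tonal: Waveform,
    source,
    geometry: HydrophoneGeometry | None = None,
    env: EnvironmentConfig | None = None,
    sim: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MultiChannelRecording:
    """Propagate a waveform from `source` to all 16 hydrophones.

    Each channel is the sum over image sources of gain/distance times the
    waveform delayed by distance/c (windowed-sinc fractional delay), plus
    seeded Gaussian noise at `sim.noise_rms` relative RMS.
    """
    env = env or EnvironmentConfig()
    geometry = geometry or DEFAULT_HYDROPHONES
    sim = sim or SimulationConfig()
    if tonal.fs != env.sampling_rate:
        raise ValueError("waveform fs must equal the environment fs")
    rng = rng if rng is not None else np.random.default_rng(sim.rng_seed)

    c = env.sound_speed
    fs = env.sampling_rate
    images = build_image_sources(source, env, sim)
    positions = np.array([im.position for im in images])
    gains = np.array([im.gain for im in images])
    hpos = geometry.positions

    dists = np.linalg.norm(positions[:, None, :] - hpos[None, :, :], axis=2)
    dists = np.maximum(dists, 1e-6)
    delays = dists / c * fs
    amps = gains[:, None] / dists
    # specular validity is receiver-dependent: an image only contributes
    # where its unfolded path meets every wall inside its physical extent
    valid = np.stack([
        valid_image_mask(images, hpos[ch], env, sim) for ch in range(16)
    ], axis=1)
    amps = np.where(valid, amps, 0.0)

    ir_len = int(np.max(delays)) + 2 * _SINC_HALF + 4
    # the +_SINC_HALF delay offset keeps early stencils in-bounds; it is
    # removed again when the convolution output is sliced
    irs = np.stack([
        _impulse_response(delays[:, ch] + _SINC_HALF, amps[:, ch], ir_len)
        for ch in range(16)
    ]).astype(np.float32)
    x = tonal.samples.astype(np.float32)
    n_out = x.size + ir_len - 1 - _SINC_HALF
    nfft = scipy.fft.next_fast_len(x.size + ir_len - 1)
    X = scipy.fft.rfft(x, nfft)
    Y = scipy.fft.irfft(X[None, :] * scipy.fft.rfft(irs, nfft, axis=1),
                        nfft, axis=1)
    out = np.ascontiguousarray(Y[:, _SINC_HALF:_SINC_HALF + n_out])
    if sim.noise_rms > 0:
        sigma = sim.noise_rms * np.sqrt(np.mean(out.astype(np.float64) ** 2,
                                                axis=1))
        out += (sigma[:, None].astype(np.float32)
                * rng.standard_normal(out.shape, dtype=np.float32))
    return MultiChannelRecording(out, fs)


# --------------------------------------------------------------------------
# Dataset generation
# --------------------------------------------------------------------------

def dataset_manifest(
    specs: list[TonalSpec],
    locations: list[SourceLocation],
    sim: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Plan a dataset: one row per (location x tonal) with the swayed
    source point and a per-recording child seed.  The manifest fully
    determines the audio, so the same seed yields a bit-identical dataset.
    """
    sim = sim or SimulationConfig()
    rng = np.random.default_rng(sim.rng_seed)
    rows = []
    for loc in locations:
        for spec in specs:
            u, v = rng.random(2)
            r = sim.sway_radius * np.sqrt(u)
            th = 2 * np.pi * v
            x = loc.position[0] + r * np.cos(th)
            y = loc.position[1] + r * np.sin(th)
            z = loc.position[2]
            child_seed = int(rng.integers(0, 2 ** 31 - 1))
            rows.append({
                "file": f"{loc.id}_{spec.tonal_id}.wav",
                "tonal_id": spec.tonal_id,
                "location_id": loc.id,
                # true swayed source point driving the simulation
                "x": x, "y": y, "z": z,
                # surveyed (nominal) location: the label a calibration
                # session would record
                "nominal_x": loc.position[0],
                "nominal_y": loc.position[1],
                "nominal_z": loc.position[2],
                "seed": child_seed,
            })
    return pd.DataFrame(rows)


def iter_synthetic_recordings(
    manifest: pd.DataFrame,
    specs: list[TonalSpec],
    geometry: HydrophoneGeometry | None = None,
    env: EnvironmentConfig | None = None,
    sim: SimulationConfig | None = None,
):
    """Yield (manifest row, playback MultiChannelRecording) lazily.

    Recordings are full playback tracks (leader + tonal); downstream code
    extracts 2-s snippets by leader detection.
    """
    env = env or EnvironmentConfig()
    sim = sim or SimulationConfig()
    by_id = {s.tonal_id: s for s in specs}
    for _, row in manifest.iterrows():
        spec = by_id[row["tonal_id"]]
        tonal = synthesize_tonal(spec, env.sampling_rate)
        track, _ = make_playback_track(tonal)
        rng = np.random.default_rng(int(row["seed"]))
        rec = simulate_propagation(
            track, (row["x"], row["y"], row["z"]), geometry, env, sim, rng
        )
        yield row, rec


def generate_synthetic_dataset(
    specs: list[TonalSpec],
    locations: list[SourceLocation],
    env: EnvironmentConfig | None = None,
    sim: SimulationConfig | None = None,
    geometry: HydrophoneGeometry | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Simulate every (location x tonal) and, if `out_dir` is given, write
    16-channel WAVs plus a manifest.csv there.  Returns the manifest."""
    import os

    manifest = dataset_manifest(specs, locations, sim)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for row, rec in iter_synthetic_recordings(
            manifest, specs, geometry, env, sim
        ):
            path = os.path.join(out_dir, row["file"])
            try:
                rec.to_wav(path)
            except OSError as exc:
                raise OSError(f"failed writing {path}: {exc}") from exc
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
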