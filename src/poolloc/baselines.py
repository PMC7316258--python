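"""Geometric comparison methods: Steered-Response Power and Spherical
Interpolation.

SRP grids the pool into cubes; each corner is scored by summing, over the
120 unique channel pairs, the pair's circular cross-correlation evaluated
at the corner's expected TDOA lag (rounded to the nearest sample).  The
argmax corner is the estimate; shifting waveforms by the true source's
TDOAs and summing dot products is exactly this correlation lookup.
PHAT-weighted correlations are available behind `use_phat` (kept as an
option, not the default).

Spherical Interpolation converts reference-channel range differences into
a closed-form least-squares source estimate via the linear system in
source position and source range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy.ndimage import maximum_filter1d

from .geometry import (
    CANONICAL_PAIRS,
    EnvironmentConfig,
    HydrophoneGeometry,
    DEFAULT_HYDROPHONES,
)
from .snippets import Snippet

__all__ = [
    "SRPConfig",
    "srp_localize",
    "SRPLocalizer",
    "pairwise_correlations",
    "spherical_interpolation",
]


@dataclass(frozen=True)
class SRPConfig:
    """Grid and weighting options for SRP localization.

    `lag_window` > 0 scores each corner with the maximum correlation
    within +-lag_window samples of the expected lag instead of the value
    at the rounded lag — a robust variant that tolerates the lag spread
    inside a grid cell.  Off (0) by default: the reference method is the
    plain corner lookup.
    """

    cube_edge: float = 0.15          # m
    use_phat: bool = False
    lag_window: int = 0              # samples
    search_bounds: tuple | None = None   # ((x0,x1),(y0,y1),(z0,z1)) or None
    chunk_size: int = 65536

    def __post_init__(self):
        if self.cube_edge <= 0:
            raise ValueError("cube_edge must be > 0")
        if self.lag_window < 0:
            raise ValueError("lag_window must be >= 0")


def pairwise_correlations(
    snippet: Snippet, use_phat: bool = False, phat_floor: float = 1e-12
) -> np.ndarray:
    """(120, n) circular cross-correlation series (FFT lag order) for the
    canonical non-self pairs; un-normalized (normalization cannot change
    the SRP argmax)."""
    data = np.asarray(snippet.data, dtype=np.float32)
    n = data.shape[1]
    F = scipy.fft.rfft(data, axis=1)
    out = np.empty((len(CANONICAL_PAIRS), n), dtype=np.float32)
    for p, (i, j) in enumerate(CANONICAL_PAIRS):
        G = F[i - 1] * np.conj(F[j - 1])
        if use_phat:
            mag = np.abs(G)
            G = G / np.maximum(mag, np.float32(phat_floor) * mag.max())
        out[p] = scipy.fft.irfft(G, n)
    return out


def _grid_axes(env: EnvironmentConfig, cfg: SRPConfig):
    cx, cy = env.pool_center_xy
    R = env.pool_radius
    if cfg.search_bounds is not None:
        (x0, x1), (y0, y1), (z0, z1) = cfg.search_bounds
    else:
        x0, x1 = cx - R, cx + R
        y0, y1 = cy - R, cy
        z0, z1 = env.floor_z, env.surface_z
    e = cfg.cube_edge
    xs = np.arange(x0, x1 + e / 2, e)
    ys = np.arange(y0, y1 + e / 2, e)
    zs = np.arange(z0, z1 + e / 2, e)
    return xs, ys, zs


def srp_localize(
    snippet: Snippet,
    geometry: HydrophoneGeometry | None = None,
    env: EnvironmentConfig | None = None,
    cfg: SRPConfig | None = None,
    correlations: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Steered-Response Power source estimate on a cube-corner grid.

    Grid corners outside the pool footprint are skipped.  Ties at the
    maximum score are broken by the smallest grid index (reported in the
    summary).  `correlations` may supply precomputed (120, n) series to
    avoid recomputation.

    Returns (xyz estimate, summary dict with score/ties/corner count).
    """
    env = env or EnvironmentConfig()
    geometry = geometry or DEFAULT_HYDROPHONES
    cfg = cfg or SRPConfig()
    corr = correlations if correlations is not None else \
        pairwise_correlations(snippet, use_phat=cfg.use_phat)
    if cfg.lag_window > 0:
        corr = maximum_filter1d(corr, size=2 * cfg.lag_window + 1,
                                axis=1, mode="wrap")
    n = corr.shape[1]
    fs = snippet.fs
    c = env.sound_speed
    hpos = geometry.positions
    i_idx = np.array([i - 1 for i, _ in CANONICAL_PAIRS])
    j_idx = np.array([j - 1 for _, j in CANONICAL_PAIRS])

    xs, ys, zs = _grid_axes(env, cfg)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    cx, cy = env.pool_center_xy
    inside = (
        (pts[:, 1] <= cy)
        & ((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
           <= env.pool_radius ** 2)
        & (pts[:, 2] >= env.floor_z) & (pts[:, 2] <= env.surface_z)
    )
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise ValueError("empty SRP search region")

    best_score = -np.inf
    best_point = None
    n_ties = 0
    pair_rows = np.arange(len(CANONICAL_PAIRS))[None, :]
    for start in range(0, pts.shape[0], cfg.chunk_size):
        P = pts[start:start + cfg.chunk_size]
        d = np.linalg.norm(P[:, None, :] - hpos[None, :, :], axis=2)
        lags = np.rint((d[:, i_idx] - d[:, j_idx]) / c * fs).astype(np.int64)
        idx = np.mod(lags, n)
        scores = corr[pair_rows, idx].sum(axis=1)
        k = int(np.argmax(scores))
        s = float(scores[k])
        if s > best_score:
            best_score = s
            best_point = P[k]          # first occurrence = smallest index
            n_ties = int(np.sum(scores == s)) - 1
        elif s == best_score:
            n_ties += int(np.sum(scores == s))
    return np.asarray(best_point), {
        "score": best_score,
        "n_ties": n_ties,
        "n_corners": int(pts.shape[0]),
        "cube_edge": cfg.cube_edge,
    }


class SRPLocalizer:
    """Convenience wrapper binding geometry/environment/config once."""

    def __init__(self, geometry=None, env=None, cfg=None):
        self.geometry = geometry or DEFAULT_HYDROPHONES
        self.env = env or EnvironmentConfig()
        self.cfg = cfg or SRPConfig()

    def localize(self, snippet: Snippet) -> tuple[np.ndarray, dict]:
        return srp_localize(snippet, self.geometry, self.env, self.cfg)


# --------------------------------------------------------------------------
# Spherical Interpolation
# --------------------------------------------------------------------------

def spherical_interpolation(
    tdoas, geometry: HydrophoneGeometry | None = None, c: float = 1533.0
) -> np.ndarray:
    """Closed-form least-squares source estimate from TDOAs.

    Accepts either the canonical 120-pair TDOA set (the reference-channel
    values tau_1j are its first 15 entries) or 15 reference-channel TDOAs
    directly.  With range differences delta_j = d_j - d_1 = -c * tau_1j,
    the source position x (relative to the reference hydrophone) and its
    range R satisfy the linear system

        2 (s_j . x) + 2 delta_j R = |s_j|^2 - delta_j^2,   j = 2..16,

    solved jointly in the least-squares sense.  Exact on consistent
    inputs; raises on a rank-deficient (collinear) array.
    """
    geometry = geometry or DEFAULT_HYDROPHONES
    tdoas = np.asarray(tdoas, dtype=float)
    if tdoas.shape == (len(CANONICAL_PAIRS),):
        tau_ref = tdoas[:15]          # pairs (1,2)..(1,16) lead the order
    elif tdoas.shape == (15,):
        tau_ref = tdoas
    else:
        raise ValueError("tdoas must have length 120 (canonical) or 15")
    if c <= 0:
        raise ValueError("sound speed must be > 0")

    pos = geometry.positions
    ref = pos[0]
    S = pos[1:] - ref                     # (15, 3)
    delta = -c * tau_ref                  # d_j - d_1
    A = np.column_stack([2.0 * S, 2.0 * delta])
    b = np.sum(S ** 2, axis=1) - delta ** 2
    if np.linalg.matrix_rank(A[:, :3], tol=1e-9) < 3:
        raise np.linalg.LinAlgError("hydrophone array is rank-deficient")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return ref + sol[:3]
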