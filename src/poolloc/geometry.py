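"""Physical environment of the half-cylindrical exhibit pool.

Coordinate convention: origin at the center of the first array's panel,
meters, z up.  The water surface sits at z = +1.60 m (the panels hang
1.60 m below the surface); the pool footprint is the closed bottom half of
a 33.5-m-diameter circle centered at (15.7, 3.87).  Pool floor depth is a
configuration parameter (the as-built depth is not public); the default of
7.0 m below the surface comfortably contains the deepest source (-4.27 m).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "EnvironmentConfig",
    "HydrophoneGeometry",
    "SourceLocation",
    "DEFAULT_HYDROPHONES",
    "DEFAULT_SOURCE_LOCATIONS",
    "canonical_pairs",
    "del_grosso_sound_speed",
    "expected_tdoas",
    "trilaterate",
    "in_pool",
    "load_environment",
]

N_CHANNELS = 16

#: Canonical ordering of hydrophone channel pairs: lexicographic (i, j),
#: i < j, 1-based channels 1..16.  Every module that touches pairs uses this.
CANONICAL_PAIRS: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(1, N_CHANNELS + 1), 2)
)

#: Pair ordering including self-pairs (i, i): lexicographic (i, j), i <= j.
CANONICAL_PAIRS_WITH_SELF: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations_with_replacement(range(1, N_CHANNELS + 1), 2)
)


def canonical_pairs(include_self: bool = False) -> tuple[tuple[int, int], ...]:
    """Return the canonical channel-pair ordering (1-based channels)."""
    return CANONICAL_PAIRS_WITH_SELF if include_self else CANONICAL_PAIRS


# --------------------------------------------------------------------------
# Sound speed
# --------------------------------------------------------------------------

def _validate_range(name: str, value: float, lo: float, hi: float) -> None:
    if not np.isfinite(value) or not (lo <= value <= hi):
        raise ValueError(
            f"{name}={value!r} outside supported range [{lo}, {hi}]"
        )


def del_grosso_sound_speed(
    temperature: float, salinity: float, depth: float = 0.0
) -> float:
    """Seawater sound speed (m/s) from the Del Grosso (1974) polynomial.

    Coefficients follow Del Grosso (1974), JASA 56(4):1084, in the restated
    form of Wong & Zhu (1995), JASA 97(3):1732, with pressure in kg/cm^2
    (gauge).  Depth is converted hydrostatically (~0.1024 kg/cm^2 per m);
    for a shallow pool the pressure terms are negligible.

    Parameters
    ----------
    temperature : float
        Water temperature, deg C, 0..35.
    salinity : float
        Salinity, ppt, 0..45.
    depth : float
        Depth below surface, m, >= 0.

    Returns
    -------
    float
        Sound speed in m/s.
    """
    _validate_range("temperature", temperature, 0.0, 35.0)
    _validate_range("salinity", salinity, 0.0, 45.0)
    if not np.isfinite(depth) or depth < 0:
        raise ValueError(f"depth={depth!r} must be finite and >= 0")

    T, S = float(temperature), float(salinity)
    P = 0.1024 * float(depth)  # kg/cm^2 gauge

    c_t = (0.501109398873e1 * T
           - 0.550946843172e-1 * T ** 2
           + 0.221535969240e-3 * T ** 3)
    c_s = 0.132952290781e1 * S + 0.128955756844e-3 * S ** 2
    c_p = (0.156059257041e0 * P
           + 0.244998688441e-4 * P ** 2
           - 0.883392332513e-8 * P ** 3)
    c_stp = (-0.127562783426e-1 * T * S
             + 0.635191613389e-2 * T * P
             + 0.265484716608e-7 * T ** 2 * P ** 2
             - 0.159349479045e-5 * T * P ** 2
             + 0.522116437235e-9 * T * P ** 3
             - 0.438031096213e-6 * T ** 3 * P
             - 0.161674495909e-8 * S ** 2 * P ** 2
             + 0.968403156410e-4 * T ** 2 * S
             + 0.485639620015e-5 * T * S ** 2 * P
             - 0.340597039004e-3 * T * S * P)
    return 1402.392 + c_t + c_s + c_p + c_stp


# --------------------------------------------------------------------------
# Configuration dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentConfig:
    """Pool environment: sampling, water properties, and footprint."""

    sampling_rate: float = 192_000.0
    temperature: float = 26.04
    salinity: float = 31.5
    depth_for_soundspeed: float = 0.0
    pool_center_xy: tuple[float, float] = (15.7, 3.87)
    pool_radius: float = 16.75
    pool_depth: float = 7.0          # m below the water surface
    surface_z: float = 1.60          # m, panel-center origin convention

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.pool_radius <= 0:
            raise ValueError("pool_radius must be > 0")
        if self.pool_depth < 5.87:
            raise ValueError("pool_depth must be >= 5.87 m (deepest source)")

    @property
    def sound_speed(self) -> float:
        """Sound speed (m/s) derived from (T, S, depth) via Del Grosso."""
        c = del_grosso_sound_speed(
            self.temperature, self.salinity, self.depth_for_soundspeed
        )
        if not 1400.0 < c < 1600.0:
            raise ValueError(f"derived sound speed {c:.1f} m/s implausible")
        return c

    @property
    def floor_z(self) -> float:
        return self.surface_z - self.pool_depth


@dataclass(frozen=True)
class HydrophoneRecord:
    channel_index: int          # 1..16
    array_id: str               # H1..H4
    local_address: str          # S1..S4
    position: tuple[float, float, float]


# As-measured hydrophone coordinates (m), four 4-hydrophone arrays.
_HYDROPHONE_TABLE = [
    (1, "H1", "S1", (0.0059, -0.0760, 0.1905)),
    (2, "H1", "S2", (-0.0059, 0.0760, 0.1905)),
    (3, "H1", "S3", (0.0059, -0.0760, -0.1905)),
    (4, "H1", "S4", (-0.0059, 0.0760, -0.1905)),
    (5, "H2", "S1", (9.1521, -10.5672, 0.1905)),
    (6, "H2", "S2", (9.0089, -10.5148, 0.1905)),
    (7, "H2", "S3", (9.1521, -10.5672, -0.1905)),
    (8, "H2", "S4", (9.0089, -10.5148, -0.1905)),
    (9, "H3", "S1", (23.2718, -10.3148, 0.1905)),
    (10, "H3", "S2", (23.1288, -10.3672, 0.1905)),
    (11, "H3", "S3", (23.2718, -10.3148, -0.1905)),
    (12, "H3", "S4", (23.1288, -10.3672, -0.1905)),
    (13, "H4", "S1", (31.7886, 0.2984, 0.1905)),
    (14, "H4", "S2", (31.7768, 0.1464, 0.1905)),
    (15, "H4", "S3", (31.7886, 0.2984, -0.1905)),
    (16, "H4", "S4", (31.7768, 0.1464, -0.1905)),
]


@dataclass(frozen=True)
class HydrophoneGeometry:
    """The 16-channel hydrophone layout (4 arrays x 4 channels)."""

    records: tuple[HydrophoneRecord, ...] = field(
        default_factory=lambda: tuple(
            HydrophoneRecord(*row) for row in _HYDROPHONE_TABLE
        )
    )

    def __post_init__(self):
        if len(self.records) != N_CHANNELS:
            raise ValueError("geometry must have exactly 16 channels")
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.array_id] = counts.get(rec.array_id, 0) + 1
        if any(v != 4 for v in counts.values()) or len(counts) != 4:
            raise ValueError("each of 4 array_ids must own exactly 4 channels")
        pos = self.positions
        if len({tuple(p) for p in pos}) != N_CHANNELS:
            raise ValueError("hydrophone positions must be distinct")

    @property
    def positions(self) -> np.ndarray:
        """(16, 3) array ordered by channel index 1..16."""
        ordered = sorted(self.records, key=lambda r: r.channel_index)
        return np.array([r.position for r in ordered], dtype=float)

    @property
    def array_ids(self) -> list[str]:
        ordered = sorted(self.records, key=lambda r: r.channel_index)
        return [r.array_id for r in ordered]


@dataclass(frozen=True)
class SourceLocation:
    id: str
    position: tuple[float, float, float]


# Surveyed speaker locations: 7 surface stations at two depths.
DEFAULT_SOURCE_LOCATIONS: tuple[SourceLocation, ...] = tuple(
    SourceLocation(i, p) for i, p in [
        ("P1", (8.84, -5.61, 0.00)),
        ("P2", (12.00, -5.49, 0.00)),
        ("P3", (15.18, -4.91, 0.00)),
        ("P4", (19.45, -5.03, 0.00)),
        ("P5", (22.19, -5.49, 0.00)),
        ("P6", (15.43, -2.02, 0.00)),
        ("P7", (15.24, -7.01, 0.00)),
        ("P8", (9.05, -5.88, -4.27)),
        ("P9", (12.13, -5.33, -4.27)),
        ("P10", (15.33, -5.03, -4.27)),
        ("P11", (19.23, -5.43, -4.27)),
        ("P12", (22.01, -5.36, -4.27)),
        ("P13", (15.39, -2.13, -4.27)),
        ("P14", (15.14, -7.62, -4.27)),
    ]
)

DEFAULT_HYDROPHONES = HydrophoneGeometry()


# --------------------------------------------------------------------------
# Ideal TDOAs
# --------------------------------------------------------------------------

def expected_tdoas(
    source, geometry: HydrophoneGeometry | None = None, c: float = 1533.0
) -> np.ndarray:
    """Ideal direct-path TDOAs (s) for the 120 canonical channel pairs.

    tau_ij = (|source - h_i| - |source - h_j|) / c; negative when channel i
    is closer (its arrival leads).
    """
    if geometry is None:
        geometry = DEFAULT_HYDROPHONES
    src = np.asarray(source, dtype=float)
    if src.shape != (3,) or not np.all(np.isfinite(src)):
        raise ValueError("source must be a finite xyz triple")
    if c <= 0:
        raise ValueError("sound speed must be > 0")
    dists = np.linalg.norm(geometry.positions - src, axis=1)
    i_idx = np.array([i - 1 for i, _ in CANONICAL_PAIRS])
    j_idx = np.array([j - 1 for _, j in CANONICAL_PAIRS])
    return (dists[i_idx] - dists[j_idx]) / c


def in_pool(point, env: EnvironmentConfig) -> bool:
    """True iff the point lies in the half-disk footprint between surface
    and floor (bottom half of the circle: y <= center_y)."""
    p = np.asarray(point, dtype=float)
    cx, cy = env.pool_center_xy
    if p[1] > cy:
        return False
    if (p[0] - cx) ** 2 + (p[1] - cy) ** 2 > env.pool_radius ** 2:
        return False
    return env.floor_z <= p[2] <= env.surface_z


# --------------------------------------------------------------------------
# Trilateration (speaker survey)
# --------------------------------------------------------------------------

def trilaterate(reference_points, distances) -> np.ndarray:
    """Least-squares position from >= 4 non-coplanar points and ranges.

    Linearizes by differencing range equations against the first reference,
    then polishes with a Gauss-Newton pass on the nonlinear range residuals.
    Exact (to solver precision) on consistent inputs.
    """
    pts = np.asarray(reference_points, dtype=float)
    rng = np.asarray(distances, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("need >= 4 xyz reference points")
    if rng.shape != (pts.shape[0],) or np.any(rng < 0):
        raise ValueError("need one nonnegative distance per reference point")

    A = 2.0 * (pts[1:] - pts[0])
    if np.linalg.matrix_rank(A, tol=1e-9) < 3:
        raise np.linalg.LinAlgError(
            "reference points are coplanar/degenerate (rank-deficient)"
        )
    b = (rng[0] ** 2 - rng[1:] ** 2
         + np.sum(pts[1:] ** 2, axis=1) - np.sum(pts[0] ** 2))
    x, *_ = np.linalg.lstsq(A, b, rcond=None)

    # Gauss-Newton refinement on the true range residuals.
    for _ in range(20):
        d = np.linalg.norm(pts - x, axis=1)
        d = np.maximum(d, 1e-12)
        r = d - rng
        J = (x - pts) / d[:, None]
        step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        x = x + step
        if np.linalg.norm(step) < 1e-12:
            break
    return x


# --------------------------------------------------------------------------
# YAML config I/O
# --------------------------------------------------------------------------

def load_environment(path) -> tuple[EnvironmentConfig, HydrophoneGeometry,
                                    tuple[SourceLocation, ...]]:
    """Read (environment, geometry, source locations) from a YAML file.

    Any omitted section falls back to the built-in defaults, which embed the
    as-measured hydrophone and source tables.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    env = EnvironmentConfig(**raw.get("environment", {}))
    if "hydrophones" in raw:
        recs = tuple(
            HydrophoneRecord(int(r["channel_index"]), r["array_id"],
                             r["local_address"], tuple(r["position"]))
            for r in raw["hydrophones"]
        )
        geom = HydrophoneGeometry(recs)
    else:
        geom = DEFAULT_HYDROPHONES
    if "source_locations" in raw:
        locs = tuple(
            SourceLocation(r["id"], tuple(r["position"]))
            for r in raw["source_locations"]
        )
    else:
        locs = DEFAULT_SOURCE_LOCATIONS
    return env, geom, locs
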