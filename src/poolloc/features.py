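"""Per-snippet TDOA + cross-correlation feature extraction.

A 2-s, 16-channel snippet at 192 kHz becomes 897,856 ordered features:

* 120 GCC-PHAT TDOA estimates (s), one per unordered channel pair
  excluding self-pairs, in canonical (i < j) order;
* 136 x 6601 elements: for every unordered pair including self-pairs, the
  central 6601 lags (+-3300 samples ~ +-17.2 ms) of the standard
  normalized circular cross-correlation, lag-ascending, pairs in
  canonical (i <= j) order.  All 136 series are normalized jointly by the
  single largest absolute value among them, suppressing amplitude
  information.

Lag/sign convention: a correlation/TDOA value at positive lag means the
*second* channel of the pair leads (arrives earlier); equivalently the
TDOA estimate approximates (d_i - d_j)/c, negative when channel i is
closer.  This matches `geometry.expected_tdoas` and is pinned by the
delayed-copy tests.

The featurizer never reads source labels, so no label leakage is
possible by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.fft

from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import CANONICAL_PAIRS, CANONICAL_PAIRS_WITH_SELF
from .snippets import Snippet

__all__ = [
    "FeatureIndexMap",
    "SnippetFeaturizer",
    "gcc_phat",
    "normalized_circular_xcorrs",
    "central_slice",
    "featurize",
    "N_FEATURES",
    "SLICE_WIDTH",
]

SLICE_WIDTH = 6601
N_TDOA = len(CANONICAL_PAIRS)                 # 120
N_XCORR = len(CANONICAL_PAIRS_WITH_SELF)      # 136
N_FEATURES = N_TDOA + N_XCORR * SLICE_WIDTH   # 897,856


def _signed_lag(idx: int | np.ndarray, n: int):
    """FFT-order index -> signed lag in samples."""
    return np.where(idx <= n // 2, idx, idx - n)


def gcc_phat(
    x, y, fs: float, floor_ratio: float = 1e-12, circular: bool = True
) -> tuple[np.ndarray, float]:
    """GCC-PHAT correlation series and TDOA estimate for one pair.

    The cross-power spectrum is normalized to unit magnitude per bin (with
    magnitude floor `floor_ratio` times the maximum bin magnitude) and
    inverse-transformed.  The TDOA is argmax-lag / fs at integer-sample
    resolution, with the signed, centered lag convention documented in the
    module docstring.  Returns (series in FFT order, tdoa seconds).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if not np.any(x) or not np.any(y):
        raise ValueError("all-zero input: GCC-PHAT phase is undefined")
    n = x.size if circular else 2 * x.size
    X = scipy.fft.rfft(x, n)
    Y = scipy.fft.rfft(y, n)
    G = X * np.conj(Y)
    mag = np.abs(G)
    G /= np.maximum(mag, floor_ratio * mag.max())
    r = scipy.fft.irfft(G, n)
    k = int(np.argmax(r))
    tdoa = float(_signed_lag(k, n)) / fs
    return r, tdoa


def central_slice(series, width: int = SLICE_WIDTH) -> np.ndarray:
    """Central `width` lags of an FFT-order circular correlation series,
    reordered lag-ascending: -(width-1)/2 ... +(width-1)/2."""
    series = np.asarray(series)
    if width % 2 == 0:
        raise ValueError("width must be odd")
    if width > series.shape[-1]:
        raise ValueError("width exceeds series length")
    half = (width - 1) // 2
    if half == 0:
        return series[..., :1]
    return np.concatenate(
        [series[..., -half:], series[..., : half + 1]], axis=-1
    )


def normalized_circular_xcorrs(
    snippet: Snippet, per_series: bool = False
) -> np.ndarray:
    """All 136 normalized circular cross-correlation series, shape
    (136, n_samples), pairs in canonical (i <= j) order.

    Default normalization divides every element by the single largest
    absolute value across the snippet's 136 series; `per_series=True`
    normalizes each series by its own maximum instead.
    """
    data = np.asarray(snippet.data, dtype=np.float32)
    if not np.any(data):
        raise ValueError("silent snippet: cross-correlations are all zero")
    n = data.shape[1]
    F = scipy.fft.rfft(data, axis=1)
    out = np.empty((N_XCORR, n), dtype=np.float32)
    for p, (i, j) in enumerate(CANONICAL_PAIRS_WITH_SELF):
        out[p] = scipy.fft.irfft(F[i - 1] * np.conj(F[j - 1]), n)
    if per_series:
        out /= np.maximum(
            np.max(np.abs(out), axis=1, keepdims=True), np.float32(1e-30)
        )
    else:
        out /= np.max(np.abs(out))
    return out


@dataclass(frozen=True)
class FeatureIndexMap:
    """Invertible map: feature index -> (kind, channel pair, lag).

    TDOA features have lag None; cross-correlation features carry their
    signed lag in samples.
    """

    slice_width: int = SLICE_WIDTH

    def __len__(self) -> int:
        return N_TDOA + N_XCORR * self.slice_width

    def entry(self, k: int) -> tuple[str, tuple[int, int], int | None]:
        if not 0 <= k < len(self):
            raise IndexError(k)
        if k < N_TDOA:
            return ("tdoa", CANONICAL_PAIRS[k], None)
        k -= N_TDOA
        pair = CANONICAL_PAIRS_WITH_SELF[k // self.slice_width]
        half = (self.slice_width - 1) // 2
        lag = k % self.slice_width - half
        return ("xcorr", pair, lag)

    def index_of(
        self, kind: str, pair: tuple[int, int], lag: int | None = None
    ) -> int:
        if kind == "tdoa":
            return CANONICAL_PAIRS.index(pair)
        if kind == "xcorr":
            half = (self.slice_width - 1) // 2
            if lag is None or not -half <= lag <= half:
                raise ValueError(f"lag {lag} outside slice")
            p = CANONICAL_PAIRS_WITH_SELF.index(pair)
            return N_TDOA + p * self.slice_width + lag + half
        raise ValueError(f"unknown kind {kind!r}")

    def pairs(self, indices=None) -> np.ndarray:
        """(n, 2) channel pairs for the given feature indices (default:
        all features)."""
        if indices is None:
            indices = np.arange(len(self))
        return np.array([self.entry(int(k))[1] for k in np.asarray(indices)])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"slice_width": self.slice_width,
                       "n_tdoa": N_TDOA, "n_xcorr_pairs": N_XCORR,
                       "n_features": len(self)}, fh)


class SnippetFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: snippets -> TDOA + cross-correlation rows.

    Parameters
    ----------
    slice_width : int
        Odd number of central correlation lags kept per pair (6601 at
        192 kHz spans +-17.2 ms, comfortably covering every first-arrival
        TDOA in the pool).
    phat_floor : float
        Magnitude floor for PHAT whitening, relative to the largest
        cross-spectrum bin; prevents division blow-ups in filtered-out
        bands.
    normalization : {"snippet", "per_series"}
        Whether one divisor is shared across all 136 series (default) or
        each series is normalized on its own.
    correlation : {"circular", "linear"}
        Circular correlations by default; "linear" zero-pads to double
        length.
    """

    def __init__(self, slice_width: int = SLICE_WIDTH,
                 phat_floor: float = 1e-12,
                 normalization: str = "snippet",
                 correlation: str = "circular"):
        self.slice_width = slice_width
        self.phat_floor = phat_floor
        self.normalization = normalization
        self.correlation = correlation

    @property
    def n_features(self) -> int:
        return N_TDOA + N_XCORR * self.slice_width

    def index_map(self) -> FeatureIndexMap:
        return FeatureIndexMap(self.slice_width)

    def fit(self, X=None, y=None):
        if self.normalization not in ("snippet", "per_series"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.correlation not in ("circular", "linear"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.slice_width % 2 == 0:
            raise ValueError("slice_width must be odd")
        return self

    def transform_one(self, snippet: Snippet) -> np.ndarray:
        """One snippet -> feature vector of length `n_features`."""
        self.fit()
        data = np.asarray(snippet.data, dtype=np.float32)
        if not np.any(data):
            raise ValueError("silent snippet cannot be featurized")
        n = data.shape[1]
        if self.slice_width > n:
            raise ValueError("slice_width exceeds the correlation length")
        nfft = n if self.correlation == "circular" else 2 * n
        fs = snippet.fs
        F = scipy.fft.rfft(data, nfft, axis=1)
        half = (self.slice_width - 1) // 2

        out = np.empty(self.n_features, dtype=np.float32)
        slices = out[N_TDOA:].reshape(N_XCORR, self.slice_width)
        global_max = np.float32(0.0)
        tdoa_pos = 0
        for p, (i, j) in enumerate(CANONICAL_PAIRS_WITH_SELF):
            G = F[i - 1] * np.conj(F[j - 1])
            r = scipy.fft.irfft(G, nfft)
            global_max = max(global_max, np.max(np.abs(r)))
            slices[p] = central_slice(r[:n] if nfft == n else r,
                                      self.slice_width)
            if self.normalization == "per_series":
                m = np.max(np.abs(slices[p]))
                if m > 0:
                    slices[p] /= m
            if i != j:
                mag = np.abs(G)
                G /= np.maximum(mag, np.float32(self.phat_floor) * mag.max())
                rw = scipy.fft.irfft(G, nfft)
                k = int(np.argmax(rw))
                out[tdoa_pos] = _signed_lag(k, nfft) / fs
                tdoa_pos += 1
        if self.normalization == "snippet":
            if global_max > 0:
                slices /= global_max
        return out

    def transform(self, snippets) -> np.ndarray:
        """Iterable of snippets -> (n_snippets, n_features) float32."""
        snippets = list(snippets) if not hasattr(snippets, "__len__") \
            else snippets
        X = np.empty((len(snippets), self.n_features), dtype=np.float32)
        for r, s in enumerate(snippets):
            X[r] = self.transform_one(s)
        return X


def featurize(snippet: Snippet, **params) -> np.ndarray:
    """Functional wrapper: one snippet -> 897,856-element feature vector."""
    return SnippetFeaturizer(**params).transform_one(snippet)
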