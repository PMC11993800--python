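"""Signal preparation: decimation, fiducial detection and coarse graining.

Four coarse-graining methods turn one ECG lead into a binary string of the
same length:

* TC — threshold crossing at the signal median (``<= median`` maps to 0),
* KM — iterative two-centroid 1-D k-means assignment,
* FD — zeros everywhere except 1 at P/Q/R/S/T peak sample indices,
* BD — zeros everywhere except 1 at R-peak indices.

Resampling is plain decimation on a fixed index pattern (no filtering, no
interpolation); the supported rates are the 500 Hz native rate and its
3/4, 1/2 and 1/4 fractions.  Fiducial detection is a deterministic
energy-based QRS detector followed by windowed extrema search for the
remaining waves, and is run on the already-decimated signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

SUPPORTED_FS = (125, 250, 375, 500)
WAVES = ("p", "q", "r", "s", "t")

__all__ = [
    "FiducialSet",
    "decimate",
    "threshold_crossing",
    "kmeans_binarize",
    "detect_fiducials",
    "feature_detection_binarize",
    "beat_detection_binarize",
    "SUPPORTED_FS",
]


@dataclass(frozen=True)
class FiducialSet:
    """Per-beat P/Q/R/S/T peak sample indices for one lead.

    Each wave tuple has one entry per detected beat; ``None`` marks a wave
    that could not be located for that beat.  Indices refer to the sampling
    frequency ``fs``.
    """

    fs: int
    p: tuple = ()
    q: tuple = ()
    r: tuple = ()
    s: tuple = ()
    t: tuple = ()

    def __post_init__(self):
        lengths = {len(getattr(self, w)) for w in WAVES}
        if len(lengths) > 1:
            raise ValueError("wave index tuples must have one entry per beat")
        for beat in zip(self.p, self.q, self.r, self.s, self.t):
            present = [i for i in beat if i is not None]
            if any(b - a <= 0 for a, b in zip(present, present[1:])):
                raise ValueError(
                    "fiducial indices must be strictly increasing P<Q<R<S<T"
                )

    @property
    def n_beats(self) -> int:
        return len(self.r)

    def r_indices(self) -> np.ndarray:
        return np.asarray([i for i in self.r if i is not None], dtype=int)

    def all_indices(self) -> np.ndarray:
        idx = {
            i for w in WAVES for i in getattr(self, w) if i is not None
        }
        return np.asarray(sorted(idx), dtype=int)


# ---------------------------------------------------------------------------
# resampling


def decimate(signal: np.ndarray, target_fs: int, source_fs: int = 500) -> np.ndarray:
    """Downsample by discarding samples on a fixed index pattern.

    From 500 Hz: 125 keeps every 4th sample, 250 every 2nd, 375 keeps
    three of every four (indices congruent to 3 mod 4 are dropped) and
    500 is the identity.  Index 0 is always kept.
    """
    if source_fs != 500:
        raise ValueError("decimation is defined from a 500 Hz source")
    if target_fs not in SUPPORTED_FS:
        raise ValueError(f"target_fs must be one of {SUPPORTED_FS}")
    x = np.asarray(signal)
    if target_fs == 500:
        return x
    if target_fs == 125:
        return x[..., ::4]
    if target_fs == 250:
        return x[..., ::2]
    n = x.shape[-1]
    keep = np.arange(n)[np.arange(n) % 4 != 3]
    return x[..., keep]


# ---------------------------------------------------------------------------
# coarse graining


def _as_1d(signal) -> np.ndarray:
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty signal")
    return x


def threshold_crossing(signal) -> str:
    """Binarize at the signal median; points <= median map to 0."""
    x = _as_1d(signal)
    bits = x > np.median(x)
    return "".join("1" if b else "0" for b in bits)


def kmeans_binarize(
    signal,
    init_deflection: float | None = None,
    tolerance: float | None = None,
) -> str:
    """Two-centroid 1-D k-means assignment, lower centroid -> 0.

    Centroids start at ``mean ± init_deflection`` (default 0.05 x standard
    deviation).  Iteration stops when the mean point-to-nearest-centroid
    distance changes by less than ``tolerance`` (default 1e-6 x signal
    range) or after ``len(signal)`` iterations.  Equidistant points are
    assigned to the lower centroid, mirroring the threshold-crossing rule
    that boundary points map to 0.  A centroid that loses all its points
    is re-seeded at the extreme value of the signal on its side.
    """
    x = _as_1d(signal)
    n = x.size
    if n < 2:
        raise ValueError("k-means binarization requires at least 2 samples")
    rng_span = float(np.ptp(x))
    if rng_span == 0.0:
        return "0" * n  # all points tie; ties break to the lower centroid
    sd = float(np.std(x))
    d0 = init_deflection if init_deflection is not None else 0.05 * sd
    tol = tolerance if tolerance is not None else 1e-6 * rng_span
    if d0 <= 0 or tol <= 0:
        raise ValueError("init_deflection and tolerance must be positive")
    mu = float(np.mean(x))
    c1, c2 = mu - d0, mu + d0
    prev = math.inf
    upper = np.zeros(n, dtype=bool)
    for _ in range(n):
        # ties (equidistant) go to the lower centroid
        upper = np.abs(x - c2) < np.abs(x - c1)
        lo, hi = x[~upper], x[upper]
        c1 = float(lo.mean()) if lo.size else float(x.min())
        c2 = float(hi.mean()) if hi.size else float(x.max())
        mean_dist = float(np.minimum(np.abs(x - c1), np.abs(x - c2)).mean())
        if abs(prev - mean_dist) < tol:
            break
        prev = mean_dist
    upper = np.abs(x - c2) < np.abs(x - c1)
    return "".join("1" if b else "0" for b in upper)


# ---------------------------------------------------------------------------
# fiducial detection

# search windows relative to the R peak, in seconds
_P_WIN = (-0.28, -0.08)
_Q_WIN = (-0.10, 0.0)
_S_WIN = (0.0, 0.10)
_T_WIN = (0.10, 0.40)


def detect_fiducials(signal, fs: int) -> FiducialSet:
    """Locate P/Q/R/S/T peaks with an energy-based QRS detector.

    The squared first difference is smoothed with a 150 ms moving window;
    peaks of this energy envelope (at least 300 ms apart, above a quarter
    of the maximum) mark QRS complexes.  The R peak is refined as the
    polarity-corrected extremum within ±100 ms, and the remaining waves
    are extrema inside fixed physiological windows around R.  Deterministic
    for fixed input; an empty :class:`FiducialSet` is returned when no
    beats are found.
    """
    x = _as_1d(signal)
    n = x.size
    if n < 2 * fs:
        raise ValueError("fiducial detection requires at least 2 s of signal")
    if float(np.ptp(x)) < 1e-9:
        logger.warning("flat signal: no beats detected")
        return FiducialSet(fs=fs)
    y = x - np.median(x)
    # polarity correction so the dominant QRS deflection is positive
    if -y.min() > y.max():
        y = -y
    energy = np.convolve(
        np.diff(y) ** 2, np.ones(max(1, int(0.15 * fs))), mode="same"
    )
    peaks, _ = find_peaks(
        energy,
        height=0.25 * energy.max(),
        distance=max(1, int(0.30 * fs)),
    )
    if peaks.size == 0:
        logger.warning("no QRS energy peaks detected")
        return FiducialSet(fs=fs)
    half = max(1, int(0.10 * fs))
    r_idx = []
    for p in peaks:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        r_idx.append(lo + int(np.argmax(y[lo:hi])))
    r_idx = sorted(set(r_idx))
    # enforce refractory spacing after refinement
    spaced = [r_idx[0]]
    for r in r_idx[1:]:
        if r - spaced[-1] >= int(0.30 * fs):
            spaced.append(r)
    waves: dict[str, list] = {w: [] for w in WAVES}

    def _extremum(lo_s, hi_s, r, mode):
        lo = max(0, r + int(round(lo_s * fs)))
        hi = min(n, r + int(round(hi_s * fs)) + 1)
        if hi - lo < 1:
            return None
        seg = y[lo:hi]
        return lo + int(np.argmax(seg) if mode == "max" else np.argmin(seg))

    for r in spaced:
        p = _extremum(*_P_WIN, r, "max")
        q = _extremum(_Q_WIN[0], -1.0 / fs, r, "min")
        s = _extremum(1.0 / fs, _S_WIN[1], r, "min")
        t = _extremum(*_T_WIN, r, "max")
        # drop waves violating the P<Q<R<S<T ordering (window truncation)
        if p is not None and q is not None and p >= q:
            p = None
        if q is not None and q >= r:
            q = None
        if s is not None and s <= r:
            s = None
        if t is not None and s is not None and t <= s:
            t = None
        waves["p"].append(p)
        waves["q"].append(q)
        waves["r"].append(r)
        waves["s"].append(s)
        waves["t"].append(t)
    return FiducialSet(fs=fs, **{w: tuple(v) for w, v in waves.items()})


# ---------------------------------------------------------------------------
# fiducial-driven binarizers


def _ones_at(indices: np.ndarray, n: int) -> str:
    if indices.size and (indices.min() < 0 or indices.max() >= n):
        raise ValueError("fiducial index out of range for string length")
    bits = np.zeros(n, dtype=np.uint8)
    bits[indices] = 1
    return "".join("1" if b else "0" for b in bits)


def feature_detection_binarize(fiducials: FiducialSet, n: int) -> str:
    """String of n zeros with 1 at every P, Q, R, S and T peak index."""
    return _ones_at(fiducials.all_indices(), n)


def beat_detection_binarize(fiducials: FiducialSet, n: int) -> str:
    """String of n zeros with 1 only at R-peak indices (heartbeats)."""
    return _ones_at(fiducials.r_indices(), n)
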