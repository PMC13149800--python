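"""M-mode ultrasound boundary-trace analysis.

Mirrors the clinical processing chain: the manually delineated upper and
lower wall boundaries are interpolated to the uniform frame grid and
subtracted to a diameter trace; a least-squares linear trend (probe or
tissue drift) is removed while preserving the mean, so absolute
diameters survive; the five systolic peaks and diastolic troughs are
found with the automatic multiscale peak-detection (AMPD) algorithm and
averaged; and because the delineation follows the outer wall, the
intima-media thickness is subtracted twice from both diameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthdata import MModeTrace

__all__ = [
    "DiameterTrace",
    "BeatExtrema",
    "diameter_from_boundaries",
    "ampd_peaks",
    "beats_to_diameters",
    "analyze_mmode",
]


@dataclass
class DiameterTrace:
    """Detrended lumen-plus-wall diameter versus time."""

    time_s: np.ndarray
    diameter_mm: np.ndarray
    trend_slope_mm_per_s: float


@dataclass
class BeatExtrema:
    """Systolic/diastolic diameters averaged over five beats."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    d_s: float  # mm, IMT-corrected
    d_d: float  # mm, IMT-corrected

    def __post_init__(self) -> None:
        if not self.d_s > self.d_d:
            raise ValueError("systolic diameter must exceed diastolic diameter")


def _trend_slope(t: np.ndarray, x: np.ndarray, method: str) -> float:
    """Linear trend slope of a diameter trace, in mm/s.

    ``"feet"`` fits the line through the diastolic feet (the minimum
    between consecutive systolic peaks), the convention used for
    distension waveforms: a periodic pulse has a non-zero least-squares
    slope over a finite window (the systolic bump sits early in the
    cycle), so plain OLS detrending tilts the waveform and biases the
    extrema, while the end-diastolic trend line removes only genuine
    drift.  ``"ols"`` is the plain least-squares slope over all samples.
    """
    tc = t - t.mean()
    ols = float(np.dot(tc, x - x.mean()) / np.dot(tc, tc))
    if method == "ols":
        return ols
    if method != "feet":
        raise ValueError("detrend method must be 'feet' or 'ols'")
    peaks = _ampd_maxima(x)
    if len(peaks) < 2:
        return ols  # no beat structure found: fall back to OLS
    feet = _pair_troughs(x, peaks, len(peaks))
    if len(feet) < 2:
        return ols
    tf = t[feet]
    xf = x[feet]
    tfc = tf - tf.mean()
    return float(np.dot(tfc, xf - xf.mean()) / np.dot(tfc, tfc))


def diameter_from_boundaries(
    trace: MModeTrace, fps: float | None = None, detrend: str = "feet"
) -> DiameterTrace:
    """Interpolate boundaries to a uniform grid, subtract, detrend.

    Detrending removes only a fitted slope and re-adds nothing (the mean
    is preserved), so absolute diameters survive for the stiffness
    computation.  See :func:`_trend_slope` for the two slope estimators.
    """
    fps = fps or trace.fps
    if np.any(trace.lower_mm <= trace.upper_mm):
        raise ValueError("lower boundary must exceed upper boundary everywhere")
    t0, t1 = trace.time_s[0], trace.time_s[-1]
    t_uniform = t0 + np.arange(int(np.floor((t1 - t0) * fps)) + 1) / fps
    upper = np.interp(t_uniform, trace.time_s, trace.upper_mm)
    lower = np.interp(t_uniform, trace.time_s, trace.lower_mm)
    diam = lower - upper
    slope = _trend_slope(t_uniform, diam, detrend)
    return DiameterTrace(
        time_s=t_uniform,
        diameter_mm=diam - slope * (t_uniform - t_uniform.mean()),
        trend_slope_mm_per_s=slope,
    )


def _ampd_maxima(x: np.ndarray, lsm_limit: float = 0.25) -> np.ndarray:
    """Automatic multiscale-based peak detection on a detrended signal.

    Builds the local-maxima scalogram over window scales k = 1 ..
    ceil(lsm_limit * n/2)-1, picks the global scale lambda minimizing the
    row-wise sum, and returns samples that are strict local maxima at
    every scale up to lambda.  Two robustness measures over the bare
    scalogram: the signal is extended by anti-symmetric (odd) reflection
    at both ends, so peaks near the trace boundaries are compared
    against a natural continuation instead of being silently discarded;
    and the scanned scales are capped at a fraction ``lsm_limit`` of the
    half-length, below the beat period for any trace of three or more
    beats, because at scales beyond the period the peaks of a
    quasi-periodic signal tie with their own repetitions and the
    every-scale maximum criterion would discard them.
    """
    n = len(x)
    max_scale = int(np.ceil(lsm_limit * n / 2)) - 1
    if max_scale < 1:
        return np.array([], dtype=int)
    pad = max_scale
    xp = np.pad(x, pad, mode="reflect", reflect_type="odd")
    # not_max[k-1, i] = 1 unless x[i] > x[i-k] and x[i] > x[i+k]
    not_max = np.ones((max_scale, n), dtype=np.uint8)
    mid = xp[pad : pad + n]
    for k in range(1, max_scale + 1):
        ok = (mid > xp[pad - k : pad + n - k]) & (mid > xp[pad + k : pad + n + k])
        not_max[k - 1, ok] = 0
    row_sums = not_max.sum(axis=1)
    lam = int(np.argmin(row_sums)) + 1
    col = not_max[:lam].sum(axis=0)
    return np.nonzero(col == 0)[0]


def _refine_extrema(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Quadratic-vertex refinement of extremum sample indices.

    A least-squares parabola over a window of a quarter of the median
    inter-extremum spacing relocates each index to the vertex, which
    suppresses the noise-driven scatter of a raw argmax.  Degenerate
    fits (flat plateaus, vertex escaping the window) keep the original
    index.
    """
    if len(idx) < 2:
        return idx
    half = max(2, int(np.median(np.diff(idx)) // 4))
    out = idx.copy()
    n = len(x)
    for j, i in enumerate(idx):
        h = min(half, i, n - 1 - i)  # symmetric window, shrunk at the edges
        if h < 2:
            continue
        lo, hi = i - h, i + h + 1
        t = np.arange(lo, hi) - i
        a, b, _ = np.polyfit(t, x[lo:hi], 2)
        if a == 0:
            continue
        vertex = -b / (2 * a)
        if abs(vertex) <= h:
            out[j] = int(np.clip(round(i + vertex), 0, n - 1))
    return out


def ampd_peaks(trace: DiameterTrace) -> tuple[np.ndarray, np.ndarray]:
    """AMPD peaks and troughs (troughs = AMPD peaks of the negated trace),
    each refined to the local quadratic vertex."""
    x = np.asarray(trace.diameter_mm, dtype=float)
    peaks = _refine_extrema(x, _ampd_maxima(x))
    troughs = _refine_extrema(-x, _ampd_maxima(-x))
    if len(peaks) == 0 and len(troughs) == 0:
        warnings.warn("no oscillation detected (monotone or flat trace)", RuntimeWarning,
                      stacklevel=2)
    return peaks, troughs


def _pair_troughs(x: np.ndarray, peaks: np.ndarray, n_needed: int) -> np.ndarray:
    """Deterministic fallback pairing: trough = argmin between consecutive peaks.

    Needed when the diastolic plateau is exactly flat (no strict local
    minimum exists); segments before the first and after the last peak
    are used if the inter-peak gaps alone do not yield enough troughs.
    """
    troughs = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        troughs.append(a + int(np.argmin(x[a : b + 1])))
    if len(troughs) < n_needed and peaks[-1] < len(x) - 1:
        troughs.append(peaks[-1] + int(np.argmin(x[peaks[-1] :])))
    if len(troughs) < n_needed and peaks[0] > 0:
        troughs.insert(0, int(np.argmin(x[: peaks[0] + 1])))
    return np.asarray(sorted(troughs), dtype=int)


def beats_to_diameters(
    trace: DiameterTrace,
    peaks: np.ndarray,
    troughs: np.ndarray,
    imt_mm: float = 0.0,
    n_beats: int = 5,
) -> BeatExtrema:
    """Average the first five systolic peaks and diastolic troughs.

    The intima-media thickness is subtracted twice from both (outer-wall
    delineation -> lumen diameter).
    """
    x = trace.diameter_mm
    if len(peaks) < n_beats:
        raise ValueError(f"need >= {n_beats} systolic peaks, found {len(peaks)}")
    if len(troughs) < n_beats:
        troughs = _pair_troughs(x, peaks, n_beats)
    if len(troughs) < n_beats:
        raise ValueError(f"need >= {n_beats} diastolic troughs, found {len(troughs)}")
    pk = np.asarray(peaks[:n_beats], dtype=int)
    tr = np.asarray(troughs[:n_beats], dtype=int)
    d_s = float(np.mean(x[pk]) - 2.0 * imt_mm)
    d_d = float(np.mean(x[tr]) - 2.0 * imt_mm)
    if d_d <= 0:
        raise ValueError("diastolic diameter non-positive after IMT correction")
    return BeatExtrema(peak_indices=pk, trough_indices=tr, d_s=d_s, d_d=d_d)


def analyze_mmode(trace: MModeTrace, imt_mm: float | None = None) -> BeatExtrema:
    """Full M-mode chain: interpolate, subtract, detrend, detect, average."""
    imt = trace.imt_mm if imt_mm is None else imt_mm
    dt = diameter_from_boundaries(trace)
    peaks, troughs = ampd_peaks(dt)
    return beats_to_diameters(dt, peaks, troughs, imt_mm=imt)
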