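"""Derived measurements: peaks, ripples, slopes, spectra, plateaus, envelopes.

The coupled reed chain produces a characteristic fine structure — a
secondary response peak beyond the main one, a train of closely spaced
ripples on the low-natural-frequency side, strongly asymmetric attenuation
away from a driven reed, spatial phase bands coinciding with amplitude
minima, multi-peaked impulse spectra that beat ("wax and wane") in the
time domain, and clustering of dominant impulse-response frequencies into
plateaus.  This module quantifies all of them.

Ripple and peak statistics operate on log-magnitude (dB) series because
the ripples are small on a linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .phasor import ComplexResponse
from .timedomain import SteadyStateProfile, Trajectory

__all__ = [
    "Spectrum",
    "PeakSet",
    "PlateauMap",
    "impulse_spectrum",
    "find_peaks",
    "peak_ratios",
    "attenuation_slopes",
    "phase_band_period",
    "dominant_frequency_map",
    "plateau_ratios",
    "envelope",
]

_DB_FLOOR = 1e-300


def _db(a: np.ndarray) -> np.ndarray:
    return 20.0 * np.log10(np.maximum(np.asarray(a, dtype=float), _DB_FLOOR))


@dataclass(frozen=True)
class Spectrum:
    """Magnitude spectra of every reed on a common frequency grid."""

    freq_hz: np.ndarray
    magnitude: np.ndarray  # (n_reeds, n_freqs)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freq_hz) <= 0):
            raise ValueError("frequency grid must be ascending")
        if self.magnitude.shape[-1] != self.freq_hz.size:
            raise ValueError("magnitude/grid size mismatch")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def grid_step_hz(self) -> float:
        return float(self.freq_hz[1] - self.freq_hz[0])


@dataclass(frozen=True)
class PeakSet:
    """Detected local maxima: (location, height, prominence_db), ascending."""

    location: np.ndarray
    height: np.ndarray
    prominence_db: np.ndarray

    def __post_init__(self) -> None:
        if not (self.location.size == self.height.size == self.prominence_db.size):
            raise ValueError("peak arrays must have equal length")
        if self.location.size > 1 and np.any(np.diff(self.location) <= 0):
            raise ValueError("peak locations must be strictly increasing")

    def __len__(self) -> int:
        return self.location.size

    def tallest(self, k: int) -> "PeakSet":
        """The k highest peaks, returned in ascending location order."""
        order = np.argsort(self.height)[::-1][:k]
        keep = np.sort(order)
        return PeakSet(
            self.location[keep], self.height[keep], self.prominence_db[keep]
        )


@dataclass(frozen=True)
class PlateauMap:
    """Dominant impulse-response frequency of each oscillator."""

    dominant_freq_hz: np.ndarray  # NaN where the spectrum was flat
    grid_step_hz: float


def impulse_spectrum(traj: Trajectory, pad_factor: int = 8) -> Spectrum:
    """Magnitude spectrum of every reed's impulse response.

    The full record is transformed without a taper window (the response is
    transient-complete), zero-padded by ``pad_factor`` to refine the grid.
    """
    if traj.drive is not None:
        raise ValueError("impulse spectrum expects an unforced trajectory")
    t = traj.time_s
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError("impulse spectrum requires a uniform time grid")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    n = t.size
    n_fft = pad_factor * n
    mag = np.abs(np.fft.rfft(traj.displacement, n=n_fft, axis=1))
    freq = np.fft.rfftfreq(n_fft, d=float(dt[0]))
    return Spectrum(
        freq_hz=freq,
        magnitude=mag,
        meta={
            "pad_factor": pad_factor,
            "record_s": float(t[-1] - t[0]),
            "sample_rate_hz": 1.0 / float(dt[0]),
        },
    )


def _interp_vertex(axis: np.ndarray, y_db: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (axis, y_db) at i-1, i, i+1."""
    if i == 0 or i == axis.size - 1:
        return float(axis[i]), float(y_db[i])
    x0, x1, x2 = axis[i - 1 : i + 2]
    y0, y1, y2 = y_db[i - 1 : i + 2]
    # local quadratic fit; handles mildly non-uniform axes
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:
        return float(axis[i]), float(y_db[i])
    xv = -b / (2 * a)
    lo, hi = min(x0, x2), max(x0, x2)
    xv = float(np.clip(xv, lo, hi))
    c = y1 - a * x1**2 - b * x1
    return xv, float(a * xv**2 + b * xv + c)


def find_peaks(
    series: np.ndarray,
    axis: np.ndarray,
    min_prominence_db: float = 1.0,
    interpolate: bool = True,
    floor_db: float | None = None,
) -> PeakSet:
    """Local maxima of ``series`` (linear amplitude) in log magnitude.

    Prominence is measured in dB.  Peak locations are refined by a local
    quadratic fit through the three samples around each maximum.  With
    ``floor_db`` set, peaks more than that many dB below the tallest peak
    are discarded.  An all-zero series yields an empty set.
    """
    series = np.asarray(series, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if series.size != axis.size:
        raise ValueError("series and axis must have equal length")
    if series.size < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("series must be finite")
    if np.all(series == 0):
        return PeakSet(np.empty(0), np.empty(0), np.empty(0))
    y = _db(series)
    idx, props = scipy.signal.find_peaks(y, prominence=min_prominence_db)
    locs, heights = [], []
    for i in idx:
        xv, yv = (_interp_vertex(axis, y, int(i)) if interpolate
                  else (float(axis[i]), float(y[i])))
        locs.append(xv)
        heights.append(10.0 ** (yv / 20.0))
    locs = np.asarray(locs)
    heights = np.asarray(heights)
    proms = props["prominences"]
    if floor_db is not None and heights.size:
        keep = heights >= heights.max() * 10.0 ** (-floor_db / 20.0)
        locs, heights, proms = locs[keep], heights[keep], proms[keep]
    order = np.argsort(locs)
    return PeakSet(locs[order], heights[order], proms[order])


def peak_ratios(peaks: PeakSet) -> np.ndarray:
    """Successive location ratios (each > 1) of an ascending peak set."""
    if len(peaks) < 2:
        return np.empty(0)
    loc = peaks.location
    return loc[1:] / loc[:-1]


def attenuation_slopes(
    response: ComplexResponse,
    driven_reed: int,
    fit_range_db: tuple[float, float] = (5.0, 30.0),
) -> tuple[float, float]:
    """Attenuation rates (dB/octave) on either side of a singly driven reed.

    Fits 20 log10(amplitude) against log2(natural frequency) over the
    region between ``fit_range_db`` dB below the peak on each side and
    returns the slope magnitudes, low-natural-frequency side first.

    The default window skips the top 5 dB, where the profile is still
    dominated by the locally parabolic peak, and spans the following
    25 dB of roll-off.  The high-frequency side steepens steadily with
    depth, so deeper windows give systematically larger slopes.
    """
    amp = response.amplitude
    freqs = response.bank.natural_freq_hz
    n = amp.size
    if not 0 <= driven_reed < n:
        raise IndexError("driven reed index out of range")
    if driven_reed in (0, n - 1):
        raise ValueError("driven reed must be interior to the array")
    level = _db(amp)
    peak_level = level[driven_reed]
    lo_db, hi_db = fit_range_db
    low_is_first = freqs[0] < freqs[-1]

    def side_slope(indices: np.ndarray) -> float:
        drop = peak_level - level[indices]
        # contiguous span from the first sample beyond lo_db to the first
        # beyond hi_db, walking away from the peak
        start = np.argmax(drop >= lo_db)
        if drop[start] < lo_db:
            raise ValueError(
                f"response never falls {lo_db} dB below the peak on this side"
            )
        past = np.nonzero(drop[start:] >= hi_db)[0]
        stop = start + (past[0] + 1 if past.size else drop.size - start)
        sel = indices[start:stop]
        if sel.size < 3:
            raise ValueError("fewer than 3 reeds in the fit window")
        x = np.log2(freqs[sel])
        slope = np.polyfit(x, level[sel], 1)[0]
        return float(abs(slope))

    toward_start = np.arange(driven_reed - 1, -1, -1)
    toward_end = np.arange(driven_reed + 1, n)
    if low_is_first:
        return side_slope(toward_start), side_slope(toward_end)
    return side_slope(toward_end), side_slope(toward_start)


def _amplitude_minima(
    amp: np.ndarray, min_prominence_db: float = 0.5
) -> np.ndarray:
    """Indices of local minima of the log-amplitude profile."""
    idx, _ = scipy.signal.find_peaks(-_db(amp), prominence=min_prominence_db)
    return idx


def phase_band_period(
    profile: SteadyStateProfile | ComplexResponse,
    min_prominence_db: float = 0.5,
    return_minima: bool = False,
):
    """Spatial periodicity (in natural-frequency Hz) of the phase bands.

    The rapid phase transitions along the array coincide with amplitude
    minima, so the bands are delimited by the minima of the log-amplitude
    profile on the low-natural-frequency side of the main response peak.
    The band spacing is not uniform — it is widest next to the peak and
    shrinks toward the apex — so the period is reported as the spacing
    between the two minima nearest the peak, which delimit the dominant
    band of the pattern.  The full minima list is available via
    ``return_minima``.
    """
    if isinstance(profile, ComplexResponse):
        amp = profile.amplitude
        freqs = profile.bank.natural_freq_hz
    else:
        amp = profile.amplitude
        freqs = profile.natural_freq_hz
    peak = int(np.argmax(amp))
    minima = _amplitude_minima(amp, min_prominence_db)
    low_side = minima[freqs[minima] < freqs[peak]]
    if low_side.size < 2:
        raise ValueError(
            "need at least 2 amplitude minima on the low-frequency side "
            f"(found {low_side.size}); is the bank coupled?"
        )
    f_min = np.sort(freqs[low_side])
    period = float(f_min[-1] - f_min[-2])  # the two minima nearest the peak
    if return_minima:
        return period, f_min
    return period


def dominant_frequency_map(spectra: Spectrum) -> PlateauMap:
    """Frequency of the globally highest spectral peak of each oscillator.

    Peak locations are refined by quadratic interpolation.  Oscillators
    with a flat spectrum get NaN.
    """
    n = spectra.magnitude.shape[0]
    out = np.full(n, np.nan)
    y_all = _db(spectra.magnitude)
    for j in range(n):
        mag = spectra.magnitude[j]
        if np.all(mag == mag[0]):
            continue
        i = int(np.argmax(mag))
        out[j], _ = _interp_vertex(spectra.freq_hz, y_all[j], i)
    return PlateauMap(dominant_freq_hz=out, grid_step_hz=spectra.grid_step_hz)


def plateau_values(
    pmap: PlateauMap, min_run: int = 3, tol_hz: float | None = None
) -> np.ndarray:
    """Collapse runs of >= min_run equal dominant frequencies into plateaus.

    Two adjacent oscillators belong to the same run when their dominant
    frequencies differ by at most ``tol_hz`` (default: half the spectral
    grid step).  Returns the mean frequency of each plateau, in array order.
    """
    if tol_hz is None:
        tol_hz = 0.5 * pmap.grid_step_hz
    f = pmap.dominant_freq_hz
    values = []
    start = 0
    for j in range(1, f.size + 1):
        end_of_run = (
            j == f.size
            or not np.isfinite(f[j])
            or not np.isfinite(f[j - 1])
            or abs(f[j] - f[j - 1]) > tol_hz
        )
        if end_of_run:
            if j - start >= min_run and np.all(np.isfinite(f[start:j])):
                values.append(float(np.mean(f[start:j])))
            start = j
    return np.asarray(values)


def plateau_ratios(
    pmap: PlateauMap, min_run: int = 3, tol_hz: float | None = None
) -> np.ndarray:
    """Successive ratios between adjacent plateau frequencies (each > 1)."""
    vals = plateau_values(pmap, min_run=min_run, tol_hz=tol_hz)
    if vals.size < 2:
        return np.empty(0)
    vals = np.sort(vals)
    return vals[1:] / vals[:-1]


def envelope(series: np.ndarray) -> np.ndarray:
    """Amplitude envelope of an oscillatory record via the analytic signal."""
    series = np.asarray(series, dtype=float)
    if series.size < 16:
        raise ValueError("series too short for envelope extraction")
    return np.abs(scipy.signal.hilbert(series))
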