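"""Calcium-transient metrics and LFP band power.

Calcium traces are normalised to a rolling-percentile baseline (dF/F) and
events are detected as suprathreshold excursions against a robust
(MAD-based) noise estimate. LFP spectra use a segment-averaged, cosine-
tapered periodogram restricted to the 0.5-100 Hz analysis range; the gamma
band (30-100 Hz) power is the trapezoidal integral of the density over the
band, optionally normalised by a baseline recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

__all__ = ["LfpPsd", "dff", "detect_transients", "event_frequency", "psd", "band_power"]

GAMMA_BAND_HZ = (30.0, 100.0)
ANALYSIS_RANGE_HZ = (0.5, 100.0)


@dataclass
class LfpPsd:
    """A power spectral density restricted to the analysis range."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray  # power density, units^2/Hz
    fs: float


def dff(
    trace: np.ndarray,
    fs: float,
    baseline_window_s: float = 30.0,
    baseline_percentile: float = 20.0,
) -> np.ndarray:
    """dF/F against a rolling-percentile baseline.

    F0 is the ``baseline_percentile``-th percentile over a sliding window of
    ``baseline_window_s`` seconds; dF/F = (F - F0) / F0. Raises if the
    baseline is not strictly positive anywhere.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    window = int(round(baseline_window_s * fs))
    if window > trace.size:
        raise ValueError(
            f"baseline window ({baseline_window_s} s = {window} samples) exceeds "
            f"trace length ({trace.size} samples)"
        )
    window = max(window, 1)
    f0 = ndimage.percentile_filter(trace, percentile=baseline_percentile, size=window, mode="nearest")
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; dF/F undefined")
    return (trace - f0) / f0


def detect_transients(
    dff_trace: np.ndarray,
    fs: float,
    k_sd: float = 3.0,
    min_dur_s: float = 0.4,
) -> pd.DataFrame:
    """Threshold-crossing calcium events on a dF/F trace.

    The threshold is ``k_sd`` times a robust SD (1.4826 * median absolute
    deviation); events are contiguous suprathreshold excursions lasting at
    least ``min_dur_s``. Returns one row per event: onset time, peak time,
    peak amplitude, duration.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    if min_dur_s < 0:
        raise ValueError("min_dur_s must be >= 0")
    x = np.asarray(dff_trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    mad = np.median(np.abs(x - np.median(x)))
    robust_sd = 1.4826 * mad
    cols = ["onset_s", "peak_s", "amplitude", "duration_s"]
    if robust_sd == 0 and np.all(x == x[0]):
        return pd.DataFrame(columns=cols)
    # floor at 5 % of the trace maximum: keeps the threshold meaningful on
    # (near-)noiseless traces where the MAD collapses to ~0
    threshold = max(k_sd * robust_sd, 0.05 * float(x.max()))
    if threshold <= 0:
        return pd.DataFrame(columns=cols)
    above = x > threshold
    lab, n = ndimage.label(above)
    rows = []
    min_len = max(1, int(np.ceil(min_dur_s * fs)))
    for sl in ndimage.find_objects(lab):
        seg = sl[0]
        if seg.stop - seg.start < min_len:
            continue
        # a suprathreshold excursion may stack several transients: interior
        # peaks with full prominence mark re-excitations within the decay
        segment = x[seg]
        interior, _ = sps.find_peaks(segment, prominence=threshold)
        onsets = [0] + [int(i) for i in interior]
        bounds = onsets[1:] + [len(segment)]
        for o, b in zip(onsets, bounds):
            peak_rel = o + int(np.argmax(segment[o:b]))
            rows.append(
                dict(
                    onset_s=(seg.start + o) / fs,
                    peak_s=(seg.start + peak_rel) / fs,
                    amplitude=float(segment[peak_rel]),
                    duration_s=(b - o) / fs,
                )
            )
    return pd.DataFrame(rows, columns=cols)


def event_frequency(events: pd.DataFrame, duration_s: float) -> float:
    """Events per minute."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return 60.0 * len(events) / duration_s


def psd(
    trace: np.ndarray,
    fs: float,
    segment_s: float = 2.0,
    overlap: float = 0.5,
    freq_range: tuple[float, float] = ANALYSIS_RANGE_HZ,
) -> LfpPsd:
    """Welch power spectral density restricted to the analysis range.

    Defaults: 2 s Hann-tapered segments with 50 % overlap. Requires at
    least 4 s of data and a sampling rate above 200 Hz (otherwise the gamma
    band is unresolvable).
    """
    trace = np.asarray(trace, dtype=float)
    if fs <= 200:
        raise ValueError(f"sampling rate {fs} Hz too low: need fs > 200 Hz")
    if trace.size / fs < 4.0:
        raise ValueError("need >= 4 s of signal")
    nperseg = int(round(segment_s * fs))
    freqs, density = sps.welch(
        trace, fs=fs, window="hann", nperseg=nperseg, noverlap=int(nperseg * overlap)
    )
    lo, hi = freq_range
    keep = (freqs >= lo) & (freqs <= hi)
    return LfpPsd(freqs=freqs[keep], psd=density[keep], fs=fs)


def band_power(
    spectrum: LfpPsd,
    band: tuple[float, float] = GAMMA_BAND_HZ,
    baseline: LfpPsd | None = None,
) -> float:
    """Trapezoidal integral of the density over ``band``; if a baseline
    spectrum is given, the ratio to the baseline's band power is returned."""
    lo, hi = band
    if lo < spectrum.freqs[0] or hi > spectrum.freqs[-1]:
        raise ValueError(
            f"band {band} outside PSD range "
            f"({spectrum.freqs[0]:.2f}-{spectrum.freqs[-1]:.2f} Hz)"
        )
    keep = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    power = float(np.trapezoid(spectrum.psd[keep], spectrum.freqs[keep]))
    if baseline is None:
        return power
    base = band_power(baseline, band)
    if base <= 0:
        raise ValueError("baseline band power is zero; normalisation undefined")
    return power / base
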