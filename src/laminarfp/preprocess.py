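"""Preprocessing: zero-phase filtering, rational down-sampling, faulty-channel
interpolation and automated removal of large transients (sharp-wave-like
events) before correlation statistics.

Filters are 4th-order Butterworth applied forward-backward (zero group
delay).  Down-sampling uses polyphase rational resampling with the built-in
anti-alias stage.  Large events are detected against a robust baseline
(median) and robust SD (MAD x 1.4826).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = [
    "filter_signal",
    "downsample",
    "interpolate_channel",
    "exclude_large_events",
    "ExclusionResult",
]

_FILTER_ORDER = 4


def _design_sos(kind: str, band, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if kind == "highpass":
        edges = np.atleast_1d(band).astype(float)
        if edges.size != 1:
            raise ValueError("highpass takes a single cutoff frequency")
        if edges[0] >= nyq:
            raise ValueError(f"cutoff {edges[0]} Hz >= Nyquist {nyq} Hz")
        return sps.butter(_FILTER_ORDER, edges[0], btype="highpass", fs=fs, output="sos")
    if kind == "bandpass":
        lo, hi = float(band[0]), float(band[1])
        if not 0 < lo < hi:
            raise ValueError(f"invalid band ({lo}, {hi})")
        if hi >= nyq:
            raise ValueError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
        return sps.butter(_FILTER_ORDER, (lo, hi), btype="bandpass", fs=fs, output="sos")
    raise ValueError(f"unknown filter kind {kind!r}")


def filter_signal(x, kind: str, band, fs: float | None = None):
    """Zero-phase Butterworth filter of a series or a :class:`Recording`.

    Parameters
    ----------
    x : ndarray or Recording
        1-D series, channels x time matrix, or a Recording.
    kind : {"highpass", "bandpass"}
    band : float or (low, high) in Hz
    fs : float
        Sampling rate; taken from the Recording when one is passed.
    """
    if isinstance(x, Recording):
        out = filter_signal(x.samples, kind, band, fs=x.fs)
        return x.copy_with(samples=out)
    if fs is None:
        raise ValueError("fs is required for array input")
    sos = _design_sos(kind, band, fs)
    x = np.asarray(x, dtype=np.float64)
    return sps.sosfiltfilt(sos, x, axis=-1)


def edge_trim_samples(kind: str, band, fs: float, n_constants: int = 3) -> int:
    """Samples to drop at each edge before statistics: 3 time constants of the
    filter's slowest pole (for a 4th-order Butterworth the slowest pole sits
    at cos(67.5 deg) ~ 0.38 of the cutoff radius)."""
    lo = float(np.atleast_1d(band)[0])
    slowest = 2 * np.pi * lo * np.cos(np.deg2rad(67.5))
    return int(np.ceil(n_constants * fs / slowest))


def downsample(x, target_fs: float, fs: float | None = None, max_denominator: int = 1000):
    """Polyphase rational down-sampling with anti-alias filtering.

    Non-rational rate ratios (up to ``max_denominator``) are rejected, as is
    up-sampling.
    """
    if isinstance(x, Recording):
        out = downsample(x.samples, target_fs, fs=x.fs)
        return x.copy_with(samples=out, fs=float(target_fs))
    if fs is None:
        raise ValueError("fs is required for array input")
    if not target_fs < fs:
        raise ValueError(f"target_fs {target_fs} must be below fs {fs}")
    ratio = Fraction(target_fs / fs).limit_denominator(max_denominator)
    if abs(float(ratio) - target_fs / fs) > 1e-12:
        raise ValueError(
            f"rate ratio {target_fs}/{fs} is not rational within denominator "
            f"{max_denominator}; resample upstream"
        )
    x = np.asarray(x, dtype=np.float64)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator, axis=-1)


def interpolate_channel(rec: Recording, channel_index: int) -> Recording:
    """Replace a faulty interior channel by the mean of its two neighbours.

    Outer channels cannot be interpolated and are rejected.
    """
    m = channel_index
    if m <= 0 or m >= rec.n_channels - 1:
        raise ValueError(
            f"channel {m} is an outer site and cannot be interpolated; "
            "faulty outer channels must be rejected"
        )
    samples = rec.samples.copy()
    samples[m] = 0.5 * (samples[m - 1] + samples[m + 1])
    return rec.copy_with(samples=samples)


@dataclass
class ExclusionResult:
    """Large-transient exclusion: the mask and the excluded intervals."""

    x: np.ndarray
    mask: np.ndarray          # True where the sample is KEPT
    intervals: list[tuple[float, float]]  # (onset_s, offset_s) excluded
    fs: float

    @property
    def excluded_fraction(self) -> float:
        return 1.0 - float(self.mask.mean())

    def masked(self) -> np.ndarray:
        """Samples with excluded stretches dropped."""
        return self.x[self.mask]


def exclude_large_events(
    x: np.ndarray,
    fs: float,
    k: float = 5.0,
    pad: float = 0.05,
) -> ExclusionResult:
    """Detect and mask large transients (sharp-wave-like events).

    Samples deviating from the median baseline by more than ``k`` robust
    standard deviations (MAD x 1.4826) are excluded, padded by ``pad``
    seconds on each side; contiguous runs are merged into intervals.

    Raises
    ------
    ValueError
        If every sample is excluded (degenerate input).
    """
    if not k > 0:
        raise ValueError("k must be positive")
    x = np.asarray(x, dtype=np.float64)
    if np.isinf(k):
        return ExclusionResult(x=x, mask=np.ones(x.size, bool), intervals=[], fs=fs)
    baseline = np.median(x)
    mad = np.median(np.abs(x - baseline))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = np.std(x)
    bad = np.abs(x - baseline) > k * robust_sd
    pad_n = int(round(pad * fs))
    edges = np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0]))
    padded = np.zeros_like(bad)
    intervals = []
    for onset, offset in zip(edges[::2], edges[1::2]):
        a = max(0, onset - pad_n)
        b = min(x.size, offset + pad_n)
        padded[a:b] = True
    if padded.all() and padded.size:
        raise ValueError("all samples excluded: degenerate input")
    # merged intervals after padding
    edges = np.flatnonzero(np.diff(np.r_[0, padded.view(np.int8), 0]))
    for onset, offset in zip(edges[::2], edges[1::2]):
        intervals.append((onset / fs, offset / fs))
    return ExclusionResult(x=x, mask=~padded, intervals=intervals, fs=fs)
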