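"""Coupling battery for pairs of field-potential generator time courses.

Four complementary measures:

* lagged cross-correlation ``R(lag) = C12 / sqrt(C11 C22)`` with the lag of
  the maximum and a phase-randomization significance level;
* magnitude-squared spectral coherence ``C_xy(f) = |P_xy|^2 / (P_xx P_yy)``
  with a per-frequency significance threshold built from phase-randomized
  surrogates (spectrum preserved, phases scrambled);
* windowed Pearson correlation density histograms at window lengths
  Δt ∈ {1, 0.1, 0.01} s: short windows probe fast fluctuations, long windows
  the signal envelope;
* mean gamma frequency from the first positive-lag autocorrelation peak of
  the 30–100 Hz band-passed time course.

Surrogate coherences are computed with batched FFTs so that the default
1000-surrogate test is cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import filter_signal

__all__ = [
    "CCResult",
    "CoherenceResult",
    "WindowedCorrelation",
    "crosscorr_lagged",
    "phase_randomize",
    "coherence_with_significance",
    "windowed_pearson_histogram",
    "mean_frequency_autocorr",
]


# ---------------------------------------------------------------------------
# lagged cross-correlation

@dataclass
class CCResult:
    lags: np.ndarray          # seconds; positive lag: y lags (trails) x
    R: np.ndarray
    cc_max: float
    tau_max: float            # seconds
    significance: float | None = None   # surrogate (1-alpha) level for |cc_max|
    n_surrogates: int = 0


def crosscorr_lagged(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    max_lag: float,
    n_surrogates: int = 0,
    alpha: float = 0.05,
    seed: int | None = None,
) -> CCResult:
    """Normalized lagged cross-correlation of two equal-length series.

    ``R(lag)`` is the correlation coefficient of ``x(t)`` and ``y(t + lag)``;
    a positive ``tau_max`` means y lags x.  With ``n_surrogates > 0`` the
    ``(1 - alpha)`` quantile of surrogate ``|cc_max|`` (phase-randomized
    copies of both inputs) is reported as the significance level.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    max_lag_n = int(round(max_lag * fs))
    if x.size < 10 * max(max_lag_n, 1):
        raise ValueError("series must be at least 10x the maximum lag")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input: correlation undefined")

    def _cc_curve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = a - a.mean()
        b = b - b.mean()
        n = a.size
        full = np.correlate(b, a, mode="full")  # index n-1+l <-> sum x(t) y(t+l)
        curve = full[n - 1 - max_lag_n : n + max_lag_n] / (n * a.std() * b.std())
        return curve

    R = _cc_curve(x, y)
    lags = np.arange(-max_lag_n, max_lag_n + 1) / fs
    imax = int(np.argmax(np.abs(R)))
    result = CCResult(
        lags=lags, R=R, cc_max=float(R[imax]), tau_max=float(lags[imax])
    )
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_surrogates)
        for i in range(n_surrogates):
            xs = phase_randomize(x, rng=rng)
            ys = phase_randomize(y, rng=rng)
            maxima[i] = np.max(np.abs(_cc_curve(xs, ys)))
        result.significance = float(np.quantile(maxima, 1 - alpha))
        result.n_surrogates = n_surrogates
    return result


# ---------------------------------------------------------------------------
# phase-randomization surrogates

def phase_randomize(
    x: np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Spectrum-preserving surrogate: randomize Fourier phases.

    The amplitude spectrum (hence power spectrum and autocorrelation) is
    preserved to machine precision; the DC component is kept so the mean is
    unchanged.  The Nyquist bin (even length) gets a random sign.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    return _phase_randomize_batch(x[None, :], rng)[0]


def _phase_randomize_batch(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomize each row of a (batch, T) array."""
    n = X.shape[-1]
    F = np.fft.rfft(X, axis=-1)
    amp = np.abs(F)
    theta = rng.uniform(0, 2 * np.pi, size=F.shape)
    S = amp * np.exp(1j * theta)
    S[..., 0] = F[..., 0]  # keep DC -> mean preserved
    if n % 2 == 0:
        # Nyquist bin must stay real; random sign preserves |FFT|
        S[..., -1] = F[..., -1] * rng.choice([-1.0, 1.0], size=F.shape[:-1])
    return np.fft.irfft(S, n=n, axis=-1)


# ---------------------------------------------------------------------------
# Welch coherence with surrogate thresholds

@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray     # C_xy(f) in [0, 1]
    threshold: np.ndarray | None    # per-frequency surrogate (1-alpha) quantile
    significant: np.ndarray | None  # C_xy > threshold
    n_surrogates: int = 0
    alpha: float = 0.05
    n_segments: int = 0

    @property
    def significant_fraction(self) -> float:
        if self.significant is None:
            return float("nan")
        return float(self.significant.mean())


def _segment_ffts(X: np.ndarray, nperseg: int, step: int, window: np.ndarray):
    """Windowed, demeaned segment rFFTs of the last axis: (..., n_seg, n_freq)."""
    segs = sliding_window_view(X, nperseg, axis=-1)[..., ::step, :]
    segs = (segs - segs.mean(axis=-1, keepdims=True)) * window
    return np.fft.rfft(segs, axis=-1)


def _welch_coherence(
    X: np.ndarray, Y: np.ndarray, nperseg: int, step: int, window: np.ndarray
) -> np.ndarray:
    """Magnitude-squared coherence of paired rows, batched over leading axes."""
    Fx = _segment_ffts(X, nperseg, step, window)
    Fy = _segment_ffts(Y, nperseg, step, window)
    Pxy = np.mean(np.conj(Fx) * Fy, axis=-2)
    Pxx = np.mean(np.abs(Fx) ** 2, axis=-2)
    Pyy = np.mean(np.abs(Fy) ** 2, axis=-2)
    return np.abs(Pxy) ** 2 / (Pxx * Pyy)


def coherence_with_significance(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    _surrogate_chunk: int = 200,
) -> CoherenceResult:
    """Welch magnitude-squared coherence with a phase-randomization null.

    Both inputs are independently phase-randomized ``n_surrogates`` times;
    the per-frequency ``(1 - alpha)`` quantile of the surrogate coherences
    is the significance threshold.  Segments overlapping a masked stretch
    (``mask`` is a keep-mask from large-event exclusion) are dropped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    nperseg = int(round(segment_s * fs))
    step = max(1, int(round(nperseg * (1 - overlap))))
    n_seg = (x.size - nperseg) // step + 1
    if n_seg < 2:
        raise ValueError(
            "need at least 2 Welch segments (coherence of one segment is 1)"
        )
    if x.size < 8 * nperseg * (1 - overlap):
        warnings.warn("fewer than 8 Welch segments; coherence bias is high")
    window = np.hanning(nperseg)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)

    keep_seg = None
    if mask is not None:
        seg_mask = sliding_window_view(np.asarray(mask, bool), nperseg)[::step, :]
        keep_seg = seg_mask.all(axis=-1)
        if keep_seg.sum() < 2:
            raise ValueError("fewer than 2 unmasked Welch segments")

    def _coh(a, b):
        Fa = _segment_ffts(a, nperseg, step, window)
        Fb = _segment_ffts(b, nperseg, step, window)
        if keep_seg is not None:
            Fa = Fa[..., keep_seg, :]
            Fb = Fb[..., keep_seg, :]
        Pab = np.mean(np.conj(Fa) * Fb, axis=-2)
        Paa = np.mean(np.abs(Fa) ** 2, axis=-2)
        Pbb = np.mean(np.abs(Fb) ** 2, axis=-2)
        return np.abs(Pab) ** 2 / (Paa * Pbb)

    C = _coh(x, y)

    threshold = significant = None
    if n_surrogates > 0:
        # single precision in the surrogate path: the (1 - alpha) quantile of
        # the null is far coarser than float32 resolution, and the batch FFTs
        # run twice as fast
        rng = np.random.default_rng(seed)
        amp_x = np.abs(np.fft.rfft(x)).astype(np.float32)
        amp_y = np.abs(np.fft.rfft(y)).astype(np.float32)
        surr = np.empty((n_surrogates, freqs.size), dtype=np.float32)
        win32 = window.astype(np.float32)
        done = 0
        while done < n_surrogates:
            m = min(_surrogate_chunk, n_surrogates - done)
            theta_x = rng.uniform(0, 2 * np.pi, (m, amp_x.size)).astype(np.float32)
            theta_y = rng.uniform(0, 2 * np.pi, (m, amp_y.size)).astype(np.float32)
            xs = sfft.irfft((amp_x * np.exp(1j * theta_x)).astype(np.complex64), n=x.size, axis=-1)
            ys = sfft.irfft((amp_y * np.exp(1j * theta_y)).astype(np.complex64), n=y.size, axis=-1)
            sa = sliding_window_view(xs, nperseg, axis=-1)[..., ::step, :]
            sb = sliding_window_view(ys, nperseg, axis=-1)[..., ::step, :]
            if keep_seg is not None:
                sa = sa[..., keep_seg, :]
                sb = sb[..., keep_seg, :]
            Fa = sfft.rfft(np.ascontiguousarray((sa - sa.mean(-1, keepdims=True)) * win32), axis=-1)
            Fb = sfft.rfft(np.ascontiguousarray((sb - sb.mean(-1, keepdims=True)) * win32), axis=-1)
            Pab = np.mean(np.conj(Fa) * Fb, axis=-2)
            Paa = np.mean(np.abs(Fa) ** 2, axis=-2)
            Pbb = np.mean(np.abs(Fb) ** 2, axis=-2)
            surr[done : done + m] = (np.abs(Pab) ** 2 / (Paa * Pbb)).real
            done += m
        threshold = np.quantile(surr.astype(np.float64), 1 - alpha, axis=0)
        significant = C > threshold

    return CoherenceResult(
        freqs=freqs,
        coherence=C,
        threshold=threshold,
        significant=significant,
        n_surrogates=n_surrogates,
        alpha=alpha,
        n_segments=int(n_seg if keep_seg is None else keep_seg.sum()),
    )


# ---------------------------------------------------------------------------
# windowed Pearson density histograms

@dataclass
class WindowedCorrelation:
    window_s: float
    r: np.ndarray             # per-window Pearson r; NaN where undefined/masked
    edges: np.ndarray
    density: np.ndarray
    mean: float               # chi
    sd: float                 # sigma
    n_windows: int = 0
    n_valid: int = 0


def windowed_pearson_histogram(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    dt: float,
    bins: int = 41,
    mask: np.ndarray | None = None,
) -> WindowedCorrelation:
    """Per-window Pearson r of two series, summarized as a density histogram.

    The signals are chopped into non-overlapping windows of length ``dt``
    seconds (incomplete trailing window dropped).  Windows with zero
    variance, or overlapping a masked stretch, are recorded as missing.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = int(round(dt * fs))
    if n < 3:
        raise ValueError(f"window of {dt} s at {fs} Hz has {n} < 3 samples")
    n_windows = x.size // n
    if n_windows < 20:
        raise ValueError(f"only {n_windows} windows; at least 20 required")
    xw = x[: n_windows * n].reshape(n_windows, n)
    yw = y[: n_windows * n].reshape(n_windows, n)
    flat = (np.ptp(xw, axis=1) == 0) | (np.ptp(yw, axis=1) == 0)
    xw = xw - xw.mean(axis=1, keepdims=True)
    yw = yw - yw.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.sum(xw**2, axis=1))
    sy = np.sqrt(np.sum(yw**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sum(xw * yw, axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0) | flat] = np.nan
    if mask is not None:
        wm = np.asarray(mask, bool)[: n_windows * n].reshape(n_windows, n)
        r[~wm.all(axis=1)] = np.nan
    valid = r[np.isfinite(r)]
    edges = np.linspace(-1.0, 1.0, bins + 1)
    density, _ = np.histogram(valid, bins=edges, density=True)
    return WindowedCorrelation(
        window_s=dt,
        r=r,
        edges=edges,
        density=density,
        mean=float(valid.mean()) if valid.size else float("nan"),
        sd=float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
        n_windows=n_windows,
        n_valid=int(valid.size),
    )


# ---------------------------------------------------------------------------
# gamma mean frequency

def mean_frequency_autocorr(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (30.0, 100.0),
) -> float:
    """Mean oscillation frequency from the autocorrelation of a band-passed
    series: reciprocal of the first positive-lag autocorrelation maximum.

    Returns NaN (with a warning) when no positive-lag peak rises above the
    noise floor.
    """
    x = np.asarray(x, float)
    lo, hi = band
    if x.size < 100 * fs / lo:
        raise ValueError("series shorter than 100 cycles of the band's low edge")
    xf = filter_signal(x, "bandpass", band, fs=fs)
    xf = xf - xf.mean()
    # FFT autocorrelation, biased normalization
    nfft = int(2 ** np.ceil(np.log2(2 * xf.size)))
    F = np.fft.rfft(xf, n=nfft)
    ac = np.fft.irfft(np.abs(F) ** 2)[: xf.size]
    ac /= ac[0]
    max_lag = int(np.ceil(2 * fs / lo))  # search up to two low-edge periods
    seg = ac[: max_lag + 2]
    # first interior local maximum at positive lag
    floor = 3.0 / np.sqrt(xf.size)
    for lag in range(1, len(seg) - 1):
        if seg[lag] >= seg[lag - 1] and seg[lag] > seg[lag + 1] and seg[lag] > floor:
            return float(fs / lag)
    warnings.warn("no positive-lag autocorrelation peak above noise floor")
    return float("nan")
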