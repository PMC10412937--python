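"""One-dimensional current-source-density (CSD) estimation.

The CSD along a linear probe is the negative second spatial difference of
the voltage, scaled by conductivity over squared inter-site distance:

    CSD_m(t) = -(sigma / h^2) * (u_{m-1}(t) - 2 u_m(t) + u_{m+1}(t))

Edge channels are omitted (no mirrored boundary).  Any channel-constant
contribution — a volume-conducted potential from a remote source — cancels
exactly, which is the point of the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording

__all__ = ["CSDMap", "csd_1d"]


@dataclass
class CSDMap:
    """CSD values on the interior channels, in sigma-scaled units (mV/µm²)."""

    values: np.ndarray        # (n_channels - 2) x n_times
    sigma: float
    h: float                  # µm
    fs: float
    depths: np.ndarray        # interior-channel depths, µm


def csd_1d(
    x: Recording | np.ndarray,
    sigma: float = 1.0,
    h: float | None = None,
    fs: float | None = None,
    smooth: bool = False,
) -> CSDMap:
    """Estimate 1-D CSD from a laminar voltage distribution.

    Parameters
    ----------
    x : Recording or ndarray (channels x time)
    sigma : float
        Extracellular conductivity (arbitrary units; results scale with it).
    h : float
        Inter-site distance in µm; taken from the Recording when given.
    smooth : bool
        Optional 3-point Hamming smoothing along depth (off by default).
    """
    if isinstance(x, Recording):
        samples, h, fs = x.samples, x.h, x.fs
        depths = x.depths
    else:
        samples = np.asarray(x, dtype=np.float64)
        if h is None:
            raise ValueError("h is required for array input")
        if fs is None:
            fs = float("nan")
        depths = h * np.arange(samples.shape[0])
    if samples.shape[0] < 3:
        raise ValueError("CSD requires at least 3 channels")
    if not h > 0:
        raise ValueError("h must be positive")
    u = samples
    values = -(sigma / h**2) * (u[:-2] - 2 * u[1:-1] + u[2:])
    if smooth and values.shape[0] >= 3:
        w = np.hamming(3)
        w /= w.sum()
        inner = w[0] * values[:-2] + w[1] * values[1:-1] + w[2] * values[2:]
        values = np.vstack([values[:1], inner, values[-1:]])
    return CSDMap(values=values, sigma=sigma, h=float(h), fs=float(fs),
                  depths=depths[1:-1])
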