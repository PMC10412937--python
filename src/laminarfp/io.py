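"""Containers and file I/O for bilateral multichannel laminar recordings.

A :class:`Recording` holds one probe's field potentials as a channels x time
matrix (mV) together with the sampling rate, per-channel depths (µm, uniform
spacing) and free-form metadata.  A :class:`BilateralRecording` pairs the left
and right probes of one animal; both sides must agree in sampling rate,
channel count and duration.

On-disk container is HDF5: datasets ``samples`` (channels x time, float64)
and ``depths``, root attributes ``fs`` and ``side``, metadata under
``meta/``.  Event/interval tables are CSV with header
``onset_s,offset_s,label``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "BilateralRecording",
    "FormatError",
    "PairingError",
    "read_recording",
    "write_recording",
    "read_intervals",
    "write_intervals",
]


class FormatError(ValueError):
    """A container is missing required fields or has inconsistent shapes."""


class PairingError(ValueError):
    """Left/right recordings cannot be assembled into a bilateral pair."""


_DEPTH_TOL = 1e-9  # µm; spacing must be uniform to within this


@dataclass
class Recording:
    """One laminar probe's field potentials.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Field potentials in mV.
    fs : float
        Sampling rate in Hz.
    depths : ndarray, shape (n_channels,)
        Electrode depths in µm, uniformly spaced.
    side : str
        ``"left"`` or ``"right"``.
    meta : dict
        Free-form metadata (subject id, epoch id, ...).
    """

    samples: np.ndarray
    fs: float
    depths: np.ndarray | None = None
    side: str = "left"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D channels x time array")
        if self.n_channels < 2:
            raise FormatError("a laminar recording needs at least 2 channels")
        if not self.fs > 0:
            raise FormatError(f"fs must be positive, got {self.fs}")
        if self.depths is None:
            # default geometry: 65 µm spacing from the surface
            self.depths = 65.0 * np.arange(self.n_channels)
        self.depths = np.asarray(self.depths, dtype=np.float64)
        if self.depths.shape != (self.n_channels,):
            raise FormatError("depths must have one entry per channel")
        steps = np.diff(self.depths)
        if len(steps) and np.ptp(steps) > _DEPTH_TOL:
            raise FormatError("depth spacing must be uniform")
        if self.side not in ("left", "right"):
            raise FormatError(f"side must be 'left' or 'right', got {self.side!r}")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_times / self.fs

    @property
    def h(self) -> float:
        """Inter-site distance in µm."""
        return float(self.depths[1] - self.depths[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    def copy_with(self, **changes: Any) -> "Recording":
        return dataclasses.replace(self, **changes)


@dataclass
class BilateralRecording:
    """Homotopic left and right laminar recordings from one animal."""

    left: Recording
    right: Recording

    def __post_init__(self) -> None:
        l, r = self.left, self.right
        if l.n_channels != r.n_channels:
            raise PairingError(
                f"channel count mismatch: left {l.n_channels}, right {r.n_channels}"
            )
        if l.fs != r.fs:
            raise PairingError(f"sampling rate mismatch: {l.fs} vs {r.fs}")
        if l.n_times != r.n_times:
            raise PairingError(
                f"duration mismatch: {l.n_times} vs {r.n_times} samples"
            )

    @property
    def fs(self) -> float:
        return self.left.fs

    @property
    def sides(self) -> tuple[Recording, Recording]:
        return self.left, self.right


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples, dtype=np.float64)
        f.create_dataset("depths", data=rec.depths, dtype=np.float64)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["side"] = rec.side
        g = f.create_group("meta")
        for k, v in rec.meta.items():
            g.attrs[k] = v


def read_recording(path: str | Path) -> Recording:
    """Read a :class:`Recording` from an HDF5 container.

    Raises
    ------
    FormatError
        If required datasets or attributes are missing.
    """
    with h5py.File(path, "r") as f:
        for ds in ("samples", "depths"):
            if ds not in f:
                raise FormatError(f"container missing dataset {ds!r}")
        if "fs" not in f.attrs:
            raise FormatError("container missing required attribute 'fs'")
        if "side" not in f.attrs:
            raise FormatError("container missing required attribute 'side'")
        meta = {}
        if "meta" in f:
            meta = {k: _native(v) for k, v in f["meta"].attrs.items()}
        return Recording(
            samples=f["samples"][()],
            fs=float(f.attrs["fs"]),
            depths=f["depths"][()],
            side=str(_native(f.attrs["side"])),
            meta=meta,
        )


def _native(v: Any) -> Any:
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


def write_intervals(intervals: list[tuple[float, float, str]], path: str | Path) -> None:
    """Write (onset, offset, label) intervals as a CSV table."""
    df = pd.DataFrame(intervals, columns=["onset_s", "offset_s", "label"])
    df.to_csv(path, index=False)


def read_intervals(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    for col in ("onset_s", "offset_s", "label"):
        if col not in df.columns:
            raise FormatError(f"interval table missing column {col!r}")
    return [
        (float(r.onset_s), float(r.offset_s), str(r.label))
        for r in df.itertuples()
    ]
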