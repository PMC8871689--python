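"""Uniformly sampled signal container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: admissible signal kinds
KINDS = ("hemoglobin", "optical_density", "acceleration")


@dataclass
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    values
        Sample values. Units depend on ``kind``: µmol/L for hemoglobin
        concentration changes, dimensionless for optical density, g for
        acceleration.
    fs
        Sampling rate in Hz (must be positive).
    label
        Free-text channel name.
    kind
        One of ``{"hemoglobin", "optical_density", "acceleration"}``.
    """

    values: np.ndarray
    fs: float
    label: str = ""
    kind: str = "hemoglobin"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size < 1:
            raise ValueError("TimeSeries must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must all be finite")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (t0 = 0)."""
        return np.arange(len(self)) / self.fs

    def copy_with(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        """Return a new series with the same metadata but different samples."""
        return TimeSeries(
            values=np.asarray(values, dtype=float),
            fs=self.fs,
            label=self.label if label is None else label,
            kind=self.kind,
        )


def as_values_fs(x, fs: float | None = None) -> tuple[np.ndarray, float]:
    """Accept either a :class:`TimeSeries` or an array plus explicit ``fs``."""
    if isinstance(x, TimeSeries):
        return x.values, x.fs
    if fs is None:
        raise TypeError("fs is required when the input is a bare array")
    return np.asarray(x, dtype=float), float(fs)
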