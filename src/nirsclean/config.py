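"""Run configuration for the detection/correction pipeline."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters governing detection, correction and simulation.

    Attributes
    ----------
    alpha
        Two-sided standard-normal tail probability used to derive the
        wavelet processing threshold; must lie in (0, 1).
    mother_wavelet
        PyWavelets name of the mother wavelet for the denoising stage.
    K
        Number of circular shifts for cyclic averaging (cycle spinning).
    p_severe
        Smoothing parameter of the cubic smoothing spline fitted inside
        severe-oscillation segments, in [0, 1]; 1 interpolates.
    hp_final_hz
        Cutoff of the final zero-phase high-pass filter (Hz).
    hp_threshold_hz
        Cutoff of the zero-phase filter applied to the clipped moving-SD
        series when building the dynamic threshold (Hz).
    threshold_filter
        ``"highpass"`` (default) or ``"lowpass"``; which response to use
        for the ``hp_threshold_hz`` stage.
    quiet_seconds
        Minimum duration of the quiet (non-oscillation) runs flanking an
        oscillation for it to be eligible as a baseline shift.
    merge_gap_s
        Oscillation runs separated by less than this many seconds of
        unlabeled samples are merged before confirmation and baseline-shift
        analysis.
    wavelet_level
        Decomposition depth for the denoising stage; ``None`` selects the
        deepest level whose approximation band still contains the
        hemodynamic band (see ``band_upper_hz``).
    band_upper_hz
        Upper edge of the hemodynamic band of interest (Hz); used only to
        choose the automatic decomposition depth.
    seed
        Seed for any randomized step (simulation); ``None`` leaves sources
        unseeded.
    """

    alpha: float = 0.05
    mother_wavelet: str = "db4"
    K: int = 16
    p_severe: float = 0.99
    hp_final_hz: float = 0.003
    hp_threshold_hz: float = 0.02
    threshold_filter: str = "highpass"
    quiet_seconds: float = 5.0
    merge_gap_s: float = 1.0
    wavelet_level: int | None = None
    band_upper_hz: float = 0.04
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 <= self.p_severe <= 1:
            raise ValueError(f"p_severe must lie in [0, 1], got {self.p_severe}")
        if self.K < 1:
            raise ValueError(f"K must be a positive integer, got {self.K}")
        if self.threshold_filter not in ("highpass", "lowpass"):
            raise ValueError(
                f"threshold_filter must be 'highpass' or 'lowpass', "
                f"got {self.threshold_filter!r}"
            )
        for name in ("hp_final_hz", "hp_threshold_hz", "quiet_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def check_against_fs(self, fs: float) -> None:
        """Verify that filter cutoffs are below the Nyquist frequency."""
        for name in ("hp_final_hz", "hp_threshold_hz"):
            cutoff = getattr(self, name)
            if cutoff >= fs / 2:
                raise ValueError(
                    f"{name}={cutoff} Hz is not below Nyquist ({fs / 2} Hz)"
                )

    def with_overrides(self, **kwargs) -> "RunConfig":
        """New config with the given non-None fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML mapping; unknown keys fail."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
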