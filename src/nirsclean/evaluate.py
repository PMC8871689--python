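"""SNR / Pearson-R scoring and benchmark harness for correction methods.

Quality is measured against a known clean reference: the SNR of a signal
``z`` is ``10·log10(Σx² / Σ(z - x)²)`` and R is the sample Pearson
correlation between clean and processed. The benchmark runner applies a
set of methods (the proposed pipeline plus in-scope comparators) to each
simulated segment and tabulates per-segment and summary scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .config import RunConfig
from .correct import (
    correct_pipeline,
    correct_severe,
    default_level,
    estimate_sigma,
    highpass,
    remove_baseline_shift,
    thresholds_from_alpha,
    zero_outliers,
)
from .detect import detect
from .simulate import SyntheticDataset
from .timeseries import TimeSeries


@dataclass(frozen=True)
class EvalResult:
    """Scores for one method on one segment. SNRs in dB, r dimensionless."""

    snr_noised: float
    snr_processed: float
    r: float
    method: str
    segment_id: str
    r_noised: float = math.nan

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")


def snr(clean, other) -> float:
    """Signal-to-noise ratio of ``other`` against the clean reference, in dB.

    Returns ``math.inf`` (a documented sentinel) when the residual is
    exactly zero.
    """
    clean = np.asarray(clean, dtype=float)
    other = np.asarray(other, dtype=float)
    if clean.shape != other.shape:
        raise ValueError("clean and other must have equal length")
    num = float(np.sum(clean**2))
    if num == 0.0:
        raise ValueError("clean signal is identically zero")
    den = float(np.sum((other - clean) ** 2))
    if den == 0.0:
        return math.inf
    return 10.0 * math.log10(num / den)


def pearson_r(clean, processed) -> float:
    """Sample Pearson correlation between clean and processed signals."""
    clean = np.asarray(clean, dtype=float)
    processed = np.asarray(processed, dtype=float)
    if clean.shape != processed.shape:
        raise ValueError("inputs must have equal length")
    if clean.std() == 0.0 or processed.std() == 0.0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(np.corrcoef(clean, processed)[0, 1])


def median_filter_baseline(
    x, width: int = 600, step: int = 10
) -> np.ndarray:
    """Sliding-median comparator evaluated on a decimated grid.

    The median of a centered window of ``width`` samples is computed every
    ``step`` samples (windows truncated at the record edges) and linearly
    interpolated back to full length.
    """
    values = x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)
    n = values.size
    if n < width:
        raise ValueError(f"series of length {n} shorter than window {width}")
    half = width // 2
    centers = np.arange(0, n, step)
    medians = np.array(
        [np.median(values[max(0, c - half) : min(n, c + half + 1)]) for c in centers]
    )
    return np.interp(np.arange(n), centers, medians)


def single_threshold_wavelet_baseline(
    x,
    fs: float | None = None,
    alpha: float = 0.05,
    wavelet: str = "db4",
    level: int | None = None,
    band_upper_hz: float = 0.04,
    threshold: float | None = None,
) -> np.ndarray:
    """Single-threshold wavelet comparator (reduced form of the denoiser).

    Identical to the dual-threshold stage except that w1 = w2 (each
    coefficient judged independently, no neighbor expansion) and there is
    no cyclic averaging: one decomposition, one reconstruction.
    ``threshold`` overrides the estimated u·σ̂ value.
    """
    if isinstance(x, TimeSeries):
        fs = x.fs
        values = x.values
    else:
        values = np.asarray(x, dtype=float)
    if fs is None:
        raise TypeError("fs is required when the input is a bare array")
    n = values.size
    lvl = level if level is not None else default_level(n, fs, wavelet, band_upper_hz)
    coeffs = pywt.wavedec(values, wavelet, mode="symmetric", level=lvl)
    details = coeffs[1:]
    if threshold is None:
        threshold = thresholds_from_alpha(alpha, estimate_sigma(details)).w2
    # w1 == w2 collapses the dual rule to independent thresholding
    new_details = zero_outliers(details, threshold, threshold)
    rec = pywt.waverec([coeffs[0], *new_details], wavelet, mode="symmetric")
    return rec[:n]


def spline_only(ts: TimeSeries, config: RunConfig | None = None) -> np.ndarray:
    """Severe + baseline-shift spline stages and final high-pass, no wavelet."""
    cfg = config or RunConfig()
    annotation = detect(ts, strategy="fnirs", config=cfg)
    x1 = correct_severe(ts.values, annotation, p=cfg.p_severe)
    x2 = remove_baseline_shift(x1, annotation, ts.fs)
    return highpass(x2, ts.fs, cfg.hp_final_hz)


def standard_methods(config: RunConfig | None = None) -> dict:
    """The comparison set: proposed pipeline plus in-scope baselines."""
    cfg = config or RunConfig()
    return {
        "proposed": lambda ts: correct_pipeline(ts, cfg).y,
        "single_threshold_wavelet": lambda ts: single_threshold_wavelet_baseline(
            ts, alpha=cfg.alpha, wavelet=cfg.mother_wavelet,
            level=cfg.wavelet_level, band_upper_hz=cfg.band_upper_hz,
        ),
        "median_filter": median_filter_baseline,
        "spline_only": lambda ts: spline_only(ts, cfg),
    }


def run_benchmark(
    datasets: list[SyntheticDataset],
    methods: dict | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Score every method on every dataset.

    Returns one row per (segment, method) with ``snr_noised``,
    ``snr_processed``, ``r_noised`` and ``r``. Infinite SNRs (zero
    residual) propagate as ``inf``.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    methods = methods if methods is not None else standard_methods(config)
    if not methods:
        raise ValueError("need at least one method")
    rows = []
    for i, ds in enumerate(datasets):
        clean = ds.clean.values
        noised = ds.noised.values
        snr_n = snr(clean, noised)
        r_n = pearson_r(clean, noised)
        for name, fn in methods.items():
            processed = np.asarray(fn(ds.noised), dtype=float)
            res = EvalResult(
                snr_noised=snr_n,
                snr_processed=snr(clean, processed),
                r=pearson_r(clean, processed),
                r_noised=r_n,
                method=name,
                segment_id=str(i),
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean and SD of the benchmark scores."""
    return (
        results.groupby("method")[["snr_noised", "snr_processed", "r_noised", "r"]]
        .agg(["mean", "std"])
        .sort_index()
    )
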