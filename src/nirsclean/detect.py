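"""Motion-artifact detection from fNIRS signals or 3-axis acceleration.

The detector computes a two-sided moving standard deviation of the signal,
builds a per-sample dynamic threshold from its 30/50/70% quantiles, and
classifies each sample as no artifact, slight oscillation, or suspected
severe oscillation. Suspected severe regions are confirmed peak-by-peak
against a 6×SD range criterion, and baseline shifts are flagged on
oscillation regions whose flanking quiet periods differ in mean level by
more than half the oscillation's range.

All stages are positively homogeneous, so detection results are invariant
under amplitude rescaling of the input; the moving SD is also
translation-invariant, so oscillation labels do not depend on DC offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from ._util import merge_runs, quantile_first, runs_of
from .annotations import (
    BASELINE_SHIFT,
    SEVERE,
    SLIGHT,
    ArtifactAnnotation,
    ArtifactSegment,
)
from .config import RunConfig
from .timeseries import TimeSeries, as_values_fs

# per-sample labels
LABEL_NONE = 0
LABEL_SLIGHT = 1
LABEL_SEVERE_SUSPECTED = 2


@dataclass
class ThresholdSeries:
    """Moving SD, its quantiles and the dynamic threshold derived from them."""

    t: np.ndarray
    A: np.ndarray
    T1: float
    T2: float
    T3: float


def window_half_width(fs: float) -> int:
    """Half-width k of the moving-SD window; the window length is 2k+1."""
    return int(round(3.0 * fs))


def moving_sd(x, fs: float | None = None) -> np.ndarray:
    """Two-sided moving standard deviation with window W = 2k+1, k = 3·fs.

    The SD is the population SD over each centered window. The first and
    last k samples, where the window does not fit, replicate the nearest
    interior value so the output has the same length as the input.
    """
    values, fs = as_values_fs(x, fs)
    k = window_half_width(fs)
    w = 2 * k + 1
    n = values.size
    if n < w:
        raise ValueError(
            f"series of length {n} is shorter than the moving-SD window "
            f"W={w} (k=3*fs={k}); cannot run detection"
        )
    # center for numerical stability; the SD is translation-invariant
    v = values - values.mean()
    c1 = np.concatenate(([0.0], np.cumsum(v)))
    c2 = np.concatenate(([0.0], np.cumsum(v * v)))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = (s2 - s1 * s1 / w) / w
    core = np.sqrt(np.maximum(var, 0.0))
    t = np.empty(n)
    t[k : n - k] = core
    t[:k] = core[0]
    t[n - k :] = core[-1]
    return t


def dynamic_threshold(
    t: np.ndarray,
    fs: float,
    cutoff_hz: float = 0.02,
    filter_kind: str = "highpass",
) -> ThresholdSeries:
    """Per-sample dynamic threshold A(n) from the moving-SD series.

    T1/T2/T3 are the maxima of the first 30/50/70% of the ascending-sorted
    series. The series is clipped into [T1, T3], filtered with a zero-phase
    order-3 IIR filter at ``cutoff_hz``, floored at T2, and offset by
    3(T3 - T1). All steps are positively homogeneous, so the threshold
    scales with the signal amplitude.
    """
    t = np.asarray(t, dtype=float)
    n = t.size
    if n < 10:
        raise ValueError(f"series too short for quantiles (N={n} < 10)")
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz not in (0, {fs / 2}) Hz")
    srt = np.sort(t)
    t1 = quantile_first(srt, 0.3)
    t2 = quantile_first(srt, 0.5)
    t3 = quantile_first(srt, 0.7)
    clipped = np.clip(t, t1, t3)
    sos = butter(3, cutoff_hz, btype=filter_kind, fs=fs, output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1), n - 1)
    filtered = sosfiltfilt(sos, clipped, padlen=padlen)
    floored = np.maximum(filtered, t2)
    a = floored + 3.0 * (t3 - t1)
    return ThresholdSeries(t=t, A=a, T1=t1, T2=t2, T3=t3)


def classify_samples(t: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Per-sample oscillation labels from moving SD vs dynamic threshold.

    t > 2A: suspected severe; A < t <= 2A: slight; t <= A: none.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    if t.shape != a.shape:
        raise ValueError("t and A must have equal length")
    labels = np.zeros(t.size, dtype=np.int8)
    labels[t > a] = LABEL_SLIGHT
    labels[t > 2.0 * a] = LABEL_SEVERE_SUSPECTED
    return labels


def _bfill_sign(sign: np.ndarray) -> np.ndarray:
    """Replace zeros with the next nonzero value (plateau → first sample)."""
    out = sign.copy()
    nxt = 0.0
    for i in range(out.size - 1, -1, -1):
        if out[i] == 0.0:
            out[i] = nxt
        else:
            nxt = out[i]
    return out


def segment_by_slope(
    x: np.ndarray, region: tuple[int, int]
) -> list[tuple[int, int]]:
    """Split a region at the troughs of the signal, one peak per segment.

    Junctions are placed at local minima; a trough plateau is resolved to
    its first sample. Regions shorter than 3 samples are one segment.
    """
    x = np.asarray(x, dtype=float)
    s, e = region
    if not (0 <= s < e <= x.size):
        raise ValueError(f"region [{s}, {e}) outside signal of length {x.size}")
    if e - s < 3:
        return [(s, e)]
    seg = x[s:e]
    sign = _bfill_sign(np.sign(np.diff(seg)))
    troughs = [
        i
        for i in range(1, seg.size - 1)
        if sign[i - 1] < 0 and sign[i] > 0
    ]
    bounds = [s] + [s + i for i in troughs] + [e]
    return [(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def confirm_severe(
    x: np.ndarray, suspected_region: tuple[int, int]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Confirm a suspected severe region peak-by-peak.

    The region is split at troughs; a sub-segment whose range
    (max - min) is at least 6× the SD of the signal over the whole
    suspected region is confirmed severe, the rest are demoted to slight.
    Adjacent sub-segments of the same outcome are merged.
    """
    x = np.asarray(x, dtype=float)
    s, e = suspected_region
    sd = float(np.std(x[s:e]))
    severe: list[tuple[int, int]] = []
    slight: list[tuple[int, int]] = []
    for a, b in segment_by_slope(x, (s, e)):
        rng = float(x[a:b].max() - x[a:b].min())
        (severe if rng >= 6.0 * sd else slight).append((a, b))
    return merge_runs(severe, 1), merge_runs(slight, 1)


def detect_baseline_shift(
    x: np.ndarray,
    oscillation_segments: list[tuple[int, int]],
    fs: float,
    quiet_seconds: float = 5.0,
) -> list[tuple[int, int]]:
    """Mark oscillation runs whose flanking quiet levels differ strongly.

    For each oscillation run with non-oscillation runs of at least
    ``quiet_seconds`` on both sides, the means over the entire adjacent
    quiet runs are compared: the run is a baseline shift iff
    |ave_before - ave_after| > (x_max - x_min)/2 over the run. Runs
    without two sufficiently long quiet flanks are not eligible.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    runs = sorted(oscillation_segments)
    min_quiet = quiet_seconds * fs
    marked: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(runs):
        prev_end = runs[i - 1][1] if i > 0 else 0
        next_start = runs[i + 1][0] if i + 1 < len(runs) else n
        before = x[prev_end:s]
        after = x[e:next_start]
        if before.size < min_quiet or after.size < min_quiet:
            continue
        half_range = (x[s:e].max() - x[s:e].min()) / 2.0
        if abs(before.mean() - after.mean()) > half_range:
            marked.append((s, e))
    return marked


def integrate_acceleration(
    ax: TimeSeries, ay: TimeSeries, az: TimeSeries
) -> TimeSeries:
    """Root-mean-square of the three acceleration axes: sqrt((ax²+ay²+az²)/3)."""
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError("acceleration axes must have equal length")
    if not (ax.fs == ay.fs == az.fs):
        raise ValueError("acceleration axes must share a sampling rate")
    acc = np.sqrt((ax.values**2 + ay.values**2 + az.values**2) / 3.0)
    return TimeSeries(values=acc, fs=ax.fs, label="acc", kind="acceleration")


def accel_threshold(d: np.ndarray) -> np.ndarray:
    """Dynamic threshold B(n) for the acceleration strategy.

    T is the maximum of the first 30% of the sorted moving-SD series d(n);
    d is clipped into [T/2, T] and doubled.
    """
    d = np.asarray(d, dtype=float)
    t = quantile_first(np.sort(d), 0.3)
    return 2.0 * np.clip(d, 0.5 * t, t)


def detect(
    x: TimeSeries,
    accel: tuple[TimeSeries, TimeSeries, TimeSeries] | None = None,
    strategy: str = "fnirs",
    config: RunConfig | None = None,
) -> ArtifactAnnotation:
    """Full artifact detection: oscillation labels, confirmation, baseline shifts.

    With ``strategy="fnirs"`` the moving SD of the signal itself is compared
    against the dynamic threshold A(n); with ``strategy="accel"`` the moving
    SD of the integrated acceleration is compared against B(n). Severe
    confirmation and baseline-shift analysis always run on the fNIRS trace.
    """
    cfg = config or RunConfig()
    cfg.check_against_fs(x.fs)
    if strategy == "fnirs":
        t = moving_sd(x)
        th = dynamic_threshold(
            t, x.fs, cfg.hp_threshold_hz, cfg.threshold_filter
        )
        labels = classify_samples(t, th.A)
        source = "fnirs"
    elif strategy == "accel":
        if accel is None or len(accel) != 3:
            raise ValueError("accel strategy requires three acceleration traces")
        acc = integrate_acceleration(*accel)
        if len(acc) != len(x):
            raise ValueError("acceleration and fNIRS traces must have equal length")
        d = moving_sd(acc)
        labels = classify_samples(d, accel_threshold(d))
        source = "accel"
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    vals = x.values
    n = vals.size
    gap = max(1, int(round(cfg.merge_gap_s * x.fs)))

    suspected = merge_runs(runs_of(labels == LABEL_SEVERE_SUSPECTED), gap)
    severe_mask = np.zeros(n, dtype=bool)
    slight_mask = labels == LABEL_SLIGHT
    for region in suspected:
        sev, sli = confirm_severe(vals, region)
        for a, b in sev:
            severe_mask[a:b] = True
        for a, b in sli:
            slight_mask[a:b] = True
    slight_mask &= ~severe_mask

    segments = [
        ArtifactSegment(a, b, SEVERE, source) for a, b in runs_of(severe_mask)
    ] + [
        ArtifactSegment(a, b, SLIGHT, source) for a, b in runs_of(slight_mask)
    ]

    osc_runs = merge_runs(runs_of(severe_mask | slight_mask), gap)
    for a, b in detect_baseline_shift(vals, osc_runs, x.fs, cfg.quiet_seconds):
        segments.append(ArtifactSegment(a, b, BASELINE_SHIFT, source))

    return ArtifactAnnotation(segments=segments, n_samples=n).validate()
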