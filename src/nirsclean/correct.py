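"""Three-stage artifact correction plus final high-pass filtering.

Stage 1 fits a near-interpolating cubic smoothing spline inside each severe
oscillation segment and subtracts it, flattening the excursion. Stage 2
fits a heavily smoothed spline inside each baseline-shift segment,
subtracts it and re-anchors the segment to its starting level, removing
the sustained level change within the segment (any residual inter-segment
offset is left to the final high-pass). Stage 3 denoises the whole signal
with a dual-threshold wavelet rule averaged over K circular shifts
(cycle spinning), and a zero-phase 0.003 Hz high-pass removes what remains
below the hemodynamic band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import make_smoothing_spline
from scipy.signal import butter, sosfiltfilt
from scipy.stats import norm

from ._util import runs_of
from .annotations import BASELINE_SHIFT, SEVERE, ArtifactAnnotation
from .config import RunConfig
from .detect import detect
from .timeseries import TimeSeries


@dataclass(frozen=True)
class WaveletThresholds:
    """Dual thresholds governing coefficient zeroing.

    ``w2 = u·σ̂`` is the processing threshold bounding the contiguous run
    removed; ``w1 = 1.3·w2`` is the detecting threshold that triggers
    removal. ``u`` is the positive standard-normal deviate with two-sided
    tail mass ``alpha``.
    """

    alpha: float
    u: float
    sigma_hat: float
    w1: float
    w2: float


def smoothing_spline(x: np.ndarray, p: float, dx: float = 1.0) -> np.ndarray:
    """Cubic smoothing spline with unit weights on an equispaced grid.

    Minimizes ``p·Σ|x(n) - f(n)|² + (1-p)·∫|f''|² dt`` with natural end
    conditions; p = 1 interpolates, p = 0 gives the least-squares line.
    ``dx`` is the abscissa spacing: the curvature penalty carries units of
    the abscissa cubed, so a given ``p`` smooths much more strongly on a
    seconds grid (dx = 1/fs) than on the default sample-index grid
    (dx = 1). The correction stages use the sample grid; there the
    baseline-shift choice p = 1/fs³ corresponds to a roughness weight of
    about fs³, i.e. an effective smoothing bandwidth of roughly half a
    second, tight enough to track a sustained level change.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"smoothing spline needs at least 4 points, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"smoothing parameter p must lie in [0, 1], got {p}")
    t = np.arange(n, dtype=float) * dx
    if p == 1.0:
        return x.copy()
    if p == 0.0:
        return np.polyval(np.polyfit(t, x, 1), t)
    lam = (1.0 - p) / p
    if n == 4:
        # scipy's banded solver needs >= 5 points; solve the tiny
        # Reinsch system directly: f = x - lam*Q c, (R + lam*QᵀQ) c = Qᵀx
        q = np.zeros((n, n - 2))
        for j in range(n - 2):
            q[j : j + 3, j] = np.array([1.0, -2.0, 1.0]) / dx
        r = (dx / 6.0) * (
            4.0 * np.eye(n - 2) + np.eye(n - 2, k=1) + np.eye(n - 2, k=-1)
        )
        c = np.linalg.solve(r + lam * q.T @ q, q.T @ x)
        return x - lam * (q @ c)
    return make_smoothing_spline(t, x, lam=lam)(t)


def correct_severe(
    x, annotation: ArtifactAnnotation, p: float = 0.99
) -> np.ndarray:
    """Subtract a near-interpolating spline inside each severe segment.

    Samples outside severe segments are returned bit-identical. Segments
    shorter than 4 samples are flattened by direct subtraction (the
    interpolation limit of the spline).
    """
    values = x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)
    out = values.copy()
    for a, b in annotation.of(SEVERE):
        seg = values[a:b]
        fit = smoothing_spline(seg, p) if b - a >= 4 else seg
        out[a:b] = seg - fit
    return out


def remove_baseline_shift(
    x1, annotation: ArtifactAnnotation, fs: float
) -> np.ndarray:
    """Remove the level change within each baseline-shift segment.

    A heavily smoothed spline (p = 1/fs³) tracks the sustained level
    change; it is subtracted and the segment re-anchored by adding back the
    fitted value at the segment's first sample, so the corrected segment
    starts exactly where the input did. Samples outside the segments are
    unchanged.
    """
    values = x1.values if isinstance(x1, TimeSeries) else np.asarray(x1, dtype=float)
    out = values.copy()
    p = 1.0 / float(fs) ** 3
    for a, b in annotation.of(BASELINE_SHIFT):
        if b - a < 4:
            continue
        fit = smoothing_spline(values[a:b], p)
        out[a:b] = values[a:b] - fit + fit[0]
    return out


def estimate_sigma(coeffs) -> float:
    """Order-statistic estimate of the coefficient SD.

    All detail coefficients are concatenated and sorted ascending; the
    estimate is the absolute value of the entry at 1-based index
    round(0.1587·L) (clamped to [1, L]). For zero-mean Gaussian
    coefficients this targets the 15.87th percentile, which equals -σ.
    """
    if isinstance(coeffs, (list, tuple)):
        coeffs = (
            np.concatenate([np.ravel(c) for c in coeffs]) if coeffs else np.array([])
        )
    c = np.sort(np.ravel(np.asarray(coeffs, dtype=float)))
    ell = c.size
    if ell == 0:
        raise ValueError("cannot estimate sigma from empty coefficients")
    idx = min(max(int(round(0.1587 * ell)), 1), ell)
    return float(abs(c[idx - 1]))


def thresholds_from_alpha(alpha: float, sigma_hat: float) -> WaveletThresholds:
    """Dual thresholds from the two-sided tail probability alpha.

    ``u`` solves P(|Z| > u) = alpha for a standard normal Z, i.e.
    u = Φ⁻¹(1 - alpha/2); then w2 = u·σ̂ and w1 = 1.3·w2.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if sigma_hat < 0:
        raise ValueError("sigma_hat must be nonnegative")
    u = float(norm.isf(alpha / 2.0))
    w2 = u * sigma_hat
    return WaveletThresholds(alpha=alpha, u=u, sigma_hat=sigma_hat, w1=1.3 * w2, w2=w2)


def zero_outliers(
    details: list[np.ndarray], w1: float, w2: float
) -> list[np.ndarray]:
    """Dual-threshold coefficient zeroing, per level.

    Within each level, any coefficient with |w| > w1 triggers removal of
    the whole contiguous run of neighbors with |w| > w2 around it (the run
    ends at the first coefficient at or below w2). Coefficients between w2
    and w1 with no triggering neighbor are untouched. Approximation
    coefficients are never passed to this function.
    """
    if w1 < w2:
        raise ValueError(f"w1 ({w1}) must be >= w2 ({w2})")
    out = []
    for w in details:
        w = np.asarray(w, dtype=float)
        a = np.abs(w)
        trig = a > w1
        if not trig.any():
            out.append(w.copy())
            continue
        modified = w.copy()
        for s, e in runs_of(a > w2):
            if trig[s:e].any():
                modified[s:e] = 0.0
        out.append(modified)
    return out


def default_level(
    n: int, fs: float, wavelet: str, band_upper_hz: float = 0.04
) -> int:
    """Decomposition depth whose approximation band keeps the hemodynamic band.

    The approximation after M levels covers 0 .. fs/2^(M+1); the depth is
    the largest M with fs/2^(M+1) >= band_upper_hz, capped by the maximum
    depth the signal length and filter length permit.
    """
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if max_level < 1:
        raise ValueError(
            f"signal of length {n} too short for one '{wavelet}' level"
        )
    by_band = int(math.floor(math.log2(fs / (2.0 * band_upper_hz))))
    return max(1, min(by_band, max_level))


def dual_threshold_denoise(
    x2,
    fs: float | None = None,
    wavelet: str = "db4",
    K: int = 16,
    alpha: float = 0.05,
    level: int | None = None,
    band_upper_hz: float = 0.04,
    thresholds: WaveletThresholds | None = None,
) -> np.ndarray:
    """Dual-threshold wavelet denoising with cyclic averaging.

    For each shift h = 1..K the signal is circularly shifted, decomposed
    (symmetric boundary extension), the coefficient SD estimated globally
    over all detail levels, outlier runs zeroed with the dual-threshold
    rule, reconstructed and unshifted; the K reconstructions are averaged
    to suppress shift-variant (pseudo-Gibbs) artifacts.

    ``thresholds`` overrides the per-shift estimate (useful to disable
    zeroing entirely and verify perfect reconstruction).

    The signal is reflect-padded before the circular shifts. Without the
    padding, a record whose start and end sit at different levels (the
    usual situation after baseline-shift removal, which leaves a residual
    offset) acquires a fabricated interior jump at the wrap point, and
    zeroing its coefficients corrupts both record ends.
    """
    if isinstance(x2, TimeSeries):
        fs = x2.fs
        values = x2.values
    else:
        values = np.asarray(x2, dtype=float)
    if fs is None:
        raise TypeError("fs is required when the input is a bare array")
    if K < 1:
        raise ValueError("K must be a positive integer")
    n = values.size
    lvl = level if level is not None else default_level(n, fs, wavelet, band_upper_hz)
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if max_level < 1:
        raise ValueError(f"signal of length {n} too short for one '{wavelet}' level")
    lvl = min(lvl, max_level)
    # pad far enough that the wrap point is outside the reconstruction
    # support of any zeroed coefficient at the deepest level
    filt_len = pywt.Wavelet(wavelet).dec_len
    pad = min(n - 1, max(K, (filt_len - 1) * 2**lvl + K))
    padded = np.pad(values, pad, mode="reflect")
    m = padded.size
    acc = np.zeros(n)
    for h in range(1, K + 1):
        shifted = np.roll(padded, h)
        coeffs = pywt.wavedec(shifted, wavelet, mode="symmetric", level=lvl)
        details = coeffs[1:]
        th = thresholds or thresholds_from_alpha(alpha, estimate_sigma(details))
        rec = pywt.waverec(
            [coeffs[0], *zero_outliers(details, th.w1, th.w2)],
            wavelet,
            mode="symmetric",
        )
        acc += np.roll(rec[:m], -h)[pad : pad + n]
    return acc / K


def highpass(x, fs: float | None = None, cutoff: float = 0.003) -> np.ndarray:
    """Zero-phase order-3 Butterworth high-pass (forward-backward)."""
    if isinstance(x, TimeSeries):
        fs = x.fs
        values = x.values
    else:
        values = np.asarray(x, dtype=float)
    if fs is None:
        raise TypeError("fs is required when the input is a bare array")
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz not in (0, {fs / 2}) Hz")
    sos = butter(3, cutoff, btype="highpass", fs=fs, output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1), values.size - 1)
    return sosfiltfilt(sos, values, padlen=padlen)


@dataclass
class PipelineResult:
    """All intermediate stages of the correction pipeline.

    ``x1``: after severe-oscillation correction; ``x2``: after
    baseline-shift removal; ``x3``: after wavelet denoising; ``y``: after
    the final high-pass.
    """

    annotation: ArtifactAnnotation
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    y: np.ndarray


def correct_pipeline(
    x: TimeSeries, config: RunConfig | None = None
) -> PipelineResult:
    """Detect artifacts and run the full correction chain x → x1 → x2 → x3 → y."""
    cfg = config or RunConfig()
    cfg.check_against_fs(x.fs)
    annotation = detect(x, strategy="fnirs", config=cfg)
    x1 = correct_severe(x.values, annotation, p=cfg.p_severe)
    x2 = remove_baseline_shift(x1, annotation, x.fs)
    x3 = dual_threshold_denoise(
        x2,
        fs=x.fs,
        wavelet=cfg.mother_wavelet,
        K=cfg.K,
        alpha=cfg.alpha,
        level=cfg.wavelet_level,
        band_upper_hz=cfg.band_upper_hz,
    )
    y = highpass(x3, x.fs, cfg.hp_final_hz)
    return PipelineResult(annotation=annotation, x1=x1, x2=x2, x3=x3, y=y)
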