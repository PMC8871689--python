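"""Synthetic fNIRS-like signals with injected motion artifacts.

The generator emulates the semi-simulated evaluation design: a clean
band-limited hemodynamic signal (0.003–0.04 Hz, unit SD) plus a small
white measurement-noise floor, contaminated by three artifact classes
with known ground truth:

* spikes — Gaussian-windowed 1–3 Hz bursts (rapid head shaking);
* slow oscillations — Hann-windowed 0.06–0.12 Hz excursions (slow head
  rotation);
* baseline shifts — smoothed steps (1 s rise) co-located with a slow
  oscillation and sustained to the end of the record (head position
  change).

Amplitudes are expressed in multiples of the clean signal's SD. Injection
is purely additive, so ``noised - clean`` is exactly the injected noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import (
    BASELINE_SHIFT,
    SEVERE,
    SLIGHT,
    ArtifactAnnotation,
    ArtifactSegment,
)
from .timeseries import TimeSeries

#: slow oscillations at or above this amplitude (in SD multiples) are
#: labeled severe in the ground truth, mirroring the 6×SD range criterion
SEVERE_SLOW_AMP = 6.0


@dataclass
class ArtifactSpec:
    """Counts, amplitudes and durations of the injected artifacts.

    Amplitudes are multiples of the clean signal's SD; durations are in
    seconds. ``n_bs`` baseline shifts are attached to slow-oscillation
    events (first) and then spikes, so ``n_bs <= n_slow + n_spikes``.
    """

    n_spikes: int = 4
    n_slow: int = 3
    n_bs: int = 2
    spike_amp: float = 10.0
    slow_amp: float = 2.0
    bs_height: float = 8.0
    spike_width_s: float = 2.0
    slow_width_s: float = 20.0
    min_gap_s: float = 60.0
    bs_rise_s: float = 1.0
    edge_margin_s: float = 10.0

    def __post_init__(self) -> None:
        if min(self.n_spikes, self.n_slow, self.n_bs) < 0:
            raise ValueError("artifact counts must be nonnegative")
        if min(self.spike_amp, self.slow_amp, self.bs_height) < 0:
            raise ValueError("artifact amplitudes must be nonnegative")
        if min(self.spike_width_s, self.slow_width_s, self.bs_rise_s) <= 0:
            raise ValueError("artifact durations must be positive")
        if self.n_bs > self.n_slow + self.n_spikes:
            raise ValueError("n_bs cannot exceed the number of oscillation events")


@dataclass
class SyntheticDataset:
    """One simulated segment: clean and noised signals plus ground truth."""

    clean: TimeSeries
    noised: TimeSeries
    truth: ArtifactAnnotation
    seed: int | None = None

    @property
    def noise(self) -> np.ndarray:
        """The injected noise, exactly (injection is additive)."""
        return self.noised.values - self.clean.values


def generate_clean(
    duration_s: float,
    fs: float = 10.0,
    seed: int | None = None,
    band: tuple[float, float] = (0.003, 0.04),
    measurement_noise_sd: float = 0.05,
    cardiac_amp: float = 0.0,
    cardiac_hz: float = 1.0,
    resp_amp: float = 0.0,
    resp_hz: float = 0.3,
) -> TimeSeries:
    """Band-limited Gaussian hemodynamic signal, unit SD, zero mean.

    White Gaussian noise is spectrally masked to the requested band and
    renormalized. A small white measurement-noise floor (default 0.05 SD,
    emulating instrument/shot noise) and optional cardiac/respiratory
    sinusoids can be added on top. Reproducible from ``seed``.
    """
    n = int(round(duration_s * fs))
    if n < 100:
        raise ValueError(f"duration too short: {n} samples (need >= 100)")
    rng = np.random.default_rng(seed)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no FFT bins at n={n}, fs={fs}")
    x = np.fft.irfft(spectrum * mask, n)
    x = (x - x.mean()) / x.std()
    if measurement_noise_sd > 0:
        x = x + measurement_noise_sd * rng.standard_normal(n)
    t = np.arange(n) / fs
    if cardiac_amp > 0:
        x = x + cardiac_amp * np.sin(2 * np.pi * cardiac_hz * t + rng.uniform(0, 2 * np.pi))
    if resp_amp > 0:
        x = x + resp_amp * np.sin(2 * np.pi * resp_hz * t + rng.uniform(0, 2 * np.pi))
    return TimeSeries(values=x, fs=fs, label="clean", kind="hemoglobin")


def _place_events(
    duration_s: float,
    widths_s: list[float],
    spec: ArtifactSpec,
    rng: np.random.Generator,
) -> list[float]:
    """Event start times (seconds) with min_gap spacing and edge margins."""
    m = len(widths_s)
    if m == 0:
        return []
    occupied = (
        2 * spec.edge_margin_s + sum(widths_s) + (m - 1) * spec.min_gap_s
    )
    slack = duration_s - occupied
    if slack < 0:
        raise ValueError(
            f"artifact spec infeasible: events need {occupied:.1f} s but the "
            f"record lasts {duration_s:.1f} s"
        )
    extra = rng.random(m + 1)
    extra = slack * extra / extra.sum()
    starts = []
    cursor = spec.edge_margin_s + extra[0]
    for i, w in enumerate(widths_s):
        starts.append(cursor)
        cursor += w + spec.min_gap_s + extra[i + 1]
    return starts


def _smoothstep(t: np.ndarray, t0: float, rise: float) -> np.ndarray:
    u = np.clip((t - t0) / rise, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def inject_artifacts(
    clean: TimeSeries,
    spec: ArtifactSpec | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Add spikes, slow oscillations and baseline shifts to a clean signal."""
    spec = spec or ArtifactSpec()
    rng = np.random.default_rng(seed)
    fs = clean.fs
    n = len(clean)
    t = clean.times
    sd = float(clean.values.std())
    if sd == 0:
        raise ValueError("clean signal must not be constant")

    events: list[tuple[str, float]] = [
        ("spike", spec.spike_width_s)
    ] * spec.n_spikes + [("slow", spec.slow_width_s)] * spec.n_slow
    rng.shuffle(events)
    starts = _place_events(clean.duration_s, [w for _, w in events], spec, rng)

    noise = np.zeros(n)
    segments: list[ArtifactSegment] = []
    slow_hosts: list[tuple[int, int]] = []
    spike_hosts: list[tuple[int, int]] = []
    for (etype, width_s), start_s in zip(events, starts):
        a = int(round(start_s * fs))
        b = min(int(round((start_s + width_s) * fs)), n)
        tt = np.arange(b - a) / fs
        center = ((b - a - 1) // 2) / fs  # on the sample grid
        if etype == "spike":
            fc = rng.uniform(1.0, 3.0)
            envelope = np.exp(-0.5 * ((tt - center) / (width_s / 6.0)) ** 2)
            # carrier peaks exactly at the envelope maximum, so the spike
            # peak amplitude equals spike_amp * sd
            phase = np.pi / 2 - 2 * np.pi * fc * center
            noise[a:b] += (
                spec.spike_amp * sd * envelope * np.sin(2 * np.pi * fc * tt + phase)
            )
            segments.append(ArtifactSegment(a, b, SEVERE))
            spike_hosts.append((a, b))
        else:
            fc = rng.uniform(0.06, 0.12)
            envelope = 0.5 * (1 - np.cos(2 * np.pi * tt / (tt[-1] if tt[-1] > 0 else 1)))
            phase = rng.uniform(0, 2 * np.pi)
            noise[a:b] += (
                spec.slow_amp * sd * envelope * np.sin(2 * np.pi * fc * tt + phase)
            )
            category = SEVERE if spec.slow_amp >= SEVERE_SLOW_AMP else SLIGHT
            segments.append(ArtifactSegment(a, b, category))
            slow_hosts.append((a, b))

    if spec.n_bs > 0:
        # slow head rotation produces the lasting level change, so slow
        # oscillations host the steps; spikes only if slow events run out
        if spec.n_bs > len(slow_hosts) + len(spike_hosts):
            raise ValueError("not enough oscillation events to host baseline shifts")
        if spec.n_bs <= len(slow_hosts):
            pool = slow_hosts
        else:
            pool = slow_hosts + spike_hosts
        chosen = rng.choice(len(pool), size=spec.n_bs, replace=False)
        for idx in sorted(chosen):
            a, b = pool[idx]
            t0 = (a + b) / 2.0 / fs  # rise centered in the host event
            height = spec.bs_height * sd * rng.choice((-1.0, 1.0))
            noise += height * _smoothstep(t, t0, spec.bs_rise_s)
            segments.append(ArtifactSegment(a, b, BASELINE_SHIFT))

    truth = ArtifactAnnotation(segments=segments, n_samples=n).validate()
    noised = clean.copy_with(clean.values + noise, label="noised")
    return SyntheticDataset(clean=clean, noised=noised, truth=truth, seed=seed)


def make_benchmark(
    n_segments: int = 20,
    duration_s: float = 600.0,
    fs: float = 10.0,
    spec: ArtifactSpec | None = None,
    seed: int | None = None,
) -> list[SyntheticDataset]:
    """Independent simulated segments with per-segment derived seeds.

    The default (20 segments of 600 s at 10 Hz) is the package's
    desk-scale benchmark configuration.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    states = np.random.SeedSequence(seed).generate_state(2 * n_segments)
    datasets = []
    for i in range(n_segments):
        clean = generate_clean(duration_s, fs, seed=int(states[2 * i]))
        datasets.append(
            inject_artifacts(clean, spec, seed=int(states[2 * i + 1]))
        )
    return datasets
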