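# nirsclean

Hybrid motion-artifact detection and correction for functional
near-infrared spectroscopy (fNIRS) time series.

Long fNIRS recordings — sleep monitoring, bedside neuromonitoring — are
riddled with motion artifacts: rapid head movement produces large
high-frequency **severe oscillations**, gentle movement produces **slight
oscillations**, and optode displacement leaves lasting **baseline shifts
(BS)**. No single correction handles all three well: wavelet filtering
removes spikes but not level shifts, spline interpolation removes level
shifts but not spikes. `nirsclean` detects each artifact class from the
fNIRS signal itself and corrects each with the tool suited to it.

## Method

**Detection.** The two-sided moving SD
`t(n) = SD(x[n−k…n+k])`, `k = 3·fs`, is compared against a dynamic
threshold `A(n)` built from its own 30/50/70% quantiles `T1,T2,T3`
(clip to `[T1,T3]`, zero-phase 0.02 Hz filter, floor at `T2`, add
`3(T3−T1)`):

```
t > 2A   suspected severe oscillation
A < t ≤ 2A   slight oscillation
t ≤ A    none
```

Suspected severe runs are confirmed peak-by-peak (range ≥ 6×SD of the
region), and an oscillation run whose ≥5 s quiet flanks differ in mean by
more than half the run's range is marked as a baseline shift. A 3-axis
accelerometer strategy (`sqrt((ax²+ay²+az²)/3)` with threshold
`B = 2·clip(d, T/2, T)`) is included for comparison.

**Correction.** Severe segments: subtract a cubic smoothing spline
(`p = 0.99`) minimizing `p·Σ(x−f)² + (1−p)·∫(f″)²`. BS segments: subtract
a heavily smoothed spline (`p = 1/fs³`) and re-anchor to the segment's
starting level. The whole record then passes a dual-threshold wavelet
denoiser: with σ̂ the 15.87th-percentile order statistic of all detail
coefficients and `u = Φ⁻¹(1−α/2)`, coefficients above `w1 = 1.3·u·σ̂`
trigger zeroing of the contiguous run of neighbors above `w2 = u·σ̂`,
averaged over K = 16 circular shifts (cycle spinning). A zero-phase
0.003 Hz high-pass finishes.

**Evaluation.** Against a known clean reference `x`,
`SNR = 10·log10(Σx²/Σ(z−x)²)` and Pearson's R; a benchmark harness scores
the pipeline against single-threshold wavelet, median-filter and
spline-only comparators on simulated segments with ground-truth
annotations.

ΔOD inputs are converted to Δ[HbO2]/Δ[Hb] by the modified Beer–Lambert
law; coefficients for 735/850 nm ship as defaults and
`coefficients_from_extinction` derives them for other wavelength pairs.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a 10-minute contaminated segment, correct it, and score the
result:

```bash
$ nirsclean simulate --duration 600 --seed 1 --out-dir .
simulated 6000 samples at 10.0 Hz (9 truth segments) -> .

$ nirsclean correct --input noised.csv --fs 10 \
    --out corrected.csv --annotation-out detected.csv
segments: {"severe": 4, "slight": 13, "baseline_shift": 2}; corrected -> corrected.csv

$ nirsclean evaluate --clean clean.csv --noised noised.csv \
    --processed corrected.csv --fs 10
{
 "method": "external",
 "snr_noised": -16.806408307500128,
 "snr_processed": -5.089061938466251,
 "r_noised": 0.2756421615980203,
 "r": 0.509686404193957
}
```

The simulated segment contains 4 injected spikes, 3 slow oscillations and
2 baseline shifts. Detection recovered all 4 spikes as severe and both
baseline shifts; correction raised the SNR against the clean reference by
11.7 dB and nearly doubled the correlation with it. The same operations
are available as library calls:

```python
import nirsclean as nc

clean = nc.generate_clean(duration_s=600, fs=10, seed=1)
ds = nc.inject_artifacts(clean, seed=1)
result = nc.correct_pipeline(ds.noised)       # annotation, x1, x2, x3, y
print(nc.snr(clean.values, result.y), nc.pearson_r(clean.values, result.y))
```

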