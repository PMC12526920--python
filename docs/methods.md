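# Methods

## Signal model and conditioning

All analysis operates on single-lead ECG amplitude series. Recordings are
conditioned in a fixed order — downsample → z-score → cap → segment —
chosen to mirror the narrative order in which the constants are usually
stated for this kind of study:

1. **Downsampling to 125 Hz.** The raw digitization rate (500 Hz in the
   simulator) must be an integer multiple of the target; non-integer ratios
   are an error rather than a silent rational resampling. The anti-alias
   filter is a linear-phase FIR (`20·q + 1` taps, cutoff `0.45 ·
   target_fs` = 56.25 Hz) applied by centered convolution over a
   reflect-padded signal, so there is no group delay: a constant maps to
   itself and peak positions do not move.
2. **Z-score standardization** over the whole recording (population
   standard deviation), not per section: the ±8 saturation rule below is
   defined on whole-recording z-units. A constant recording is an error.
3. **Saturation capping at ±8 z-units.** Amplitudes beyond ±8 are treated
   as amplifier-saturation spikes and clamped. The operation is idempotent
   and touches nothing within the threshold.
4. **Segmentation into 35 non-overlapping 15-s sections**, starting at
   sample 0, trailing remainder discarded.

A strided moving-average baseline remover (trend over a centered 125-sample
window evaluated every 31 samples, linearly interpolated and subtracted) is
provided **for visualization only**; it never feeds the RR or SQI paths.

## Frequency-domain RR estimator

The estimator measures one RR duration per section (or per whole signal)
without detecting individual beats:

1. band-pass to the 5–15 Hz QRS band by spectral masking: forward real FFT,
   bins outside the band zeroed, inverse FFT (idempotent, linear, exactly
   real);
2. symmetric clip at the 95th percentile of absolute amplitude — residual
   saturation energy is tamed without flattening QRS complexes. The clip is
   applied to |x| with symmetric saturation (a signed-percentile variant
   would be asymmetric for the near-zero-mean z-scored sections);
3. first difference, then elementwise squaring;
4. centered moving average, window 19, advancing 10 samples per output
   point. The first output is centered at sample 9 (0-based) of the squared
   difference series and windows reaching past either end are dropped, so
   an N-sample input yields `⌊(N−1−19)/10⌋+1` envelope points at an exact
   effective rate f_s/10 = 12.5 Hz. The decimated-envelope convention (vs.
   computing every 10th point of a full-rate average and holding it) is
   used because the subsequent spectrum needs a well-defined sampling rate.

The envelope is periodic at the heart rate. Its magnitude spectrum is
zero-padded and the largest peak inside the cardiac search band
**[0.833, 1.833] Hz** (resting heart rates of 50–110 bpm) gives
RR = 1/f_peak.

Numerical choices in the peak search:

- **Zero-padding** to a bin spacing of at most 0.005 Hz (configurable). A
  raw 15-s envelope has ~0.067 Hz bins — more than 3 % RR quantization at
  60 bpm, too coarse to report sub-percent errors.
- **At least 8× oversampling of the intrinsic resolution.** On long signals
  the cardiac spectral lines are about one intrinsic bin (1/T) wide. If the
  padded grid samples such a line near its edge, scalloping can lose up to
  ~36 % of its magnitude, enough to demote an off-bin fundamental below a
  near-on-bin harmonic (both the fundamental and its second harmonic lie in
  the search band for heart rates below 55 bpm). Padding to ≥ 8× the
  envelope length bounds the scalloping loss at < 1 % and preserves the
  ranking.
- **Tie-break toward the lowest in-band frequency**, favoring the cardiac
  fundamental over harmonics. Exact float ties are fragile, so magnitudes
  within 1e-9 (relative) of the band maximum count as tied.
- A band with no spectral content at all is an error ("no cardiac
  content"), not a silent zero.

The estimator is invariant to positive amplitude scaling, and on noiseless
constant-HR synthetic sections it recovers RR within 1 % at every heart
rate from 50 to 110 bpm (verified per 5 bpm step in the suite; the residual
error is grid quantization, ≈ 0.2 %).

## Pan–Tompkins baseline

The time-domain reference detector follows the classic recipe: 5–15 Hz
band-pass (2nd-order Butterworth, applied forward-backward so detections do
not shift), five-point derivative, squaring, 150-ms moving-window
integration, adaptive signal/noise levels (running 0.125/0.875 updates,
threshold = noise + 0.25·(signal − noise)), a search-back pass at half
threshold when more than 1.66 mean-RR elapses without a beat, and a 200-ms
refractory period. Detections are refined to the local maximum of the
band-passed signal within ±100 ms. Integration window, refractory and
update coefficients are exposed in `RunConfig`. The whole-signal RR is the
mean peak-to-peak interval.

## Signal quality index

SQI = Σ power in 5–15 Hz / Σ power elsewhere, from the magnitude-squared
real FFT of the unwindowed section (no taper). Conventions: the DC bin is
excluded from both sums (sections are z-scored and near-zero-mean); band
edges are inclusive in the numerator; out-of-band power below 1e-12 of the
total is treated as exactly zero and reported as an infinite sentinel (a
pure in-band tone leaves only float dust outside the band). An all-zero
section is an error. The recording-level SQI is the arithmetic mean of its
35 section values; an infinite section propagates to an infinite mean. The
index is invariant to amplitude scaling and decreases monotonically in
added out-of-band noise power.

## Error and agreement statistics

- ERR = RR_reference − RR_textile (seconds). ERP = 100·|ERR|/RR_reference.
  ERP is **absolute-valued by design**: the coverage bins start at 0 and a
  mean ERP must remain positive even when the signed bias is negative.
- Error coverage rates over [0,5], ]5,10], ]10,15], ]15,20], ]20,∞[ percent
  — the first bin closed, later bins left-open/right-closed, so every value
  lands in exactly one bin and the rates sum to 100.
- Bland–Altman: bias = mean difference, limits at bias ± 1.96 sample
  standard deviations (ddof = 1, as for all printed-style summaries here).
- Linear regression and Pearson correlation via ordinary least squares.
- Paired binomial sign test, exact and two-sided: ties excluded, and with k
  positive among n non-zero differences, p = min(1, 2·min(P(X≤k), P(X≥k)))
  for X ~ Binomial(n, ½). The suite checks this against exhaustive
  enumeration of all 2ⁿ sign patterns for n ≤ 12. All-zero differences
  yield p = 1 with an explicit flag. No direction is assumed and no
  multiple-testing correction is applied across a comparison family.
- Group comparisons pair section-level SQI values by (subject, section) —
  the same person in the same timeframe — and report per-group
  median/mean/std/range/N plus the pairwise sign-test p values.

## Synthetic data generator

The generator emulates the study conditions end to end: ~525-s paired
recordings (reference + capacitive) digitized at 500 Hz, with shared
ground-truth R-peak times.

- **Beat timing**: i.i.d. truncated-normal RR intervals. Mean 60/HR s; the
  per-beat spread maps from a heart-rate sd by the delta method
  (σ_RR = 60·σ_HR/HR²); truncation at the RR equivalents of the heart-rate
  bounds (50–110 bpm by default, hard physiological limits 20–220 bpm).
  The i.i.d. model reflects a resting/monotonous protocol; no
  autocorrelated heart-rate-variability structure is modeled, and a hook
  accepts a user-supplied RR series where that matters. The first beat
  falls 0.5 s after recording start. A dataset-level option draws each
  recording's constant heart rate uniformly within the bounds.
- **Morphology**: one Gaussian bump per wave (P, Q, R, S, T) with
  amplitudes 0.15/−0.12/1.0/−0.25/0.35 z-units, widths 20/8/10/8/60 ms and
  offsets −200/−25/0/+25/+300 ms from the R peak. Only R-peak timing
  matters downstream; the template is deliberately simple and the R
  amplitude is required to dominate strictly.
- **Degradation** (capacitive channel): baseline-wander sinusoid
  (default 0.2 Hz, random phase), additive white Gaussian noise,
  Poisson-placed ±spike_amp saturation spikes uniform within each 15-s
  span (single raw sample by default; a width parameter models longer
  saturation plateaus), optional powerline tone (off by default — the
  acquisition front end is assumed to low-pass below the mains frequency).
  The *moderate* preset — wander amplitude 1 z-unit at 0.2 Hz, broadband
  sd 0.5 z-units, one ±20 z-unit spike per section — is the stated noisy
  study condition used in the robustness experiment.
- Determinism: all randomness flows from one integer seed; per-recording
  seeds derive from the master seed, so a dataset is bit-identical across
  runs.

What the generator does **not** emulate: electrode-coupling physics and
motion biomechanics, realistic beat-morphology variation, autocorrelated
HRV, transient motion artifacts with QRS-band-overlapping spectra, and
non-stationary noise levels. Passing tests therefore demonstrate
correctness of the algorithms under the stated noise phenomenology, not
clinical performance on real capacitive recordings. In particular, the
synthetic capacitive channel's SQI values depend directly on the chosen
noise amplitudes and are not calibrated to reproduce any observed SQI
distribution.

## Experiment sizes

The packaged experiments use 70 clean recordings of 525 s for the
method-agreement run and 20 paired recordings (700 sections) for the
moderate-noise robustness run — large enough for stable means while staying
comfortable on a single CPU (the full acceptance run completes in well
under a minute).

## Known limitations

- The spectral estimator reports one RR per section; it cannot resolve
  beat-to-beat variability (SDNN/RMSSD are out of scope).
- For heart rates below ~55 bpm the second harmonic of the envelope also
  falls inside the search band; heavy in-band noise can then pull the peak
  to the harmonic, halving the reported RR. This is the dominant failure
  mode in the noisy-section experiment and concentrates at low SQI.
- The Pan–Tompkins implementation is offline (zero-phase filtering); it is
  not a sample-by-sample real-time port.
- File I/O supports the package's own delimited-text + YAML sidecar format
  only; no physiological container formats are read or written.
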