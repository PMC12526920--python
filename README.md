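# cecgkit

Analysis toolkit for **capacitive ECG** (cECG) — cardiac signals sensed
through clothing by capacitively coupled textile electrodes, e.g. woven into
a car-seat back for unobtrusive driver monitoring. Capacitive channels are
far noisier than adhesive Ag-AgCl reference electrodes (rECG): baseline
wander from coupling changes, broadband noise, and high-amplitude
amplifier-saturation spikes. `cecgkit` implements the signal-processing and
statistical chain needed to characterize such recordings:

- a **frequency-domain RR-duration estimator** that never locates individual
  beats: band-pass the signal to the QRS band (5–15 Hz), clip at the 95th
  percentile, differentiate, square, and smooth into a beat-energy envelope
  at f_s/10; the RR duration is the reciprocal of the dominant envelope
  spectral peak inside the cardiac band [0.833, 1.833] Hz (50–110 bpm),
- a classic **Pan–Tompkins QRS detector** (band-pass, derivative, squaring,
  150-ms moving-window integration, adaptive thresholds with search-back,
  200-ms refractory) as the time-domain gold standard,
- a **signal quality index** SQI = P(5–15 Hz) / P(rest of spectrum),
  computed on 35 non-overlapping 15-s sections per recording and averaged,
- **agreement statistics**: ERR = RR_ref − RR_textile, ERP = 100·|ERR|/RR_ref,
  error coverage rates over the bins [0,5], ]5,10], ]10,15], ]15,20],
  ]20,∞[ %, Bland–Altman bias ± 1.96 σ limits, linear regression/Pearson
  correlation, and the exact two-sided paired binomial sign test used for
  every group comparison,
- a **synthetic paired-recording simulator** (clean reference + degraded
  capacitive channel, shared ground-truth R-peak times) so the whole chain
  is testable without access to any clinical recording.

Raw recordings are conditioned before analysis: downsampled to 125 Hz with a
linear-phase anti-alias FIR, z-scored over the whole recording, and clamped
at ±8 z-units (amplitudes beyond ±8 are treated as amplifier saturation).

## Worked example

```python
import numpy as np
import cecgkit as ck

# one paired 525-s recording at a constant 72 bpm with moderate noise
spec = ck.RRSeriesSpec(mean_hr=72, hr_sd=0, duration=525)
(pair,) = ck.gen_paired_dataset(1, spec, noise=ck.NoiseSpec.moderate(), seed=1)

cap = ck.ensure_preprocessed(pair.capacitive)
table = ck.analyze_sections(cap)                     # 35 x 15-s sections
rr_whole = ck.analyze_whole(pair.reference)

print(f"truth RR           : {pair.truth.mean_rr:.4f} s")
print(f"whole-signal FFT RR: {rr_whole['fft']:.4f} s (reference channel)")
print(f"whole-signal PT  RR: {rr_whole['pt']:.4f} s (reference channel)")
erp = [ck.rr_errors(pair.truth.mean_rr, rr).erp for rr in table.rr_fft]
print(f"capacitive sections: mean ERP {np.mean(erp):.2f} %, "
      f"median SQI {table.sqi.median():.2f}")
cov = ck.coverage_rates(erp)
print("coverage [0,5] ]5,10] ]10,15] ]15,20] ]20,inf[:",
      " ".join(f"{r:.1f}" for r in cov.rates))
```

prints

```
truth RR           : 0.8333 s
whole-signal FFT RR: 0.8333 s (reference channel)
whole-signal PT  RR: 0.8333 s (reference channel)
capacitive sections: mean ERP 0.31 %, median SQI 0.04
coverage [0,5] ]5,10] ]10,15] ]15,20] ]20,inf[: 100.0 0.0 0.0 0.0 0.0
```

At 72 bpm the true RR is 60/72 = 0.8333 s; both estimators recover it
exactly on the clean reference channel. On the degraded capacitive channel
every 15-s section stays within 5 % error even though its signal quality
index is very low — RR accuracy of the spectral method is largely
independent of SQI, because the estimator needs only the periodicity of the
QRS energy envelope, not clean beat shapes.

There is also a CLI (`cecgkit simulate | preprocess | analyze | compare |
report`); run `cecgkit --help` for the flags.

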