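"""Paired synthetic reference/capacitive ECG recordings with known R-peak truth.

The study conditions this generator emulates: ~525-s single-lead recordings,
digitized at 500 Hz, amplitudes later z-scored; a clean reference channel and
a capacitive channel degraded by baseline wander, broadband noise, and
high-amplitude saturation spikes exceeding |8| z-units.  Beat timing is an
i.i.d. truncated-normal RR series inside a resting heart-rate range
(50-110 bpm by default); morphology is a sum of Gaussian bumps per wave
(P, Q, R, S, T), a deliberately simple stand-in — only R-peak timing matters
downstream.

Every function is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .core import Recording

RAW_FS = 500.0  #: default raw digitization rate, Hz

HR_HARD_BOUNDS = (20.0, 220.0)  # physiological sanity limits on hr_bounds, bpm


@dataclass(frozen=True)
class RRSeriesSpec:
    """Beat-timing specification.

    ``mean_hr`` may be None, meaning: draw a constant per-recording heart rate
    uniformly within ``hr_bounds`` (used for multi-recording datasets).
    ``hr_sd`` = 0 gives metronomic beats.
    """

    mean_hr: float | None = 70.0      # bpm
    hr_sd: float = 0.0                # bpm
    hr_bounds: tuple[float, float] = (50.0, 110.0)
    duration: float = 525.0           # s

    def __post_init__(self) -> None:
        lo, hi = self.hr_bounds
        if not (HR_HARD_BOUNDS[0] <= lo < hi <= HR_HARD_BOUNDS[1]):
            raise ValueError(
                f"hr_bounds must satisfy {HR_HARD_BOUNDS[0]} <= lo < hi <= "
                f"{HR_HARD_BOUNDS[1]}, got {self.hr_bounds}"
            )
        if self.mean_hr is not None and not lo <= self.mean_hr <= hi:
            raise ValueError(
                f"mean_hr={self.mean_hr} outside hr_bounds={self.hr_bounds}"
            )
        if self.hr_sd < 0:
            raise ValueError("hr_sd must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class Wave:
    amplitude: float   # z-units
    width: float       # s (Gaussian sigma)
    offset: float      # s, relative to the R peak

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class ECGTemplate:
    """Per-wave Gaussian-bump beat morphology; R must dominate in |amplitude|."""

    waves: dict[str, Wave]

    def __post_init__(self) -> None:
        if "R" not in self.waves:
            raise ValueError("template must contain an R wave")
        r_amp = abs(self.waves["R"].amplitude)
        for name, w in self.waves.items():
            if name != "R" and abs(w.amplitude) >= r_amp:
                raise ValueError(
                    f"R amplitude must be strictly largest; {name} has "
                    f"|{w.amplitude}| >= |{r_amp}|"
                )

    @classmethod
    def default(cls) -> "ECGTemplate":
        return cls(waves={
            "P": Wave(0.15, 0.020, -0.200),
            "Q": Wave(-0.12, 0.008, -0.025),
            "R": Wave(1.00, 0.010, 0.000),
            "S": Wave(-0.25, 0.008, 0.025),
            "T": Wave(0.35, 0.060, 0.300),
        })


@dataclass(frozen=True)
class NoiseSpec:
    """Capacitive-channel degradation parameters (all amplitudes in z-units).

    ``spike_rate`` is the expected number of saturation spikes per 15-s
    section; spikes are ±``spike_amp`` plateaus of ``spike_width`` seconds
    (0 → a single raw sample) placed uniformly within each section span.
    """

    baseline_wander_amp: float = 0.0
    baseline_wander_freq: float = 0.2    # Hz, must stay < 0.5
    broadband_sd: float = 0.0
    spike_rate: float = 0.0              # spikes per 15-s section
    spike_amp: float = 20.0              # z-units, must exceed 8 if used
    spike_width: float = 0.0             # s; 0 -> one raw sample
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0         # Hz

    def __post_init__(self) -> None:
        for name in ("baseline_wander_amp", "broadband_sd", "spike_rate",
                     "spike_amp", "spike_width", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.baseline_wander_freq < 0.5:
            raise ValueError("baseline_wander_freq must be in (0, 0.5) Hz")
        if self.spike_rate > 0 and self.spike_amp <= 8:
            raise ValueError("spike_amp must exceed 8 z-units when spikes are placed")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls()

    @classmethod
    def moderate(cls) -> "NoiseSpec":
        """Moderate capacitive-channel noise: 1 z-unit wander at 0.2 Hz,
        0.5 z-unit broadband noise, one ±20 z-unit spike per section."""
        return cls(baseline_wander_amp=1.0, baseline_wander_freq=0.2,
                   broadband_sd=0.5, spike_rate=1.0, spike_amp=20.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth attached to a generated recording."""

    r_peak_times: np.ndarray           # s, sorted
    rr_series: np.ndarray              # s, successive differences
    noise: NoiseSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_peak_times",
                           np.asarray(self.r_peak_times, dtype=float))
        object.__setattr__(self, "rr_series",
                           np.asarray(self.rr_series, dtype=float))
        t = self.r_peak_times
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")
        if t.size >= 2 and not np.allclose(np.diff(t), self.rr_series):
            raise ValueError("rr_series inconsistent with r_peak_times")

    @property
    def mean_rr(self) -> float:
        return float(np.mean(self.rr_series))

    def with_noise(self, noise: NoiseSpec) -> "SyntheticTruth":
        return SyntheticTruth(self.r_peak_times, self.rr_series, noise, self.seed)


class PairedRecording(NamedTuple):
    reference: Recording
    capacitive: Recording
    truth: SyntheticTruth


def gen_rr_series(spec: RRSeriesSpec, seed: int,
                  first_peak_offset: float = 0.5) -> SyntheticTruth:
    """Draw an R-peak time series from a truncated-normal RR model.

    Intervals are i.i.d. truncated normal with mean 60/mean_hr seconds, a
    standard deviation mapped from ``hr_sd`` bpm by the delta method
    (sd_rr = 60·hr_sd/mean_hr²), and truncation at the RR equivalents of
    ``hr_bounds``.  Peaks start at ``first_peak_offset`` and stop at
    ``spec.duration``.
    """
    if spec.mean_hr is None:
        raise ValueError("gen_rr_series needs a concrete mean_hr "
                         "(RRSeriesSpec.mean_hr is None)")
    rng = np.random.default_rng(seed)
    mean_rr = 60.0 / spec.mean_hr
    n_max = int(np.ceil((spec.duration - first_peak_offset) / mean_rr * 1.5)) + 16
    if spec.hr_sd == 0:
        rr = np.full(n_max, mean_rr)
    else:
        sd_rr = 60.0 * spec.hr_sd / spec.mean_hr ** 2
        lo_rr = 60.0 / spec.hr_bounds[1]
        hi_rr = 60.0 / spec.hr_bounds[0]
        a, b = (lo_rr - mean_rr) / sd_rr, (hi_rr - mean_rr) / sd_rr
        rr = stats.truncnorm.rvs(a, b, loc=mean_rr, scale=sd_rr,
                                 size=n_max, random_state=rng)
    times = first_peak_offset + np.concatenate([[0.0], np.cumsum(rr)])
    times = times[times <= spec.duration]
    if times.size < 2:
        raise ValueError("duration too short for even two beats")
    return SyntheticTruth(r_peak_times=times, rr_series=np.diff(times), seed=seed)


def synth_clean_ecg(truth: SyntheticTruth, template: ECGTemplate | None = None,
                    fs: float = RAW_FS, duration: float | None = None) -> Recording:
    """Render a clean reference-channel ECG from R-peak times.

    Each beat is the sum of the template's Gaussian bumps centered at
    ``r_time + wave.offset``; waves are evaluated over ±5 sigma only.
    ``duration`` fixes the rendered length in seconds (default: last R peak
    plus 0.6 s).
    """
    if fs < 250:
        raise ValueError("raw generation requires fs >= 250 Hz")
    template = template or ECGTemplate.default()
    if duration is None:
        duration = (truth.r_peak_times[-1] + 0.6) if truth.r_peak_times.size else 1.0
    n = int(np.ceil(duration * fs))
    x = np.zeros(n)
    for wave in template.waves.values():
        half = int(np.ceil(5 * wave.width * fs))
        k = np.arange(-half, half + 1)
        for rt in truth.r_peak_times:
            c = int(round((rt + wave.offset) * fs))
            idx = c + k
            ok = (idx >= 0) & (idx < n)
            t_rel = idx[ok] / fs - (rt + wave.offset)
            x[idx[ok]] += wave.amplitude * np.exp(-0.5 * (t_rel / wave.width) ** 2)
    return Recording(x, fs=fs, channel_kind="reference",
                     meta={"synthetic": True, "seed": truth.seed,
                           "history": ["synth_clean_ecg"]})


def degrade_to_cecg(clean: Recording, noise: NoiseSpec, seed: int,
                    section_length: float = 15.0) -> Recording:
    """Add capacitive-channel artifacts to a clean recording.

    output = clean + wander sinusoid (random phase) + white Gaussian noise
    + Poisson-placed ±spike_amp saturation spikes (uniform within each
    ``section_length`` span) + optional powerline sinusoid.
    """
    rng = np.random.default_rng(seed)
    n, fs = clean.n_samples, clean.fs
    t = np.arange(n) / fs
    x = clean.samples.copy()
    if noise.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t + phase)
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + phase)
    if noise.broadband_sd > 0:
        x += rng.normal(0.0, noise.broadband_sd, size=n)
    if noise.spike_rate > 0:
        nper = int(round(section_length * fs))
        width = max(1, int(round(noise.spike_width * fs)))
        for start in range(0, n - nper + 1, nper):
            for _ in range(rng.poisson(noise.spike_rate)):
                pos = start + rng.integers(0, nper - width + 1)
                sign = rng.choice([-1.0, 1.0])
                x[pos:pos + width] += sign * noise.spike_amp
    return clean.replace(samples=x, channel_kind="capacitive",
                         extra_meta={"noise": noise, "noise_seed": seed},
                         history_entry="degrade_to_cecg")


def gen_paired_dataset(n_recordings: int,
                       rr_spec: RRSeriesSpec | None = None,
                       template: ECGTemplate | None = None,
                       noise: NoiseSpec | None = None,
                       seed: int = 0,
                       fs: float = RAW_FS,
                       rr_series_hook: Callable[[int], SyntheticTruth] | None = None,
                       ) -> list[PairedRecording]:
    """Generate paired (reference, capacitive) recordings sharing one truth.

    If ``rr_spec.mean_hr`` is None, each recording draws a constant heart
    rate uniformly within ``rr_spec.hr_bounds``.  ``rr_series_hook(i)`` may
    supply a custom RR truth per recording instead.  All per-recording seeds
    derive deterministically from ``seed``.
    """
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    rr_spec = rr_spec or RRSeriesSpec()
    noise = noise or NoiseSpec.moderate()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31, size=(n_recordings, 2))
    pairs: list[PairedRecording] = []
    for i in range(n_recordings):
        s_rr, s_noise = (int(v) for v in child_seeds[i])
        if rr_series_hook is not None:
            truth = rr_series_hook(i)
        elif rr_spec.mean_hr is None:
            hr = float(master.uniform(*rr_spec.hr_bounds))
            truth = gen_rr_series(
                RRSeriesSpec(hr, rr_spec.hr_sd, rr_spec.hr_bounds,
                             rr_spec.duration), seed=s_rr)
        else:
            truth = gen_rr_series(rr_spec, seed=s_rr)
        truth = truth.with_noise(noise)
        ref = synth_clean_ecg(truth, template, fs=fs,
                              duration=rr_spec.duration + 1.0)
        ref.meta["recording_index"] = i
        cap = degrade_to_cecg(ref, noise, seed=s_noise)
        pairs.append(PairedRecording(ref, cap, truth))
    return pairs
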