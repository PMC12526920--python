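"""Signal conditioning chain: downsample to 125 Hz, z-score, ±8 cap, segment.

The chain order is downsample → standardize → cap → segment.  The ±8 rule
targets amplifier-saturation spikes: after z-scoring, any amplitude beyond
±8 z-units is treated as saturation and clamped.  A strided moving-average
baseline remover is provided for visualization only — it never feeds the RR
or SQI paths.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import Recording, SectionSet


def downsample(rec: Recording, target_fs: float = 125.0,
               cutoff_frac: float = 0.45) -> Recording:
    """Anti-alias low-pass then decimate by an integer factor.

    The filter is a linear-phase FIR (``20*q + 1`` taps, cutoff
    ``cutoff_frac * target_fs``) applied with zero delay via centered
    convolution over a reflect-padded signal, so a constant stays constant
    and peak positions do not shift.

    Raises
    ------
    ValueError
        If ``rec.fs`` is not an integer multiple of ``target_fs`` — no
        rational-resampling dialect is silently applied.
    """
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"fs={rec.fs} Hz is not an integer multiple of target_fs={target_fs} Hz")
    if q == 1:
        return rec.replace(history_entry=f"downsample(noop, fs={rec.fs})")
    numtaps = 20 * q + 1
    h = signal.firwin(numtaps, cutoff_frac * target_fs, fs=rec.fs)
    pad = numtaps // 2
    xp = np.pad(rec.samples, pad, mode="reflect")
    y = signal.fftconvolve(xp, h, mode="same")[pad:-pad]
    return rec.replace(samples=y[::q], fs=target_fs,
                       history_entry=f"downsample({rec.fs}->{target_fs} Hz)")


def standardize(rec: Recording) -> Recording:
    """Z-score the whole recording: zero mean, unit population standard deviation."""
    mu = float(np.mean(rec.samples))
    sd = float(np.std(rec.samples))  # population convention (ddof=0)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant signal (zero variance)")
    return rec.replace(samples=(rec.samples - mu) / sd,
                       history_entry="standardize(z-score)")


def cap_spikes(rec: Recording, threshold: float = 8.0) -> Recording:
    """Clamp saturation spikes: every sample clipped to [-threshold, +threshold]."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return rec.replace(samples=np.clip(rec.samples, -threshold, threshold),
                       history_entry=f"cap_spikes(±{threshold})")


def segment(rec: Recording, section_length: float = 15.0,
            n_sections: int = 35) -> SectionSet:
    """Cut the first ``n_sections`` contiguous windows of ``section_length`` s.

    Windows start at sample 0; any trailing remainder is discarded.
    """
    nper = int(round(section_length * rec.fs))
    needed = n_sections * nper
    if rec.n_samples < needed:
        deficit = (needed - rec.n_samples) / rec.fs
        raise ValueError(
            f"recording too short for {n_sections} x {section_length}-s sections: "
            f"missing {deficit:.2f} s ({needed - rec.n_samples} samples)")
    sections = [rec.samples[i * nper:(i + 1) * nper] for i in range(n_sections)]
    starts = np.arange(n_sections) * nper
    return SectionSet(parent=rec, section_length=section_length,
                      sections=sections, starts=starts)


def remove_baseline(rec: Recording, window: int = 125, step: int = 31) -> Recording:
    """Subtract a strided moving-average trend (visualization only).

    The trend is the mean over a centered ``window``-sample box evaluated
    every ``step`` samples, linearly interpolated back to the full rate
    (edge values held), then subtracted.  Never used in the RR or SQI paths.
    """
    n = rec.n_samples
    if window >= n:
        raise ValueError(f"window ({window}) must be smaller than the signal ({n})")
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    css = np.concatenate([[0.0], np.cumsum(rec.samples)])
    half = window // 2
    centers = np.arange(half, n - (window - half) + 1, step)
    starts = centers - half
    trend_pts = (css[starts + window] - css[starts]) / window
    trend = np.interp(np.arange(n), centers, trend_pts)
    return rec.replace(samples=rec.samples - trend,
                       history_entry=f"remove_baseline(window={window}, step={step})")


def preprocess_recording(rec: Recording, target_fs: float = 125.0,
                         cap_threshold: float = 8.0) -> Recording:
    """Full conditioning chain: downsample → standardize → cap."""
    out = rec
    if rec.fs != target_fs:
        out = downsample(out, target_fs)
    out = standardize(out)
    return cap_spikes(out, cap_threshold)


def is_preprocessed(rec: Recording, target_fs: float = 125.0) -> bool:
    """Heuristic: at target rate with z-scored amplitudes already."""
    history = rec.meta.get("history", [])
    if any("standardize" in h for h in history) and rec.fs == target_fs:
        return True
    return False
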