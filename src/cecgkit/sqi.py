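"""QRS-band power-ratio signal quality index.

SQI = (power in the 5-15 Hz QRS band) / (power of the rest of the spectrum).
Computed on each 15-s section of a preprocessed recording; the 35 section
values average to one SQI per recording.  A clean adhesive-electrode signal
concentrates power near the QRS band and scores high (well above 1); a
noisy capacitive signal spreads power into wander and broadband noise and
scores low.  SQI = 1 marks equal power inside and outside the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SectionSet


@dataclass(frozen=True)
class SQIValue:
    """In-band to out-of-band power ratio (``inf`` when nothing is out of band)."""

    value: float
    scope: str | int = "section"     # section index or "recording"
    band: tuple[float, float] = (5.0, 15.0)

    def __post_init__(self) -> None:
        if not (self.value >= 0 or np.isinf(self.value)):
            raise ValueError("SQI must be >= 0")


def compute_sqi(x: np.ndarray, fs: float, lo: float = 5.0, hi: float = 15.0,
                scope: str | int = "section") -> SQIValue:
    """Power ratio of the [lo, hi] Hz band to the rest of the spectrum.

    One-sided power spectrum of the unwindowed series (no taper); the DC
    bin is excluded from both sums (sections are z-scored and near
    zero-mean anyway).  Band edges are inclusive in the numerator.  A zero
    out-of-band power yields ``inf``; an all-zero input is an error rather
    than 0/0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.any(x != 0):
        raise ValueError("SQI undefined for an all-zero section")
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    power = power[1:]          # drop DC
    freqs = freqs[1:]
    in_band = (freqs >= lo) & (freqs <= hi)
    num = float(power[in_band].sum())
    den = float(power[~in_band].sum())
    # out-of-band power below float roundoff dust counts as zero
    if den <= 1e-12 * (num + den):
        return SQIValue(value=np.inf, scope=scope, band=(lo, hi))
    return SQIValue(value=num / den, scope=scope, band=(lo, hi))


def sqi_per_section(sections: SectionSet, lo: float = 5.0,
                    hi: float = 15.0) -> list[SQIValue]:
    """SQI of every section, in order."""
    return [compute_sqi(sec, sections.fs, lo, hi, scope=i)
            for i, sec in enumerate(sections)]


def sqi_per_recording(sections: SectionSet, lo: float = 5.0, hi: float = 15.0,
                      expected_sections: int = 35) -> SQIValue:
    """Arithmetic mean of the per-section SQIs (``inf`` propagates)."""
    if len(sections) < expected_sections:
        raise ValueError(
            f"expected {expected_sections} sections, got {len(sections)}")
    values = [v.value for v in sqi_per_section(sections, lo, hi)]
    return SQIValue(value=float(np.mean(values)), scope="recording", band=(lo, hi))
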