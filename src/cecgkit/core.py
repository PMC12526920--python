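"""Core containers for single-lead ECG recordings and their 15-s sections.

A :class:`Recording` is a sampled single-lead ECG with a sampling rate, a
channel kind (``"reference"`` for adhesive Ag-AgCl skin electrodes,
``"capacitive"`` for through-clothing textile electrodes) and free-form
provenance metadata.  A :class:`SectionSet` is the list of contiguous,
non-overlapping fixed-length windows cut from the start of a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNEL_KINDS = ("reference", "capacitive")


@dataclass
class Recording:
    """A sampled single-lead ECG.

    Parameters
    ----------
    samples : ndarray
        Amplitude series, raw units or z-units.  Must be finite and non-empty.
    fs : float
        Sampling rate in Hz, > 0.
    channel_kind : str
        ``"reference"`` or ``"capacitive"``.
    meta : dict
        Free-form provenance (subject, session, seed, processing history).
    """

    samples: np.ndarray
    fs: float
    channel_kind: str = "reference"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.channel_kind not in CHANNEL_KINDS:
            raise ValueError(
                f"channel_kind must be one of {CHANNEL_KINDS}, got {self.channel_kind!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    def replace(self, samples=None, fs=None, channel_kind=None, extra_meta=None,
                history_entry=None) -> "Recording":
        """Return a copy with selected fields replaced.

        ``extra_meta`` is merged into a copy of ``meta``; ``history_entry``
        is appended to ``meta["history"]`` (created if absent) so every
        processing stage leaves a trace.
        """
        meta = dict(self.meta)
        if extra_meta:
            meta.update(extra_meta)
        if history_entry is not None:
            meta["history"] = list(meta.get("history", [])) + [history_entry]
        return Recording(
            samples=self.samples.copy() if samples is None else samples,
            fs=self.fs if fs is None else fs,
            channel_kind=self.channel_kind if channel_kind is None else channel_kind,
            meta=meta,
        )


@dataclass
class SectionSet:
    """Non-overlapping fixed-length windows cut from the start of a recording.

    Windows are contiguous, each exactly ``fs * section_length`` samples long,
    and tile ``[0, n_sections * section_length)`` seconds of the parent.
    """

    parent: Recording
    section_length: float
    sections: list  # list of 1-D ndarrays
    starts: np.ndarray  # start offsets in samples

    def __post_init__(self) -> None:
        nper = int(round(self.parent.fs * self.section_length))
        for i, (sec, st) in enumerate(zip(self.sections, self.starts)):
            if len(sec) != nper:
                raise ValueError(f"section {i} has {len(sec)} samples, expected {nper}")
            if st != i * nper:
                raise ValueError("sections must be contiguous and non-overlapping")

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def fs(self) -> float:
        return self.parent.fs

    def __iter__(self):
        return iter(self.sections)

    def __len__(self) -> int:
        return len(self.sections)

    def __getitem__(self, i):
        return self.sections[i]
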