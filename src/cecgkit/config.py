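"""Run configuration: every tunable of the analysis chain in one place.

Defaults reproduce the published constants of the methodology this package
implements: 125 Hz working rate, ±8 z-unit spike cap, 35 sections of 15 s,
5-15 Hz QRS band, 19-point/10-step envelope smoother, 0.833-1.833 Hz cardiac
search band (50-110 bpm), and the 125/31 moving-average baseline remover
used for visualization.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


def band_from_bpm(lo_bpm: float, hi_bpm: float) -> tuple[float, float]:
    """Cardiac search band in Hz from a resting heart-rate range in bpm."""
    if not 0 < lo_bpm < hi_bpm:
        raise ValueError("need 0 < lo_bpm < hi_bpm")
    return lo_bpm / 60.0, hi_bpm / 60.0


@dataclass
class RunConfig:
    # preprocessing
    fs_target: float = 125.0          # Hz, working sampling rate
    cap_threshold: float = 8.0        # z-units, saturation-spike cap
    section_length: float = 15.0      # s
    n_sections: int = 35
    aa_cutoff_frac: float = 0.45      # anti-alias FIR cutoff as fraction of fs_target
    # QRS band (shared by the band-pass step and the SQI)
    qrs_band: tuple[float, float] = (5.0, 15.0)   # Hz
    # envelope chain
    clip_percentile: float = 95.0
    envelope_window: int = 19         # samples
    envelope_step: int = 10           # samples -> envelope rate fs/10
    # spectral RR search
    search_band_bpm: tuple[float, float] = (50.0, 110.0)
    freq_resolution: float = 0.005    # Hz, max spectral bin spacing for the peak search
    # baseline-wander remover (visualization only)
    baseline_window: int = 125        # samples
    baseline_step: int = 31           # samples
    # Pan-Tompkins detector
    pt_integration_window: float = 0.150   # s
    pt_refractory: float = 0.200           # s
    # error coverage bins (ERP percent, first bin closed, others left-open]
    erp_bin_edges: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    # statistics
    alpha: float = 0.05

    @property
    def search_band(self) -> tuple[float, float]:
        """Cardiac search band in Hz derived from ``search_band_bpm``."""
        return band_from_bpm(*self.search_band_bpm)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = RunConfig()
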