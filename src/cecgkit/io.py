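"""Delimited-text signal storage with a YAML metadata sidecar, plus result
writing with a digest manifest.

A signal lives in ``<name>.csv`` — a ``# fs=<Hz> channel=<kind>`` comment
header followed by one amplitude per line — with ``<name>.yaml`` alongside
carrying sampling rate, channel kind, sample count and free-form provenance
(subject, session, seed, processing history).  The header and sidecar must
agree; inconsistencies are errors, not warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Recording


def _yaml_safe(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _yaml_safe(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_signal(rec: Recording, path) -> Path:
    """Write a recording as delimited text plus its YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# fs={rec.fs:g} channel={rec.channel_kind}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, rec.samples, fmt="%.10g")
    sidecar = {
        "fs": float(rec.fs),
        "channel_kind": rec.channel_kind,
        "n_samples": int(rec.n_samples),
        "meta": _yaml_safe(rec.meta),
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return path


def read_signal(path) -> Recording:
    """Read a recording, validating header/sidecar consistency.

    Raises on a missing sidecar, an fs or channel mismatch between header
    and sidecar, a sample-count mismatch, or any non-numeric/missing value
    (the error names the first bad row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sc_path = sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sc_path}")
    with open(sc_path) as fh:
        sidecar = yaml.safe_load(fh)
    for key in ("fs", "channel_kind", "n_samples"):
        if key not in sidecar:
            raise ValueError(f"sidecar {sc_path} lacks required key {key!r}")

    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing '# fs=... channel=...' header")
        fields = dict(tok.split("=", 1) for tok in first.lstrip("# ").split())
        header_fs = float(fields["fs"])
        header_channel = fields.get("channel", "")
        samples = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                samples.append(float(line))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric sample {line!r}")
            if not np.isfinite(samples[-1]):
                raise ValueError(f"{path}:{lineno}: non-finite sample {line!r}")

    if abs(header_fs - float(sidecar["fs"])) > 1e-9:
        raise ValueError(
            f"{path}: header fs={header_fs} disagrees with sidecar fs={sidecar['fs']}")
    if header_channel and header_channel != sidecar["channel_kind"]:
        raise ValueError(f"{path}: header channel={header_channel!r} disagrees "
                         f"with sidecar channel_kind={sidecar['channel_kind']!r}")
    if len(samples) != int(sidecar["n_samples"]):
        raise ValueError(f"{path}: {len(samples)} samples on disk, sidecar "
                         f"declares {sidecar['n_samples']}")
    return Recording(np.asarray(samples), fs=float(sidecar["fs"]),
                     channel_kind=sidecar["channel_kind"],
                     meta=sidecar.get("meta") or {})


def write_results(tables: dict[str, pd.DataFrame] | None,
                  figures: dict | None, out_dir) -> dict:
    """Write result tables (CSV) and figures (PNG); return a digest manifest.

    File naming is deterministic (sorted by name); the manifest maps each
    artifact to its SHA-256 content digest and is itself written as
    ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name in sorted(tables or {}):
        p = out_dir / f"{name}.csv"
        tables[name].to_csv(p, index=True)
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    for name in sorted(figures or {}):
        p = out_dir / f"{name}.png"
        figures[name].savefig(p, dpi=120)
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
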