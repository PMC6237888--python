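"""Peak-list CSV and sample-manifest round-tripping.

Peak lists are plain CSV with columns ``mz,intensity,snr`` (header
required, '.' decimal). Sample context lives in a YAML manifest mapping
sample id -> {file, system, sugar, amino_acid, time_h, replicate,
is_blank}.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .assignment import Peak, PeakList

PEAKLIST_COLUMNS = ["mz", "intensity", "snr"]


def write_peaklist_csv(peaklist: PeakList, path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.mz, p.intensity, p.snr) for p in peaklist.peaks],
        columns=PEAKLIST_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_peaklist_csv(
    path: str | Path,
    sample_id: str,
    system: str,
    time_h: float,
    replicate: int,
    is_blank: bool = False,
    sugar: str | None = None,
    amino_acid: str | None = None,
    resolution_floor_mda: float = 1.0,
) -> PeakList:
    df = pd.read_csv(path)
    missing = [c for c in PEAKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing peak-list column(s) {missing}")
    peaks = [
        Peak(mz=float(r.mz), intensity=float(r.intensity), snr=float(r.snr))
        for r in df.itertuples()
    ]
    return PeakList(
        sample_id=sample_id,
        system=system,
        time_h=time_h,
        replicate=replicate,
        peaks=peaks,
        is_blank=is_blank,
        sugar=sugar,
        amino_acid=amino_acid,
        resolution_floor_mda=resolution_floor_mda,
    )


_MANIFEST_KEYS = {
    "file", "system", "sugar", "amino_acid", "time_h", "replicate", "is_blank"
}


def write_manifest(entries: Mapping[str, dict], path: str | Path) -> None:
    """Write the sample manifest as YAML (sorted for reproducible bytes)."""
    payload = {
        sid: {k: entry.get(k) for k in sorted(_MANIFEST_KEYS)}
        for sid, entry in sorted(entries.items())
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_manifest(path: str | Path) -> dict[str, dict[str, Any]]:
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: manifest must map sample ids to entries")
    out: dict[str, dict[str, Any]] = {}
    for sid, entry in data.items():
        if not isinstance(entry, dict):
            raise ValueError(f"{path}: entry for {sid!r} is not a mapping")
        unknown = set(entry) - _MANIFEST_KEYS
        if unknown:
            raise ValueError(
                f"{path}: unknown manifest key(s) {sorted(unknown)} for {sid!r}"
            )
        for key in ("system", "time_h", "replicate"):
            if key not in entry:
                raise ValueError(f"{path}: {sid!r} misses required {key!r}")
        out[str(sid)] = {
            "file": entry.get("file", f"{sid}.csv"),
            "system": str(entry["system"]),
            "sugar": entry.get("sugar"),
            "amino_acid": entry.get("amino_acid"),
            "time_h": float(entry["time_h"]),
            "replicate": int(entry["replicate"]),
            "is_blank": bool(entry.get("is_blank", False)),
        }
    return out


def load_peaklist(
    sample_id: str, entry: Mapping[str, Any], base_dir: str | Path
) -> PeakList:
    """Load one manifest entry's peak list relative to the manifest dir."""
    path = Path(base_dir) / entry["file"]
    if not path.exists():
        raise FileNotFoundError(
            f"manifest references missing peak list {path} "
            f"(sample {sample_id!r})"
        )
    return read_peaklist_csv(
        path,
        sample_id=sample_id,
        system=entry["system"],
        time_h=entry["time_h"],
        replicate=entry["replicate"],
        is_blank=entry["is_blank"],
        sugar=entry.get("sugar"),
        amino_acid=entry.get("amino_acid"),
    )
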