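"""Signal and dataset file formats.

A signal is stored as a two-column CSV (sample_index, value_uV) with a
JSON sidecar of the same stem carrying sampling rate, label and
provenance; values are serialized with 17 significant digits so a
write/read round trip is bit-exact.  A dataset manifest is a JSON file
listing member signals with their paths and labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureVector
from .simulate import CLASSES, Signal


class SignalParseError(ValueError):
    pass


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_signal(signal: Signal, path: str | Path) -> Path:
    """Write CSV samples plus a JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample_index,value_uV\n")
        for i, v in enumerate(signal.samples):
            fh.write(f"{i},{v:.17g}\n")
    meta = {
        "signal_id": signal.signal_id,
        "fs_hz": signal.fs_hz,
        "label": signal.label,
        "parent_id": signal.parent_id,
        "offset": signal.offset,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_signal(path: str | Path) -> Signal:
    """Read a CSV+sidecar signal; parse errors name the offending line."""
    path = Path(path)
    values = []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise SignalParseError(f"{path}: file is empty")
    start = 1 if lines[0].lower().startswith("sample_index") else 0
    if len(lines) <= start:
        raise SignalParseError(f"{path}: no sample rows")
    for ln, line in enumerate(lines[start:], start=start + 1):
        line = line.strip()
        if not line:
            continue
        fields = line.split(",")
        try:
            v = float(fields[-1])
        except ValueError:
            raise SignalParseError(f"{path}: line {ln}: non-numeric value {fields[-1]!r}") from None
        if not np.isfinite(v):
            raise SignalParseError(f"{path}: line {ln}: non-finite value {fields[-1]!r}")
        values.append(v)
    if not values:
        raise SignalParseError(f"{path}: no sample rows")

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SignalParseError(f"{path}: missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("fs_hz", "label"):
        if key not in meta:
            raise SignalParseError(f"{sidecar}: missing required field {key!r}")
    return Signal(
        samples=np.asarray(values),
        fs_hz=float(meta["fs_hz"]),
        label=meta["label"],
        signal_id=meta.get("signal_id", path.stem),
        parent_id=meta.get("parent_id"),
        offset=meta.get("offset"),
    )


def write_manifest(signals: list[Signal], paths: list[Path], out_path: str | Path, provenance: dict | None = None) -> Path:
    out_path = Path(out_path)
    ids = [s.signal_id for s in signals]
    if len(set(ids)) != len(ids):
        raise ValueError("signal ids must be unique within a manifest")
    entries = [
        {
            "signal_id": s.signal_id,
            "path": str(Path(p).resolve().relative_to(out_path.resolve().parent)),
            "label": s.label,
            "fs_hz": s.fs_hz,
            "parent_id": s.parent_id,
            "offset": s.offset,
        }
        for s, p in zip(signals, paths)
    ]
    doc = {"signals": entries, "provenance": provenance or {}}
    with open(out_path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return out_path


def read_manifest(path: str | Path) -> list[Signal]:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    signals = []
    for entry in doc["signals"]:
        label = entry.get("label", "unknown")
        if label not in (*CLASSES, "unknown"):
            raise SignalParseError(f"{path}: unknown label {label!r} for {entry.get('signal_id')}")
        sig_path = path.parent / entry["path"]
        if not sig_path.exists():
            raise SignalParseError(f"{path}: referenced file {sig_path} does not exist")
        signals.append(read_signal(sig_path))
    return signals


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """One row per downsampled signal: metadata then f001 … f262."""
    meta = pd.DataFrame(
        {
            "signal_id": [f.signal_id for f in features],
            "parent_id": [f.parent_id for f in features],
            "offset": [f.offset for f in features],
            "label": [f.label for f in features],
        }
    )
    mat = np.vstack([f.fused for f in features])
    cols = [f"f{i + 1:03d}" for i in range(mat.shape[1])]
    return pd.concat([meta, pd.DataFrame(mat, columns=cols)], axis=1)


def frame_to_features(frame: pd.DataFrame) -> list[FeatureVector]:
    fcols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    n_fd = len(fcols) - 256
    out = []
    for _, row in frame.iterrows():
        vec = row[fcols].to_numpy(dtype=float)
        out.append(
            FeatureVector(
                fd=vec[:n_fd],
                lbp=vec[n_fd:],
                signal_id=row["signal_id"],
                parent_id=row["parent_id"],
                offset=int(row["offset"]),
                label=row["label"],
            )
        )
    return out
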