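"""Session readers/writers: the documented CSV bundle format.

A session is a directory with two files:

``manifest.json``
    fs, t0, filter cutoffs, condition, ordered channel labels (the
    ``"LEAD_Ex-Ey"`` dialect) with validity flags, and the stimulation
    event log.
``samples.csv``
    one column per channel label, one row per sample, microvolts.

The bundle round-trips samples losslessly (full float64 repr) and stim
events exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import Recording, StimEvent, parse_channel_label

__all__ = ["write_recording", "read_recording"]

MANIFEST = "manifest.json"
SAMPLES = "samples.csv"
FORMAT_VERSION = 1


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a CSV bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "fs": rec.fs,
        "t0": rec.t0,
        "hp_cutoff": rec.hp_cutoff,
        "lp_cutoff": rec.lp_cutoff,
        "condition": rec.condition,
        "channels": [
            {"label": ch.label, "valid": bool(ch.valid)} for ch in rec.channels
        ],
        "events": [ev.to_dict() for ev in rec.events],
    }
    (path / MANIFEST).write_text(json.dumps(manifest, indent=2))
    df = pd.DataFrame(rec.samples.T, columns=rec.labels)
    df.to_csv(path / SAMPLES, index=False)
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a CSV bundle back into a :class:`Recording`.

    Rejects a missing manifest and any channel label outside the
    ``"LEAD_Ex-Ey"`` dialect, naming the offending field.
    """
    path = Path(path)
    mpath = path / MANIFEST
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest: {mpath}")
    manifest = json.loads(mpath.read_text())
    for key in ("fs", "channels"):
        if key not in manifest:
            raise ValueError(f"manifest missing required field {key!r}")

    channels = []
    for entry in manifest["channels"]:
        ch = parse_channel_label(entry["label"])  # raises on bad dialect
        ch.valid = bool(entry.get("valid", True))
        channels.append(ch)

    df = pd.read_csv(path / SAMPLES)
    if list(df.columns) != [ch.label for ch in channels]:
        raise ValueError("samples.csv columns do not match manifest channels")
    events = [StimEvent.from_dict(d) for d in manifest.get("events", [])]
    return Recording(
        fs=float(manifest["fs"]),
        channels=channels,
        samples=df.to_numpy().T,
        t0=manifest.get("t0", "1970-01-01T00:00:00"),
        hp_cutoff=float(manifest.get("hp_cutoff", 0.5)),
        lp_cutoff=float(manifest.get("lp_cutoff", 100.0)),
        condition=manifest.get("condition", "sling"),
        events=events,
    )
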