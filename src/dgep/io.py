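"""Readers and writers for the dataset's on-disk formats.

* EP sweeps: one wide CSV per animal — metadata columns
  (session, intensity_uA, pulse, repetition, stim_time_s,
  sample_rate_hz) followed by sample columns ``s000000…`` in mV.
* Broadband: little-endian int16 flat binary, channel-interleaved
  (frame-major), with a JSON sidecar
  ``{n_channels, sample_rate_hz, uv_per_bit, event_times_s, …}``.
* Ground-truth spike times / morphometry / scores: plain CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .ep_waveform import Sweep
from .unit_activity import BroadbandRecording

__all__ = ["write_sweeps_csv", "read_sweeps_csv", "write_broadband",
           "read_broadband", "write_json", "read_json"]

#: Intan-style quantization step for the ±6.4 mV, 16-bit front end
UV_PER_BIT = 0.195

_META_COLS = ["session", "intensity_uA", "pulse", "repetition",
              "stim_time_s", "sample_rate_hz"]


def write_sweeps_csv(sweeps: list[Sweep], path: str | Path) -> Path:
    path = Path(path)
    if not sweeps:
        pd.DataFrame(columns=_META_COLS).to_csv(path, index=False)
        return path
    n = max(sw.samples.size for sw in sweeps)
    rows = []
    for sw in sweeps:
        row = {"session": sw.session, "intensity_uA": sw.intensity,
               "pulse": sw.pulse, "repetition": sw.repetition,
               "stim_time_s": sw.stim_time,
               "sample_rate_hz": sw.sample_rate}
        for i, v in enumerate(sw.samples):
            row[f"s{i:06d}"] = v
        rows.append(row)
    cols = _META_COLS + [f"s{i:06d}" for i in range(n)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False,
                                            float_format="%.6g")
    return path


def read_sweeps_csv(path: str | Path) -> list[Sweep]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise SchemaError("missing sweep columns", file=str(path),
                          field=",".join(missing))
    sample_cols = [c for c in df.columns if c.startswith("s") and
                   c[1:].isdigit()]
    sweeps = []
    for _, row in df.iterrows():
        samples = row[sample_cols].to_numpy(dtype=float)
        samples = samples[np.isfinite(samples)]
        sweeps.append(Sweep(samples=samples,
                            sample_rate=float(row["sample_rate_hz"]),
                            stim_time=float(row["stim_time_s"]),
                            intensity=float(row["intensity_uA"]),
                            pulse=str(row["pulse"]),
                            session=str(row["session"]),
                            repetition=int(row["repetition"])))
    return sweeps


def write_broadband(rec: BroadbandRecording, prefix: str | Path) -> Path:
    """Write ``<prefix>.bin`` (int16 LE, frame-major) + ``<prefix>.json``."""
    prefix = Path(prefix)
    q = np.clip(np.round(rec.data / UV_PER_BIT), -32768, 32767)
    q.astype("<i2").T.tofile(prefix.with_suffix(".bin"))
    sidecar = {"n_channels": rec.n_channels,
               "sample_rate_hz": rec.sample_rate,
               "uv_per_bit": UV_PER_BIT,
               "event_times_s": rec.event_times,
               "channel_depth_order": list(rec.channel_depth_order),
               "n_samples": int(rec.data.shape[1])}
    write_json(sidecar, prefix.with_suffix(".json"))
    return prefix.with_suffix(".bin")


def read_broadband(prefix: str | Path) -> BroadbandRecording:
    prefix = Path(prefix)
    sidecar_path = prefix.with_suffix(".json")
    try:
        sidecar = read_json(sidecar_path)
    except (json.JSONDecodeError, OSError) as exc:
        raise SchemaError(f"unreadable sidecar: {exc}",
                          file=str(sidecar_path)) from exc
    for key in ("n_channels", "sample_rate_hz", "uv_per_bit",
                "event_times_s"):
        if key not in sidecar:
            raise SchemaError("missing sidecar key", file=str(sidecar_path),
                              field=key)
    raw = np.fromfile(prefix.with_suffix(".bin"), dtype="<i2")
    n_ch = int(sidecar["n_channels"])
    if raw.size % n_ch:
        raise SchemaError("binary length not divisible by channel count",
                          file=str(prefix.with_suffix(".bin")))
    data = raw.reshape(-1, n_ch).T.astype(float) * float(
        sidecar["uv_per_bit"])
    return BroadbandRecording(
        data=data, sample_rate=float(sidecar["sample_rate_hz"]),
        event_times={k: float(v)
                     for k, v in sidecar["event_times_s"].items()},
        channel_depth_order=tuple(sidecar.get("channel_depth_order",
                                              range(n_ch))))


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
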