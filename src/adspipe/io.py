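"""Standard-format persistence: HDF5 recordings, CSV tables, YAML configs.

Recordings are stored as int16 HDF5 with a microvolt scale factor;
spike trains, stimulation logs and all analysis tables round-trip as CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .ads import StimEventLog
from .core import ContinuousRecording, UnitSpikeTrain


def save_recording(path: str | Path, recording: ContinuousRecording) -> None:
    """Write a recording to HDF5 (datasets /data int16 + scale attr,
    /sample_rate, /channel_table group)."""
    peak = float(np.abs(recording.samples).max()) if recording.samples.size else 1.0
    scale = max(peak, 1e-9) / 32767.0
    with h5py.File(path, "w") as f:
        d = f.create_dataset(
            "data",
            data=np.round(recording.samples / scale).astype(np.int16),
            compression="gzip",
        )
        d.attrs["scale_uV"] = scale
        f.create_dataset("sample_rate", data=float(recording.sample_rate))
        g = f.create_group("channel_table")
        tab = recording.channel_table
        g.create_dataset("channel", data=tab["channel"].to_numpy(dtype=np.int64))
        g.create_dataset(
            "region", data=np.array([r.encode() for r in tab["region"]])
        )
        g.create_dataset("shank", data=tab["shank"].to_numpy(dtype=np.int64))
        g.create_dataset("site", data=tab["site"].to_numpy(dtype=np.int64))


def load_recording(path: str | Path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        scale = float(f["data"].attrs["scale_uV"])
        samples = f["data"][...].astype(float) * scale
        sample_rate = float(f["sample_rate"][()])
        g = f["channel_table"]
        tab = pd.DataFrame(
            {
                "channel": g["channel"][...],
                "region": [r.decode() for r in g["region"][...]],
                "shank": g["shank"][...],
                "site": g["site"][...],
            }
        )
    return ContinuousRecording(samples=samples, sample_rate=sample_rate, channel_table=tab)


def trains_to_csv(path: str | Path, trains: list[UnitSpikeTrain]) -> None:
    """One row per spike: unit_id, region, channel, label, timestamp_s."""
    rows = []
    for tr in trains:
        for t in tr.timestamps:
            rows.append(
                {
                    "unit_id": tr.unit_id,
                    "region": tr.region,
                    "channel": -1 if tr.channel is None else tr.channel,
                    "label": tr.label,
                    "timestamp_s": t,
                }
            )
    pd.DataFrame(
        rows, columns=["unit_id", "region", "channel", "label", "timestamp_s"]
    ).to_csv(path, index=False)


def trains_from_csv(path: str | Path, provenance: str = "external") -> list[UnitSpikeTrain]:
    """Import (possibly externally sorted) spike trains, bypassing the sorter."""
    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        ch = int(grp["channel"].iloc[0]) if "channel" in grp else None
        trains.append(
            UnitSpikeTrain(
                unit_id=str(uid),
                region=str(grp["region"].iloc[0]),
                timestamps=np.sort(grp["timestamp_s"].to_numpy(dtype=float)),
                channel=None if ch == -1 else ch,
                label=str(grp["label"].iloc[0]) if "label" in grp else "neural",
                provenance=provenance,
            )
        )
    return trains


def stim_log_to_csv(path: str | Path, log: StimEventLog) -> None:
    pd.DataFrame(
        {
            "time_s": log.times,
            "amplitude_uA": np.full(log.n_stimuli, log.amplitude),
            "trigger_time_s": log.trigger_times,
        }
    ).to_csv(path, index=False)


def stim_log_from_csv(path: str | Path, blanking_period: float = 0.028) -> StimEventLog:
    df = pd.read_csv(path)
    amp = float(df["amplitude_uA"].iloc[0]) if len(df) else 0.0
    return StimEventLog(
        times=df["time_s"].to_numpy(dtype=float),
        amplitude=amp,
        trigger_times=df["trigger_time_s"].to_numpy(dtype=float),
        blanking_period=blanking_period,
    )


def load_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def save_yaml(path: str | Path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)
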