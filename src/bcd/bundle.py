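"""Session-bundle reader/writer.

A session is stored as a single HDF5 file: LFP, heartbeat times and
per-unit spike times as datasets, everything else (sampling rate, channel
→ nucleus map, stimulus schedule, seed) as one JSON metadata attribute.
The round trip is lossless. Vendor electrophysiology formats are out of
scope; `load_session` is the single shim point where an importer for such
formats would plug in.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .synthgen import SessionRecord, SpikeTrain, StimEvent

__all__ = ["save_session", "load_session"]


def save_session(path: str | Path, session: SessionRecord) -> None:
    meta = {
        "fs": session.fs,
        "channel_nuclei": session.channel_nuclei,
        "stim_events": [
            [e.onset, e.offset, e.block_id, e.block_type] for e in session.stim_events
        ],
        "seed": session.seed,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp, compression="gzip", compression_opts=4)
        f.create_dataset("heartbeats", data=np.asarray(session.heartbeats, float))
        g = f.create_group("spikes")
        for i, st in enumerate(session.spikes):
            d = g.create_dataset(f"unit{i:03d}", data=np.asarray(st.times, float))
            d.attrs["channel"] = st.channel
        f.attrs["meta"] = json.dumps(meta)


def load_session(path: str | Path) -> SessionRecord:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        lfp = f["lfp"][...]
        heartbeats = f["heartbeats"][...]
        spikes = [
            SpikeTrain(times=f["spikes"][k][...], channel=int(f["spikes"][k].attrs["channel"]))
            for k in sorted(f["spikes"])
        ]
    events = [StimEvent(o, off, int(b), t) for o, off, b, t in meta["stim_events"]]
    return SessionRecord(
        lfp=lfp,
        fs=float(meta["fs"]),
        channel_nuclei=list(meta["channel_nuclei"]),
        stim_events=events,
        spikes=spikes,
        heartbeats=heartbeats,
        seed=meta["seed"],
    )
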