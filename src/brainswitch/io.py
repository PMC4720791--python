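"""Recording I/O: single-file HDF5 container plus CSV event sheets.

The container stores ``/samples`` (channels x time, µV), an ``/events``
table (onset seconds + labels) and root attributes for the sampling rate and
channel labels — enough to round-trip a :class:`~brainswitch.simulate.Recording`.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import Event, Recording

__all__ = [
    "save_recording",
    "load_recording",
    "events_to_csv",
    "events_from_csv",
]


def save_recording(recording: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=recording.samples)
        f.create_dataset("event_onsets",
                         data=np.array([e.onset for e in recording.events]))
        f.create_dataset(
            "event_labels",
            data=np.array([e.label for e in recording.events], dtype="S16"))
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["channel_labels"] = [l.encode() for l in recording.channel_labels]


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        onsets = f["event_onsets"][()]
        labels = [l.decode() for l in f["event_labels"][()]]
        fs = float(f.attrs["sampling_rate"])
        ch = tuple(l.decode() if isinstance(l, bytes) else str(l)
                   for l in f.attrs["channel_labels"])
    events = [Event(float(t), lab) for t, lab in zip(onsets, labels)]
    return Recording(samples=samples, channel_labels=ch, sampling_rate=fs,
                     events=events)


def events_to_csv(recording: Recording, path: str | Path) -> None:
    """Event sheet with onset_s, label and the 0-based run index."""
    run = -1
    rows = []
    for e in recording.events:
        if e.label == "run_start":
            run += 1
        rows.append({"onset_s": e.onset, "label": e.label,
                     "run_index": max(run, 0)})
    pd.DataFrame(rows).to_csv(path, index=False)


def events_from_csv(path: str | Path) -> list[Event]:
    df = pd.read_csv(path)
    return [Event(float(r.onset_s), str(r.label)) for r in df.itertuples()]
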