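"""Reading and writing recordings, events, and trial archives.

Recordings travel as wide TSV (one ``sample`` column plus one column per
channel, values in microvolts) with a small JSON sidecar carrying the
sampling rate and channel order; events as TSV with one row per trial
marker. EDF recordings can be read if ``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .preprocess import TrialSet
from .simulate import ControllerTrace, Marker, Recording

__all__ = [
    "write_recording_tsv",
    "read_recording_tsv",
    "write_events_tsv",
    "read_events_tsv",
    "write_controller_tsv",
    "read_controller_tsv",
    "save_trialset",
    "load_trialset",
    "read_raw_edf",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording_tsv(recording: Recording, path) -> None:
    path = Path(path)
    df = pd.DataFrame(recording.samples.T, columns=list(recording.channel_labels))
    df.insert(0, "sample", np.arange(recording.n_samples))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = {
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "units": "uV",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_recording_tsv(path, events_path=None) -> Recording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, sep="\t")
    labels = tuple(meta["channel_labels"])
    samples = df[list(labels)].to_numpy(float).T
    markers = read_events_tsv(events_path) if events_path is not None else []
    return Recording(
        samples=samples,
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=labels,
        markers=markers,
    )


def write_events_tsv(markers: List[Marker], path) -> None:
    df = pd.DataFrame(
        [
            {
                "onset_sample": m.onset,
                "run_id": m.run_id,
                "n_level": m.n_level,
                "trial_index": m.trial_index,
            }
            for m in markers
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> List[Marker]:
    df = pd.read_csv(path, sep="\t")
    return [
        Marker(
            onset=int(r.onset_sample),
            run_id=int(r.run_id),
            n_level=int(r.n_level),
            trial_index=int(r.trial_index),
        )
        for r in df.itertuples()
    ]


def write_controller_tsv(trace: ControllerTrace, path) -> None:
    pd.DataFrame(
        {"trial": np.arange(len(trace.positions)), "n_level": trace.n_levels,
         "position": trace.positions}
    ).to_csv(path, sep="\t", index=False)


def read_controller_tsv(path) -> ControllerTrace:
    df = pd.read_csv(path, sep="\t")
    return ControllerTrace(
        positions=df["position"].to_numpy(float),
        n_levels=df["n_level"].to_numpy(int),
    )


def save_trialset(trials: TrialSet, path) -> None:
    """Archive a TrialSet as NPZ (data) + JSON sidecar (labels, provenance)."""
    path = Path(path)
    np.savez_compressed(path, data=trials.data)
    meta = {
        "labels": trials.labels.tolist(),
        "run_ids": trials.run_ids.tolist(),
        "trial_indices": trials.trial_indices.tolist(),
        "sampling_rate": trials.sampling_rate,
        "channel_labels": list(trials.channel_labels),
    }
    sidecar = path if path.suffix == ".npz" else path.with_suffix(".npz")
    _sidecar(sidecar).write_text(json.dumps(meta, indent=2))


def load_trialset(path) -> TrialSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as npz:
        data = npz["data"]
    meta = json.loads(_sidecar(path).read_text())
    return TrialSet(
        data=data,
        labels=np.array(meta["labels"]),
        run_ids=np.array(meta["run_ids"]),
        trial_indices=np.array(meta["trial_indices"]),
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=tuple(meta["channel_labels"]),
    )


def read_raw_edf(path, events_path=None) -> Recording:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires mne; install with 'pip install cogload[edf]'"
        ) from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    markers = read_events_tsv(events_path) if events_path is not None else []
    return Recording(
        samples=samples,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        markers=markers,
    )
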