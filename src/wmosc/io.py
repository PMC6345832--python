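"""On-disk formats.

Arrays are flat little-endian float32 binaries with a JSON sidecar that
documents dimensions and grids; tables are TSV with a header line;
metadata is JSON. Epochs are stored trial-major ([trial][channel][sample]),
time-frequency maps channel-major ([channel][frequency][time]).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, TimeFrequencyMap
from .layout import SensorLayout

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_tfr",
    "read_tfr",
    "write_layout",
    "read_layout",
    "write_table",
    "read_table",
]

FLOAT_FMT = "%.10g"


def _write_bin(path: Path, arr: np.ndarray) -> None:
    np.asarray(arr, dtype="<f4").tofile(path)


def _read_bin(path: Path, shape: tuple) -> np.ndarray:
    arr = np.fromfile(path, dtype="<f4").astype(np.float64)
    return arr.reshape(shape)


def write_epochs(directory, epochs: EpochSet) -> list:
    """Write ``<id>_eeg.bin`` + ``<id>_eeg.json``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / f"{epochs.subject_id}_eeg"
    _write_bin(stem.with_suffix(".bin"), epochs.data)
    meta = {
        "subject_id": epochs.subject_id,
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_times,
        "sampling_rate_hz": epochs.sampling_rate,
        "t0_s": epochs.t0,
        "sample_onset_s": epochs.sample_onset,
        "condition": [str(c) for c in epochs.condition],
        "channel_names": list(epochs.channel_names),
        "order": "[trial][channel][sample]",
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return [stem.with_suffix(".bin"), stem.with_suffix(".json")]


def read_epochs(directory, subject_id: str) -> EpochSet:
    stem = Path(directory) / f"{subject_id}_eeg"
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    data = _read_bin(
        stem.with_suffix(".bin"),
        (meta["n_trials"], meta["n_channels"], meta["n_samples"]),
    )
    return EpochSet(
        data=data,
        sampling_rate=meta["sampling_rate_hz"],
        t0=meta["t0_s"],
        sample_onset=meta["sample_onset_s"],
        condition=np.array(meta["condition"]),
        subject_id=meta["subject_id"],
        channel_names=tuple(meta["channel_names"]),
    )


def write_tfr(directory, tfr: TimeFrequencyMap) -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / f"{tfr.subject_id}_tfr_{tfr.condition}"
    _write_bin(stem.with_suffix(".bin"), tfr.power)
    meta = {
        "subject_id": tfr.subject_id,
        "condition": tfr.condition,
        "baseline_state": tfr.baseline_state,
        "n_trials": tfr.n_trials,
        "freqs_hz": tfr.freqs.tolist(),
        "times_s": tfr.times.tolist(),
        "sample_onset_s": tfr.sample_onset,
        "channel_names": list(tfr.channel_names),
        "order": "[channel][frequency][time]",
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return [stem.with_suffix(".bin"), stem.with_suffix(".json")]


def read_tfr(directory, subject_id: str, condition: str) -> TimeFrequencyMap:
    stem = Path(directory) / f"{subject_id}_tfr_{condition}"
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    n_ch = len(meta["channel_names"])
    n_f = len(meta["freqs_hz"])
    n_t = len(meta["times_s"])
    power = _read_bin(stem.with_suffix(".bin"), (n_ch, n_f, n_t))
    return TimeFrequencyMap(
        power=power,
        freqs=np.array(meta["freqs_hz"]),
        times=np.array(meta["times_s"]),
        baseline_state=meta["baseline_state"],
        n_trials=meta["n_trials"],
        condition=meta["condition"],
        subject_id=meta["subject_id"],
        channel_names=tuple(meta["channel_names"]),
        sample_onset=meta["sample_onset_s"],
    )


def write_layout(path, layout: SensorLayout) -> None:
    with open(path, "w") as fh:
        json.dump(layout.to_dict(), fh, indent=1)


def read_layout(path) -> SensorLayout:
    with open(path) as fh:
        return SensorLayout.from_dict(json.load(fh))


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
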