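"""File I/O: EDF continuous recordings, event sidecars, HDF5 epoch caches.

Writing uses a small built-in EDF encoder (16-bit, physical range taken
from the data); reading goes through MNE's EDF reader, so a write/read
round trip crosses two independent implementations and checks both.
Events travel in a tab-separated sidecar with columns
``onset_sample`` and ``condition``.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import EpochsSet
from .simulate import ContinuousRecord

_EDF_EPOCH = "01.01.2000 00.00.00"


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(record: ContinuousRecord, path: str | os.PathLike) -> None:
    """Write a continuous record as EDF (microvolt signals, 1 s records).

    The last data record is zero-padded to a whole second; readers return
    the padded length, so compare against ``record.n_samples`` when round
    tripping.
    """
    fs = int(round(record.fs))
    if abs(record.fs - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    data = np.asarray(record.data, dtype=float)
    n_ch, n = data.shape
    n_rec = int(np.ceil(n / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n] = data

    # widen the data range slightly, then round to the 8-character EDF field
    # representation, so digitization uses exactly the scale a reader will
    # reconstruct and all codes stay inside the digital range
    lo = padded.min(axis=1)
    hi = padded.max(axis=1)
    span = np.maximum(hi - lo, 1e-6)
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in lo - 0.002 * span])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in hi + 0.002 * span])
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    date, time = _EDF_EPOCH.split(" ")
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate 01-JAN-2000 X X X", 80),
            _ascii(date, 8),
            _ascii(time, 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        [_ascii(ch, 16) for ch in record.channels],
        [_ascii("AgAgCl electrode", 80)] * n_ch,
        [_ascii("uV", 8)] * n_ch,
        [_ascii(f"{v:.6g}"[:8], 8) for v in pmin],
        [_ascii(f"{v:.6g}"[:8], 8) for v in pmax],
        [_ascii(dmin, 8)] * n_ch,
        [_ascii(dmax, 8)] * n_ch,
        [_ascii("", 80)] * n_ch,
        [_ascii(fs, 8)] * n_ch,
        [_ascii("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_continuous(
    edf_path: str | os.PathLike, event_path: str | os.PathLike | None = None
) -> tuple[ContinuousRecord, pd.DataFrame | None]:
    """Read an EDF recording (via MNE) and its optional event sidecar.

    Returns the signal in microvolts with the sampling rate from the file
    header.  Raises ``ValueError`` if any event onset lies beyond the end of
    the record, or if events are not sorted by onset.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts for uV-dimensioned EDF
    record = ContinuousRecord(data=data, fs=float(raw.info["sfreq"]), channels=list(raw.ch_names))
    events = None
    if event_path is not None:
        events = read_events(event_path)
        if (events["onset_sample"] >= record.n_samples).any():
            raise ValueError("event onset beyond end of record")
    return record, events


def write_events(events: pd.DataFrame, path: str | os.PathLike) -> None:
    events[["onset_sample", "condition"]].to_csv(path, sep="\t", index=False)


def read_events(path: str | os.PathLike) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    if not {"onset_sample", "condition"} <= set(events.columns):
        raise ValueError("event file needs columns onset_sample and condition")
    onsets = events["onset_sample"].to_numpy()
    if np.any(np.diff(onsets) < 0):
        raise ValueError("events must be sorted by onset")
    return events


def save_epochs(epochs: EpochsSet, path: str | os.PathLike) -> None:
    """Cache an EpochsSet as HDF5 (datasets: data, conditions, channels,
    kept_mask; attrs: fs, t0)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data, compression="gzip")
        fh.create_dataset(
            "conditions", data=np.asarray(epochs.conditions, dtype="S16")
        )
        fh.create_dataset("channels", data=np.asarray(epochs.channels, dtype="S16"))
        fh.create_dataset("kept_mask", data=epochs.kept_mask)
        fh.attrs["fs"] = epochs.fs
        fh.attrs["t0"] = epochs.t0


def load_epochs(path: str | os.PathLike) -> EpochsSet:
    with h5py.File(path, "r") as fh:
        return EpochsSet(
            data=fh["data"][()],
            fs=float(fh.attrs["fs"]),
            t0=float(fh.attrs["t0"]),
            channels=[c.decode() for c in fh["channels"][()]],
            conditions=np.array([c.decode() for c in fh["conditions"][()]]),
            kept_mask=fh["kept_mask"][()].astype(bool),
        )


def subject_paths(out_dir: str | os.PathLike, subject_id: str) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "edf": out / f"{subject_id}.edf",
        "events": out / f"{subject_id}_events.tsv",
    }
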