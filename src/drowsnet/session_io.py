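"""File formats: HDF5 session/epoch containers, a minimal EDF reader/writer
with an events CSV sidecar, and atomic-write helpers.

The HDF5 container round-trips sessions bit-for-bit (float64); EDF is
16-bit-quantized by the format and therefore only approximate.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import h5py
import numpy as np

from .montage import montage
from .preprocess import EpochSet
from .simulate import Event, RawSession

__all__ = [
    "atomic_write",
    "write_session",
    "read_session",
    "write_epochs",
    "read_epochs",
    "write_edf",
    "read_edf",
    "write_events_csv",
    "read_events_csv",
]


@contextmanager
def atomic_write(path: str | Path, mode: str = "wb"):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _validate_labels(labels: list[str]) -> None:
    known = set(montage())
    unknown = [l for l in labels if l not in known]
    if unknown:
        raise ValueError(f"unknown channel labels: {unknown}")


# --------------------------------------------------------------------------
# HDF5 containers
# --------------------------------------------------------------------------

def write_session(session: RawSession, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp")
    with h5py.File(tmp, "w") as f:
        f.create_dataset("data", data=session.data)
        ev = f.create_group("events")
        ev.create_dataset("sample", data=np.array([e.sample for e in session.events], dtype=np.int64))
        ev.create_dataset("kind", data=np.array([e.kind for e in session.events], dtype="S16"))
        ev.create_dataset(
            "kss", data=np.array([-1 if e.kss is None else e.kss for e in session.events], dtype=np.int64)
        )
        meta = f.create_group("meta")
        meta.attrs["fs"] = session.fs
        meta.attrs["subject_id"] = session.subject_id
        meta.attrs["channel_labels"] = json.dumps(session.channel_labels)
        meta.attrs["channel_types"] = json.dumps(session.channel_types)
    os.replace(tmp, path)


def _read_session_h5(path: Path) -> RawSession:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        samples = f["events/sample"][...]
        kinds = [k.decode() for k in f["events/kind"][...]]
        kss = f["events/kss"][...]
        meta = f["meta"].attrs
        events = [
            Event(int(s), kind, None if v < 0 else int(v))
            for s, kind, v in zip(samples, kinds, kss)
        ]
        labels = json.loads(meta["channel_labels"])
        _validate_labels(labels)
        return RawSession(
            data=data,
            channel_labels=labels,
            channel_types=json.loads(meta["channel_types"]),
            events=events,
            fs=float(meta["fs"]),
            subject_id=str(meta["subject_id"]),
        )


def write_epochs(epochs: EpochSet, path: str | Path, folds: np.ndarray | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp")
    with h5py.File(tmp, "w") as f:
        f.create_dataset("epochs", data=epochs.epochs)
        f.create_dataset("kss", data=epochs.kss)
        f.create_dataset("trial_index", data=epochs.trial_index)
        f.create_dataset("labels2", data=epochs.labels2)
        f.create_dataset("labels5", data=epochs.labels5)
        if folds is not None:
            f.create_dataset("folds", data=folds)
        if epochs.subject_index is not None:
            f.create_dataset("subject_index", data=epochs.subject_index)
        f.attrs["fs"] = epochs.fs
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["channel_labels"] = json.dumps(epochs.channel_labels)
    os.replace(tmp, path)


def read_epochs(path: str | Path) -> tuple[EpochSet, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        es = EpochSet(
            epochs=f["epochs"][...],
            kss=f["kss"][...],
            trial_index=f["trial_index"][...],
            subject_id=str(f.attrs["subject_id"]),
            fs=float(f.attrs["fs"]),
            channel_labels=json.loads(f.attrs["channel_labels"]),
            subject_index=f["subject_index"][...] if "subject_index" in f else None,
        )
        folds = f["folds"][...] if "folds" in f else None
    return es, folds


# --------------------------------------------------------------------------
# EDF (16-bit, one data record per second) + events CSV sidecar
# --------------------------------------------------------------------------

def _fixed(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{{:.{max(width - 2, 0)}g}}", "{:g}"):
        s = fmt.format(value)
        if len(s) <= width:
            return _fixed(s, width)
    return _fixed(s[:width], width)


def write_edf(session: RawSession, path: str | Path) -> None:
    """Minimal EDF export (integer sampling rate, 1-s data records).

    Events go to a ``<stem>.events.csv`` sidecar since plain EDF has no
    annotation channel.
    """
    fs = session.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = session.data.shape[0]
    n_records = int(np.ceil(session.n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : session.n_samples] = session.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((padded - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    header = bytearray()
    header += _fixed("0", 8)
    header += _fixed(f"subject {session.subject_id}", 80)
    header += _fixed("synthetic drowsiness session", 80)
    header += _fixed("01.01.00", 8)
    header += _fixed("00.00.00", 8)
    header += _fixed(str(256 * (1 + n_ch)), 8)
    header += _fixed("", 44)
    header += _fixed(str(n_records), 8)
    header += _fixed("1", 8)
    header += _fixed(str(n_ch), 4)
    for field, width in (
        (session.channel_labels, 16),
        (["" for _ in range(n_ch)], 80),
        (["uV"] * n_ch, 8),
    ):
        for value in field:
            header += _fixed(str(value), width)
    for v in pmin:
        header += _num(float(v), 8)
    for v in pmax:
        header += _num(float(v), 8)
    for _ in range(n_ch):
        header += _fixed(str(dmin), 8)
    for _ in range(n_ch):
        header += _fixed(str(dmax), 8)
    for _ in range(n_ch):
        header += _fixed("", 80)
    for _ in range(n_ch):
        header += _fixed(str(fs), 8)
    for _ in range(n_ch):
        header += _fixed("", 32)

    with atomic_write(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.astype("<i2").tobytes())

    write_events_csv(session.events, Path(path).with_suffix(".events.csv"))


def read_edf(path: str | Path, require_events: bool = True) -> RawSession:
    """Read a minimal EDF file written by :func:`write_edf`.

    Raises ``FileNotFoundError`` if the events sidecar is missing (unless
    ``require_events=False``).
    """
    path = Path(path)
    raw = path.read_bytes()
    n_ch = int(raw[252:256].decode().strip())
    n_records = int(raw[236:244].decode().strip())
    off = 256
    labels = [raw[off + 16 * i : off + 16 * (i + 1)].decode().strip() for i in range(n_ch)]
    off += 16 * n_ch + 80 * n_ch + 8 * n_ch
    pmin = np.array([float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
    off += 8 * n_ch
    pmax = np.array([float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
    off += 8 * n_ch
    dmin = np.array([float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
    off += 8 * n_ch
    dmax = np.array([float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
    off += 8 * n_ch + 80 * n_ch
    spr = [int(raw[off + 8 * i : off + 8 * (i + 1)].decode().strip()) for i in range(n_ch)]
    if len(set(spr)) != 1:
        raise ValueError("mixed per-channel sampling rates are not supported")
    fs = spr[0]
    header_bytes = 256 * (1 + n_ch)

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    body = body.reshape(n_records, n_ch, fs)
    digital = body.transpose(1, 0, 2).reshape(n_ch, n_records * fs).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]

    _validate_labels(labels)
    types = ["EOG" if l.startswith("EOG") else "EEG" for l in labels]

    sidecar = path.with_suffix(".events.csv")
    if sidecar.exists():
        events = read_events_csv(sidecar)
    elif require_events:
        raise FileNotFoundError(
            f"events sidecar {sidecar} not found; EDF sessions require an events CSV"
        )
    else:
        events = []
    return RawSession(data=data, channel_labels=labels, channel_types=types,
                      events=events, fs=float(fs), subject_id=path.stem)


def write_events_csv(events: list[Event], path: str | Path) -> None:
    with atomic_write(path, "w") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "kind", "kss_value"])
        for e in events:
            writer.writerow([e.sample, e.kind, "" if e.kss is None else e.kss])


def read_events_csv(path: str | Path) -> list[Event]:
    events: list[Event] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            kss = row["kss_value"]
            events.append(Event(int(row["sample_index"]), row["kind"], int(kss) if kss else None))
    return events


def read_session(path: str | Path, format: str | None = None) -> RawSession:
    """Load a session from the HDF5 container or from EDF (+events CSV)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "container"
    if format == "container":
        return _read_session_h5(path)
    if format == "edf":
        return read_edf(path)
    raise ValueError(f"unknown format {format!r}")
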