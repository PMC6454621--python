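"""Recording-session container and on-disk bundle I/O.

A session holds a single-channel 10 kHz microneurogram (MNG), one to four
10 kHz surface-EMG channels, a 10 Hz pressure readout, the cue timeline and,
for synthetic sessions, the per-unit ground-truth spike times.

On disk a session is a directory bundle::

    <path>/
      meta.json          sampling rates, units, protocol timeline, seed, schema
      channels.h5        columnar time series (HDF5 store, default)  -- or --
      channels/*.csv     columnar time series (CSV store)
      ground_truth.json  per-unit spike-time lists (synthetic sessions only)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .protocols import ProtocolTimeline

SCHEMA_VERSION = 1
MNG_FS = 10_000.0
PRESSURE_FS = 10.0


@dataclass
class RecordingSession:
    mng: np.ndarray                      # volts (a.u.) @ 10 kHz
    semg: list[np.ndarray]               # 1-4 channels @ 10 kHz
    pressure: np.ndarray                 # kPa @ 10 Hz
    protocol: ProtocolTimeline
    ground_truth: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None
    fs: float = MNG_FS
    pressure_fs: float = PRESSURE_FS

    @property
    def duration(self) -> float:
        return len(self.mng) / self.fs

    def time(self) -> np.ndarray:
        return np.arange(len(self.mng)) / self.fs

    def validate(self) -> None:
        n = len(self.mng)
        for i, ch in enumerate(self.semg):
            if len(ch) != n:
                raise ValueError(f"sEMG channel {i} length mismatch")
        expected_p = int(round(n / self.fs * self.pressure_fs))
        if abs(len(self.pressure) - expected_p) > 1:
            raise ValueError("pressure trace does not span the session")


class SchemaError(ValueError):
    """Bundle missing metadata or written by an incompatible schema."""


def write_session(session: RecordingSession, path: str | Path,
                  store: str = "hdf5") -> Path:
    """Write a session bundle. ``store`` is "hdf5" (default) or "csv"."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "store": store,
        "fs": session.fs,
        "pressure_fs": session.pressure_fs,
        "n_semg": len(session.semg),
        "seed": session.seed,
        "protocol": session.protocol.to_dict(),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    channels = {"mng": session.mng, "pressure": session.pressure}
    for i, ch in enumerate(session.semg):
        channels[f"semg{i}"] = ch
    if store == "hdf5":
        import h5py

        with h5py.File(path / "channels.h5", "w") as f:
            for name, arr in channels.items():
                f.create_dataset(name, data=np.asarray(arr, dtype=np.float64))
    elif store == "csv":
        cdir = path / "channels"
        cdir.mkdir(exist_ok=True)
        for name, arr in channels.items():
            np.savetxt(cdir / f"{name}.csv", np.asarray(arr, dtype=np.float64),
                       fmt="%.10g")
    else:
        raise ValueError(f"unknown store {store!r}")
    if session.ground_truth:
        gt = {k: np.asarray(v, dtype=float).tolist()
              for k, v in session.ground_truth.items()}
        (path / "ground_truth.json").write_text(json.dumps(gt))
    return path


def read_session(path: str | Path) -> RecordingSession:
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise SchemaError(f"no meta.json in {path}")
    meta = json.loads(meta_file.read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"bundle schema version {version!r} unsupported "
            f"(expected {SCHEMA_VERSION})")
    store = meta.get("store", "hdf5")
    channels: dict[str, np.ndarray] = {}
    if store == "hdf5":
        import h5py

        with h5py.File(path / "channels.h5", "r") as f:
            for name in f:
                channels[name] = f[name][...]
    else:
        for csv in sorted((path / "channels").glob("*.csv")):
            channels[csv.stem] = np.loadtxt(csv, ndmin=1)
    semg = [channels[k] for k in sorted(k for k in channels if k.startswith("semg"))]
    ground_truth = {}
    gt_file = path / "ground_truth.json"
    if gt_file.exists():
        ground_truth = {k: np.asarray(v, dtype=float)
                        for k, v in json.loads(gt_file.read_text()).items()}
    return RecordingSession(
        mng=channels["mng"],
        semg=semg,
        pressure=channels["pressure"],
        protocol=ProtocolTimeline.from_dict(meta["protocol"]),
        ground_truth=ground_truth,
        seed=meta.get("seed"),
        fs=float(meta["fs"]),
        pressure_fs=float(meta["pressure_fs"]),
    )
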