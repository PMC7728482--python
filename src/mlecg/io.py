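"""Record containers and file I/O.

The canonical on-disk format is an NPY array (leads x samples, float64,
millivolts) with a JSON sidecar carrying the sampling rate, lead names and —
when known — ground-truth R-peak indices and a class label.  CSV (one column
per lead) and WFDB record/header pairs (format 16) are supported read-only /
as secondary formats.  All sample indices in sidecars are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Standard 12-lead order used throughout the package.
LEAD_NAMES = ("I", "II", "III", "aVL", "aVF", "aVR",
              "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class ECGRecord:
    """A multilead ECG record.

    Parameters
    ----------
    signal : ndarray, shape (n_leads, n_samples)
        Voltages in millivolts.
    fs : float
        Sampling rate in Hz.
    lead_names : tuple of str
        Ordered lead identifiers; defaults to the standard 12-lead set.
    """

    signal: np.ndarray
    fs: float
    lead_names: tuple = LEAD_NAMES

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim == 1:
            self.signal = self.signal[None, :]
        if self.signal.ndim != 2:
            raise ValueError("signal must be a lead x sample matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.lead_names = tuple(self.lead_names)[: self.n_leads]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead by name (case-insensitive)."""
        names = [n.lower() for n in self.lead_names]
        key = name.lower()
        if key not in names:
            raise KeyError(f"lead {name!r} not present (have {self.lead_names})")
        return self.signal[names.index(key)]

    def with_signal(self, signal: np.ndarray, fs: float | None = None) -> "ECGRecord":
        return replace(self, signal=signal, fs=self.fs if fs is None else fs)

    def copy(self) -> "ECGRecord":
        return replace(self, signal=self.signal.copy())


@dataclass
class RecordMeta:
    """Sidecar metadata for a stored record."""

    fs: float
    lead_names: tuple
    r_peaks: list = field(default_factory=list)
    label: int | None = None


def save_record(record: ECGRecord, path, r_peaks=None, label=None) -> Path:
    """Write ``path``.npy plus ``path``.json sidecar; returns the NPY path."""
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    npy = path.with_suffix(".npy")
    np.save(npy, record.signal)
    meta = {
        "fs": record.fs,
        "lead_names": list(record.lead_names),
        "r_peaks": [int(i) for i in (r_peaks if r_peaks is not None else [])],
        "label": None if label is None else int(label),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return npy


def load_record(path) -> tuple[ECGRecord, RecordMeta]:
    """Read an NPY+JSON record pair written by :func:`save_record`."""
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    sig = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    rec = ECGRecord(sig, fs=meta["fs"], lead_names=tuple(meta["lead_names"]))
    return rec, RecordMeta(fs=meta["fs"], lead_names=tuple(meta["lead_names"]),
                           r_peaks=list(meta.get("r_peaks", [])),
                           label=meta.get("label"))


def save_csv(record: ECGRecord, path) -> Path:
    """Write one column per lead; sampling rate goes in a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(record.signal.T, columns=list(record.lead_names))
    df.to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps({"fs": record.fs, "lead_names": list(record.lead_names)}))
    return path


def load_csv(path, fs: float | None = None) -> ECGRecord:
    path = Path(path)
    df = pd.read_csv(path)
    if fs is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError("fs not given and no JSON sidecar found")
        fs = json.loads(sidecar.read_text())["fs"]
    return ECGRecord(df.to_numpy().T, fs=fs, lead_names=tuple(df.columns))


def read_wfdb(record_path) -> ECGRecord:
    """Read a WFDB record (text .hea header + format-16 .dat), read-only.

    Supports the single-segment, single-.dat, format-16 layout; signal values
    are converted to millivolts via each channel's ADC gain.
    """
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    lines = [ln.split("#")[0].strip() for ln in hea.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else None
    gains, names, fnames, fmts = [], [], [], []
    for spec in lines[1:1 + n_sig]:
        parts = spec.split()
        fnames.append(parts[0])
        fmts.append(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain = 200.0
        if len(parts) > 2:
            g = parts[2].split("(")[0].split("/")[0]
            gain = float(g) if float(g) != 0 else 200.0
        gains.append(gain)
        names.append(parts[-1] if len(parts) > 4 else f"ch{len(names)}")
    if len(set(fnames)) != 1:
        raise ValueError("multi-.dat WFDB records are not supported")
    if any(f != "16" for f in fmts):
        raise ValueError("only WFDB format 16 is supported")
    raw = (record_path.parent / fnames[0]).read_bytes()
    data = np.frombuffer(raw, dtype="<i2")
    if n_samp is None:
        n_samp = data.size // n_sig
    data = data[: n_samp * n_sig].reshape(n_samp, n_sig).T.astype(np.float64)
    sig = data / np.asarray(gains)[:, None]  # ADC units -> mV
    return ECGRecord(sig, fs=fs, lead_names=tuple(names))


def write_wfdb(record: ECGRecord, record_path, gain: float = 200.0) -> Path:
    """Write a minimal WFDB format-16 record (used for round-trip tests)."""
    record_path = Path(record_path)
    name = record_path.name
    n_sig, n_samp = record.signal.shape
    hdr = [f"{name} {n_sig} {record.fs:g} {n_samp}"]
    for ln in record.lead_names:
        hdr.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {ln}")
    record_path.with_suffix(".hea").write_text("\n".join(hdr) + "\n")
    adc = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    record_path.with_suffix(".dat").write_bytes(adc.T.tobytes())
    return record_path.with_suffix(".hea")


def load_any(path, fs: float | None = None) -> ECGRecord:
    """Dispatch on extension: .npy (with sidecar), .csv, or WFDB .hea."""
    path = Path(path)
    if path.suffix == ".npy" or path.with_suffix(".npy").exists():
        return load_record(path)[0]
    if path.suffix == ".csv":
        return load_csv(path, fs=fs)
    if path.suffix == ".hea" or path.with_suffix(".hea").exists():
        return read_wfdb(path.with_suffix(""))
    raise ValueError(f"cannot infer record format for {path}")
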