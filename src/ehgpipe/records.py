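"""Multichannel EHG/TOCO record container and file I/O.

An :class:`EHGRecord` bundles the 16 abdominal EHG channels recorded by a
4x4 electrode grid, the simultaneous tocodynamometer (TOCO) trace, the
sampling rate, and the contraction annotations (TOCO peak times).

Two on-disk representations are supported:

* ``portable`` — a line-oriented plain-text format designed so fixtures are
  human-readable and diffable, loadable with any generic text reader.
* ``wfdb`` — a minimal subset of the PhysioNet WFDB format: a text ``.hea``
  header plus a format-16 (little-endian int16) ``.dat`` signal file.
  Contraction annotations are stored in a plain-text ``<record>.uc`` sidecar
  (one peak time in seconds per line) rather than a binary annotation file.

Time convention: seconds from record start; sample index = round(t * fs);
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

N_EHG_CHANNELS = 16

PORTABLE_MAGIC = "# ehgpipe-record v1"


class RecordFormatError(ValueError):
    """Raised when a record file cannot be parsed."""


class ChannelCountError(RecordFormatError):
    """Raised when a file does not contain the expected channel layout."""


@dataclass
class ContractionAnnotation:
    """A clinician-style contraction event anchored at the TOCO peak."""

    peak_time: float
    start_time: float | None = None
    end_time: float | None = None

    def __post_init__(self) -> None:
        if self.peak_time < 0:
            raise ValueError(f"peak_time must be >= 0, got {self.peak_time}")
        if self.start_time is not None and self.end_time is not None:
            if not (self.start_time < self.peak_time < self.end_time):
                raise ValueError(
                    "annotation must satisfy start_time < peak_time < end_time, "
                    f"got ({self.start_time}, {self.peak_time}, {self.end_time})"
                )


@dataclass
class EHGRecord:
    """16 EHG channels + TOCO + annotations at a common sampling rate.

    Parameters
    ----------
    ehg : ndarray, shape (16, n_samples)
        EHG channels in electrode order, arbitrary amplitude units.
    toco : ndarray, shape (n_samples,)
        Tocodynamometer trace, arbitrary units.
    fs : float
        Sampling rate in Hz, shared by all channels.
    annotations : list of ContractionAnnotation
    """

    ehg: np.ndarray
    toco: np.ndarray
    fs: float
    annotations: list[ContractionAnnotation] = field(default_factory=list)
    recording_id: str = ""
    subject_id: str = ""
    gestational_age: float | None = None

    def __post_init__(self) -> None:
        self.ehg = np.asarray(self.ehg, dtype=float)
        self.toco = np.asarray(self.toco, dtype=float)
        if self.ehg.ndim != 2:
            raise ValueError("ehg must be a 2-D array (channels, samples)")
        if self.ehg.shape[1] != self.toco.shape[0]:
            raise ValueError(
                "EHG channels and TOCO must have equal sample counts: "
                f"{self.ehg.shape[1]} vs {self.toco.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for ann in self.annotations:
            if ann.peak_time > self.duration:
                raise ValueError(
                    f"annotation peak {ann.peak_time}s beyond record end {self.duration}s"
                )

    @property
    def n_channels(self) -> int:
        return self.ehg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ehg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def sample_index(self, t: float) -> int:
        return int(round(t * self.fs))

    def validate_conformant(self) -> None:
        """Check the database-conformant channel layout (16 EHG + TOCO)."""
        if self.n_channels != N_EHG_CHANNELS:
            raise ChannelCountError(
                f"expected {N_EHG_CHANNELS} EHG channels, got {self.n_channels}"
            )


# ---------------------------------------------------------------------------
# Portable plain-text format
# ---------------------------------------------------------------------------

def _write_portable(record: EHGRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(PORTABLE_MAGIC + "\n")
        fh.write(f"fs {record.fs!r}\n")
        fh.write(f"recording_id {record.recording_id}\n")
        fh.write(f"subject_id {record.subject_id}\n")
        ga = "NA" if record.gestational_age is None else repr(record.gestational_age)
        fh.write(f"gestational_age {ga}\n")
        names = [f"ehg{i + 1}" for i in range(record.n_channels)] + ["toco"]
        fh.write("channels " + " ".join(names) + "\n")
        fh.write(f"annotations {len(record.annotations)}\n")
        for ann in record.annotations:
            parts = [repr(ann.peak_time)]
            if ann.start_time is not None and ann.end_time is not None:
                parts += [repr(ann.start_time), repr(ann.end_time)]
            fh.write("ann " + " ".join(parts) + "\n")
        fh.write(f"data {record.n_samples}\n")
        stacked = np.vstack([record.ehg, record.toco[None, :]]).T
        np.savetxt(fh, stacked, fmt="%.9g")


def _read_portable(path: Path) -> EHGRecord:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != PORTABLE_MAGIC:
            raise RecordFormatError(f"{path}: not a portable ehgpipe record (bad magic)")
        header: dict[str, str] = {}
        annotations: list[ContractionAnnotation] = []
        n_samples = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, rest = line.partition(" ")
            if key == "ann":
                vals = [float(v) for v in rest.split()]
                if len(vals) == 1:
                    annotations.append(ContractionAnnotation(vals[0]))
                elif len(vals) == 3:
                    annotations.append(ContractionAnnotation(vals[0], vals[1], vals[2]))
                else:
                    raise RecordFormatError(f"{path}: malformed annotation line: {line!r}")
            elif key == "data":
                n_samples = int(rest)
                break
            else:
                header[key] = rest
        if n_samples is None:
            raise RecordFormatError(f"{path}: missing 'data' section")
        for required in ("fs", "channels"):
            if required not in header:
                raise RecordFormatError(f"{path}: corrupt header, missing '{required}'")
        names = header["channels"].split()
        if "toco" not in names:
            raise RecordFormatError(f"{path}: missing TOCO channel")
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (n_samples, len(names)):
        raise RecordFormatError(
            f"{path}: expected {n_samples} x {len(names)} samples, got {data.shape}"
        )
    toco_idx = names.index("toco")
    ehg_idx = [i for i in range(len(names)) if i != toco_idx]
    ga = header.get("gestational_age", "NA")
    return EHGRecord(
        ehg=data[:, ehg_idx].T,
        toco=data[:, toco_idx],
        fs=float(header["fs"]),
        annotations=annotations,
        recording_id=header.get("recording_id", ""),
        subject_id=header.get("subject_id", ""),
        gestational_age=None if ga == "NA" else float(ga),
    )


# ---------------------------------------------------------------------------
# Minimal WFDB subset (format 16)
# ---------------------------------------------------------------------------

_WFDB_FMT = 16
_ADC_MAX = 32000  # headroom below int16 full scale


def _write_wfdb(record: EHGRecord, path: Path) -> None:
    """Write <path>.hea / <path>.dat (format 16) and a text .uc annotation sidecar."""
    base = path.with_suffix("")
    name = base.name
    n_sig = record.n_channels + 1
    signals = np.vstack([record.ehg, record.toco[None, :]])
    gains = np.empty(n_sig)
    digital = np.empty_like(signals, dtype=np.int16)
    for i, sig in enumerate(signals):
        peak = float(np.max(np.abs(sig)))
        gains[i] = _ADC_MAX / peak if peak > 0 else 1.0
        digital[i] = np.round(sig * gains[i]).astype(np.int16)
    interleaved = digital.T.reshape(-1)
    with open(base.with_suffix(".dat"), "wb") as fh:
        fh.write(struct.pack(f"<{interleaved.size}h", *interleaved.tolist()))
    desc = [f"EHG{i + 1}" for i in range(record.n_channels)] + ["TOCO"]
    with open(base.with_suffix(".hea"), "w") as fh:
        fh.write(f"{name} {n_sig} {record.fs!r} {record.n_samples}\n")
        for i in range(n_sig):
            units = "uV" if i < record.n_channels else "au"
            fh.write(
                f"{name}.dat {_WFDB_FMT} {gains[i]:.9g}(0)/{units} "
                f"16 0 {digital[i, 0]} 0 0 {desc[i]}\n"
            )
        fh.write(f"# recording_id {record.recording_id}\n")
        fh.write(f"# subject_id {record.subject_id}\n")
        if record.gestational_age is not None:
            fh.write(f"# gestational_age {record.gestational_age!r}\n")
    with open(base.with_suffix(".uc"), "w") as fh:
        for ann in record.annotations:
            fh.write(f"{ann.peak_time!r}\n")


def _parse_gain(token: str) -> tuple[float, float]:
    """Parse a WFDB gain spec ``gain(baseline)/units`` -> (gain, baseline)."""
    gain_part = token.split("/")[0]
    baseline = 0.0
    if "(" in gain_part:
        gain_str, base_str = gain_part.rstrip(")").split("(")
        baseline = float(base_str)
    else:
        gain_str = gain_part
    gain = float(gain_str) if gain_str else 200.0  # WFDB default gain
    return (gain if gain != 0 else 200.0), baseline


def _read_wfdb(path: Path) -> EHGRecord:
    base = Path(path).with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise RecordFormatError(f"missing header file {hea}")
    lines = [ln.rstrip("\n") for ln in open(hea) if ln.strip()]
    meta = {}
    sig_lines = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            parts = ln[1:].split(None, 1)
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
        else:
            sig_lines.append(ln)
    head = lines[0].split()
    if len(head) < 4:
        raise RecordFormatError(f"{hea}: corrupt record line: {lines[0]!r}")
    n_sig, fs, n_samples = int(head[1]), float(head[2]), int(head[3])
    if len(sig_lines) != n_sig:
        raise RecordFormatError(
            f"{hea}: header declares {n_sig} signals but lists {len(sig_lines)}"
        )
    gains, baselines, descs = [], [], []
    for ln in sig_lines:
        toks = ln.split()
        if len(toks) < 3 or int(toks[1]) != _WFDB_FMT:
            raise RecordFormatError(f"{hea}: unsupported signal spec: {ln!r} (format 16 only)")
        g, b = _parse_gain(toks[2])
        gains.append(g)
        baselines.append(b)
        descs.append(toks[8] if len(toks) > 8 else "")
    raw = np.fromfile(base.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n_samples:
        raise RecordFormatError(
            f"{base}.dat: expected {n_sig * n_samples} samples, found {raw.size}"
        )
    digital = raw.reshape(n_samples, n_sig).T.astype(float)
    physical = (digital - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    toco_idx = [i for i, d in enumerate(descs) if d.upper() == "TOCO"]
    if not toco_idx:
        raise RecordFormatError(f"{hea}: missing TOCO channel")
    ti = toco_idx[0]
    ehg_rows = [i for i in range(n_sig) if i != ti]
    annotations = []
    uc = base.with_suffix(".uc")
    if uc.exists():
        annotations = [ContractionAnnotation(float(ln)) for ln in open(uc) if ln.strip()]
    ga = meta.get("gestational_age")
    return EHGRecord(
        ehg=physical[ehg_rows],
        toco=physical[ti],
        fs=fs,
        annotations=annotations,
        recording_id=meta.get("recording_id", base.name),
        subject_id=meta.get("subject_id", ""),
        gestational_age=float(ga) if ga is not None else None,
    )


# ---------------------------------------------------------------------------
# Public interface
# ---------------------------------------------------------------------------

def write_record(record: EHGRecord, path: str | Path, format: str = "portable") -> None:
    """Write a record to disk in ``portable`` or ``wfdb`` format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "portable":
        _write_portable(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'portable' or 'wfdb'")


def read_record(path: str | Path, format: str = "portable", *, conformant: bool = True) -> EHGRecord:
    """Read a record; ``conformant=True`` enforces the 16-EHG-channel layout."""
    path = Path(path)
    if format == "portable":
        record = _read_portable(path)
    elif format == "wfdb":
        record = _read_wfdb(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'portable' or 'wfdb'")
    if conformant:
        record.validate_conformant()
    return record
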