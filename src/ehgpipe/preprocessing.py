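"""Downsampling and Butterworth bandpass filtering of EHG records.

The analysis chain decimates the 200 Hz acquisition-rate signals to 20 Hz
(anti-alias lowpass followed by integer decimation) and applies a 5th-order
Butterworth bandpass at 0.1-4 Hz — the band that carries uterine electrical
burst activity while rejecting baseline drift and high-frequency
interference. Filtering is zero-phase (forward-backward) by default so the
temporal alignment between EHG bursts and TOCO peaks, which the peak-anchored
segmentation relies on, is preserved; a causal single-pass mode is available.

The TOCO pressure trace is downsampled but not bandpass-filtered (its
near-DC bump shape would be destroyed by the 0.1 Hz high-pass edge).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .records import EHGRecord

__all__ = ["FilterSpec", "downsample", "bandpass", "preprocess_record"]


@dataclass
class FilterSpec:
    """Bandpass filter design: order-5 Butterworth analog prototype,
    bilinear-transformed to a digital bandpass (10 poles)."""

    order: int = 5
    passband: tuple[float, float] = (0.1, 4.0)
    target_fs: float = 20.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        self.passband = tuple(self.passband)
        lo, hi = self.passband
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if not (0 < lo < hi):
            raise ValueError(f"passband must satisfy 0 < low < high, got {self.passband}")
        if hi >= self.target_fs / 2:
            raise ValueError(
                f"passband high edge {hi} Hz must be below target Nyquist "
                f"{self.target_fs / 2} Hz"
            )

    def sos(self, fs: float) -> np.ndarray:
        if self.passband[1] >= fs / 2:
            raise ValueError(f"passband exceeds Nyquist for fs={fs}")
        return sps.butter(self.order, self.passband, btype="bandpass", fs=fs, output="sos")

    def response(self, freqs: np.ndarray | list[float], fs: float) -> np.ndarray:
        """Analytic magnitude response |H(f)| of the designed digital filter."""
        _, h = sps.sosfreqz(self.sos(fs), worN=2 * np.pi * np.asarray(freqs) / fs)
        mag = np.abs(h)
        return mag**2 if self.zero_phase else mag


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Integer-factor decimation with an anti-alias lowpass.

    ``fs_in`` must be an integer multiple of ``fs_out`` (200 -> 20 gives
    factor 10); resampling by interpolation is deliberately out of scope.
    The anti-alias filter is an 8th-order zero-phase Butterworth lowpass at
    0.8x the target Nyquist. Output length is floor(len(x)/factor).
    """
    ratio = fs_in / fs_out
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"fs_in={fs_in} must be an integer multiple of fs_out={fs_out}"
        )
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < factor:
        raise ValueError(f"signal length {x.shape[-1]} shorter than decimation factor {factor}")
    if factor == 1:
        return x.copy()
    sos = sps.butter(8, 0.8 * (fs_out / 2), btype="lowpass", fs=fs_in, output="sos")
    smoothed = sps.sosfiltfilt(sos, x, axis=-1)
    n_out = x.shape[-1] // factor
    return smoothed[..., : n_out * factor : factor]


def bandpass(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply the Butterworth bandpass; same length as the input."""
    x = np.asarray(x, dtype=float)
    sos = spec.sos(fs)
    # sosfiltfilt needs enough samples for its edge-padding warm-up
    padlen = 3 * (2 * sos.shape[0] + 1)
    if spec.zero_phase and x.shape[-1] <= padlen:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for zero-phase filtering "
            f"(needs > {padlen} samples)"
        )
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def preprocess_record(record: EHGRecord, spec: FilterSpec | None = None) -> EHGRecord:
    """Decimate to ``spec.target_fs`` and bandpass all EHG channels.

    Annotation times are in seconds and therefore unchanged; the TOCO trace
    is decimated only.
    """
    spec = spec or FilterSpec()
    ehg_ds = downsample(record.ehg, record.fs, spec.target_fs)
    toco_ds = downsample(record.toco, record.fs, spec.target_fs)
    ehg_f = bandpass(ehg_ds, spec, spec.target_fs)
    return EHGRecord(
        ehg=ehg_f,
        toco=toco_ds,
        fs=spec.target_fs,
        annotations=[replace(a) for a in record.annotations],
        recording_id=record.recording_id,
        subject_id=record.subject_id,
        gestational_age=record.gestational_age,
    )
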