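"""Synthetic 16-channel EHG + TOCO records with planted contractions.

The generator emulates the structure of the Icelandic 16-electrode EHG
database: 16 EHG channels sampled at 200 Hz, a simultaneous TOCO pressure
trace, and contraction annotations. Each planted contraction is a
band-limited Gaussian-noise burst (filtered white noise, not a pure tone, so
a downstream classifier cannot key on a single frequency) under a smooth
Gaussian envelope, present on all 16 channels with per-channel amplitude
variation. The TOCO trace is a train of raised-cosine bumps whose peaks may
be jittered relative to the EHG burst centers, mimicking the imperfect
synchronization between tocograph and EHG seen in real recordings.

Background activity between contractions is stationary colored noise (an
assumption: real inter-contraction EHG statistics are not characterized
here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import ContractionAnnotation, EHGRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "make_contraction_burst",
    "generate_record",
    "generate_dataset",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic EHG/TOCO world.

    Defaults describe a third-trimester-style monitoring session: 200 Hz
    acquisition, bursts concentrated in 0.3-1 Hz (inside the 0.1-4 Hz
    analysis band), ~40 s contraction envelopes separated by at least 240 s
    so that clean 60 s non-contraction windows exist between events, and a
    burst-vs-background SNR of 20 dB.
    """

    n_recordings: int = 3
    n_contractions_per_recording: int = 8
    record_duration: float = 2400.0  # seconds
    fs: float = 200.0
    burst_band: tuple[float, float] = (0.3, 1.0)
    burst_envelope_width: float = 40.0  # seconds
    inter_contraction_gap: float = 240.0  # minimum peak-to-peak spacing, seconds
    snr_db: float = 20.0
    toco_offset_jitter: float = 5.0  # seconds, uniform half-width
    toco_bump_width: float = 60.0  # raised-cosine base width, seconds
    seed: int = 0

    def __post_init__(self) -> None:
        self.burst_band = tuple(self.burst_band)
        lo, hi = self.burst_band
        if not (0 < lo < hi):
            raise ValueError(f"burst_band must satisfy 0 < low < high, got {self.burst_band}")
        if self.fs <= 2 * hi:
            raise ValueError(
                f"fs={self.fs} must exceed twice the burst band upper edge {hi}"
            )
        needed = self.n_contractions_per_recording * (
            self.burst_envelope_width + self.inter_contraction_gap
        )
        if self.record_duration < needed:
            raise ValueError(
                f"record_duration={self.record_duration}s cannot hold "
                f"{self.n_contractions_per_recording} contractions "
                f"(needs >= {needed}s)"
            )


@dataclass
class GroundTruth:
    """Planted truth for one record, used by recovery tests."""

    contraction_centers: list[float]
    toco_peak_times: list[float]
    channel_amplitudes: np.ndarray  # shape (16,)

    def __post_init__(self) -> None:
        if len(self.contraction_centers) != len(self.toco_peak_times):
            raise ValueError("contraction_centers and toco_peak_times must align")


def make_contraction_burst(
    duration: float,
    fs: float,
    band: tuple[float, float],
    envelope_width: float,
    seed: int,
) -> np.ndarray:
    """One zero-mean band-limited burst under a Gaussian envelope.

    The carrier is white Gaussian noise bandpassed to ``band`` (4th-order
    Butterworth, zero-phase); the envelope is a Gaussian with standard
    deviation ``envelope_width / 4`` centered mid-burst, so well over 90% of
    the energy lies in the central ``envelope_width`` seconds.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError(f"duration*fs must be >= 2 samples, got {n}")
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must lie strictly inside (0, fs/2={fs / 2})")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, white)
    t = np.arange(n) / fs
    center = duration / 2
    sigma = envelope_width / 4 if envelope_width > 0 else 0.0
    if sigma == 0:
        envelope = np.zeros(n)
    else:
        envelope = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    burst = carrier * envelope
    burst -= burst.mean()
    rms = np.sqrt(np.mean(burst**2))
    if rms > 0:
        burst /= rms
        burst *= envelope.max()  # unit peak-region RMS scale
    return burst


def _toco_bump(t: np.ndarray, peak: float, base_width: float) -> np.ndarray:
    """Raised-cosine pressure bump, amplitude 1 at the peak, support base_width."""
    half = base_width / 2
    x = (t - peak) / half
    bump = np.where(np.abs(x) < 1, 0.5 * (1 + np.cos(np.pi * x)), 0.0)
    return bump


def _place_centers(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Contraction centers: jittered regular spacing, honoring the minimum gap."""
    n = cfg.n_contractions_per_recording
    if n == 0:
        return np.empty(0)
    # margin keeps the burst, the TOCO bump and the +/-60 s positional grid
    # inside the record even after peak jitter
    margin = (
        max(1.5 * cfg.burst_envelope_width, cfg.toco_bump_width / 2, 60.0)
        + cfg.toco_offset_jitter
    )
    if n == 1:
        return np.array([cfg.record_duration / 2])
    # spacing chosen so centers +/- slack stay within [margin+slack, D-margin-slack]
    spacing = (cfg.record_duration - 2 * margin + cfg.inter_contraction_gap) / n
    if spacing < cfg.inter_contraction_gap:
        raise ValueError(
            f"cannot place {n} contractions {cfg.inter_contraction_gap}s apart "
            f"in {cfg.record_duration}s"
        )
    slack = (spacing - cfg.inter_contraction_gap) / 2
    centers = (margin + slack) + spacing * np.arange(n)
    centers += rng.uniform(-slack, slack, size=n)
    return centers


def generate_record(config: SyntheticConfig, seed: int) -> tuple[EHGRecord, GroundTruth]:
    """Generate one 16-channel EHG record with TOCO and annotations.

    ``seed`` fully determines the realization; the SNR is set so that the
    per-channel burst RMS (before the per-channel amplitude factor) is
    ``10**(snr_db/20)`` times the background-noise RMS.
    """
    rng = np.random.default_rng(seed)
    n = int(round(config.record_duration * config.fs))
    t = np.arange(n) / config.fs
    centers = _place_centers(config, rng)
    jitter = rng.uniform(
        -config.toco_offset_jitter, config.toco_offset_jitter, size=centers.size
    )
    toco_peaks = centers + jitter

    # stationary colored background: 1/f-type baseline wander (dominant, as
    # in real abdominal recordings after bandpass filtering) plus a small
    # broadband component for texture
    sos_slow = sps.butter(2, 0.3, btype="lowpass", fs=config.fs, output="sos")
    sos_fuzz = sps.butter(2, [1.5, 4.0], btype="bandpass", fs=config.fs, output="sos")
    noise_rms_target = 1.0
    burst_rms = noise_rms_target * 10 ** (config.snr_db / 20)
    amplitudes = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=16))

    ehg = np.empty((16, n))
    for ch in range(16):
        slow = sps.sosfiltfilt(sos_slow, rng.standard_normal(n))
        fuzz = sps.sosfiltfilt(sos_fuzz, rng.standard_normal(n))
        bg = slow / np.sqrt(np.mean(slow**2)) + 0.35 * fuzz / np.sqrt(np.mean(fuzz**2))
        bg *= noise_rms_target / np.sqrt(np.mean(bg**2))
        ehg[ch] = bg
    burst_dur = 3 * config.burst_envelope_width
    for ci, center in enumerate(centers):
        seed_burst = int(rng.integers(0, 2**31 - 1))
        # contraction durations vary between events, as in real tracings
        env_width = config.burst_envelope_width * rng.uniform(0.8, 1.2)
        for ch in range(16):
            burst = make_contraction_burst(
                burst_dur,
                config.fs,
                config.burst_band,
                env_width,
                seed=seed_burst + ch,
            )
            # rescale so central-region RMS hits the SNR target
            env_mask = np.abs(np.arange(burst.size) / config.fs - burst_dur / 2) <= (
                env_width / 2
            )
            rms = np.sqrt(np.mean(burst[env_mask] ** 2))
            burst *= burst_rms / rms * amplitudes[ch]
            i0 = int(round((center - burst_dur / 2) * config.fs))
            lo = max(i0, 0)
            hi = min(i0 + burst.size, n)
            ehg[ch, lo:hi] += burst[lo - i0 : hi - i0]

    toco = np.zeros(n)
    for peak in toco_peaks:
        toco += _toco_bump(t, peak, config.toco_bump_width)

    annotations = [ContractionAnnotation(float(p)) for p in np.sort(toco_peaks)]
    order = np.argsort(toco_peaks)
    truth = GroundTruth(
        contraction_centers=[float(c) for c in centers[order]],
        toco_peak_times=[float(p) for p in toco_peaks[order]],
        channel_amplitudes=amplitudes,
    )
    record = EHGRecord(
        ehg=ehg,
        toco=toco,
        fs=config.fs,
        annotations=annotations,
        recording_id=f"synthetic-{seed}",
        subject_id=f"subject-{seed}",
        gestational_age=float(rng.uniform(30, 40)),
    )
    return record, truth


def generate_dataset(config: SyntheticConfig) -> list[tuple[EHGRecord, GroundTruth]]:
    """Generate ``config.n_recordings`` records with seeds derived from config.seed."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(max(config.n_recordings, 1)) % (2**31 - 1)
    out = []
    for i in range(config.n_recordings):
        record, truth = generate_record(config, seed=int(seeds[i]))
        record.recording_id = f"rec{i:03d}"
        record.subject_id = f"subj{i:03d}"
        out.append((record, truth))
    return out
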