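"""TOCO-peak-anchored extraction of contraction / non-contraction segments.

A contraction (UC) segment is a window symmetric around a TOCO peak; the
standard training unit is 60 s (peak +/- 30 s). A non-contraction (non-UC)
segment of the same duration is taken at the midpoint between two adjacent
TOCO peaks, provided the gap is wide enough that the window stays clear of
both contractions.

For the positional analysis, the 120 s span [peak-60, peak+60) is tiled
three ways into fixed windows named ``<duration>_<side><index>``:

* twelve 10 s windows  10_L6..10_L1, 10_R1..10_R6
* six    20 s windows  20_L3..20_L1, 20_R1..20_R3
* four   30 s windows  30_L2..30_L1, 30_R1..30_R2

Index counts outward from the peak: ``d_L1`` touches the peak on the left
(``[peak-d, peak)``), ``d_R1`` starts at the peak (``[peak, peak+d)``).
All intervals are half-open; sample start index = round(start_time * fs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import ContractionAnnotation, EHGRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentWindow",
    "LabeledSegment",
    "position_grid",
    "extract_uc",
    "extract_nonuc",
    "extract_positional",
    "DEFAULT_GUARD",
]

UC = "UC"
NONUC = "nonUC"

#: Extra gap (s) required beyond the non-UC window duration before a between-
#: peaks window is accepted: gap >= duration + DEFAULT_GUARD. 120 s keeps a
#: 60 s midpoint window at least 60 s away from each peak, clear of the
#: whole positional grid span.
DEFAULT_GUARD = 120.0


@dataclass(frozen=True)
class SegmentWindow:
    """A named window at a fixed offset from an anchor (TOCO peak)."""

    label: str
    offset_start: float  # seconds relative to the anchor
    duration: float  # seconds

    @property
    def offset_end(self) -> float:
        return self.offset_start + self.duration

    def interval(self, anchor_time: float) -> tuple[float, float]:
        return (anchor_time + self.offset_start, anchor_time + self.offset_end)


@dataclass
class LabeledSegment:
    """One channel's samples for one window, with its class label."""

    samples: np.ndarray
    label: str  # UC or nonUC
    window_label: str
    channel_id: int  # 1..16
    recording_id: str
    subject_id: str
    anchor_time: float  # TOCO peak time (UC) or gap midpoint (nonUC)
    fs: float

    @property
    def group_key(self) -> tuple[str, float]:
        """Identifies the parent (recording, anchor) event across channels."""
        return (self.recording_id, self.anchor_time)


FULL_WINDOW = SegmentWindow("60", -30.0, 60.0)


def position_grid() -> list[SegmentWindow]:
    """The 22 positional windows tiling [peak-60, peak+60) per duration.

    For duration d and index k, ``d_Lk`` covers [peak-k*d, peak-(k-1)*d) and
    ``d_Rk`` covers [peak+(k-1)*d, peak+k*d).
    """
    windows: list[SegmentWindow] = []
    for d, n_side in ((10.0, 6), (20.0, 3), (30.0, 2)):
        for k in range(1, n_side + 1):
            windows.append(SegmentWindow(f"{int(d)}_L{k}", -k * d, d))
            windows.append(SegmentWindow(f"{int(d)}_R{k}", (k - 1) * d, d))
    return windows


def _slice_segment(
    record: EHGRecord,
    start_time: float,
    duration: float,
) -> np.ndarray | None:
    """Half-open slice [start, start+duration) on all channels, or None if out of bounds."""
    i0 = int(round(start_time * record.fs))
    n = int(round(duration * record.fs))
    if i0 < 0 or i0 + n > record.n_samples:
        return None
    return record.ehg[:, i0 : i0 + n]


def _make_segments(
    record: EHGRecord,
    start_time: float,
    duration: float,
    label: str,
    window_label: str,
    anchor_time: float,
) -> list[LabeledSegment]:
    block = _slice_segment(record, start_time, duration)
    if block is None:
        logger.info(
            "skipping %s window %r at anchor %.1fs of %s: [%.1f, %.1f) outside record",
            label,
            window_label,
            anchor_time,
            record.recording_id,
            start_time,
            start_time + duration,
        )
        return []
    return [
        LabeledSegment(
            samples=block[ch].copy(),
            label=label,
            window_label=window_label,
            channel_id=ch + 1,
            recording_id=record.recording_id,
            subject_id=record.subject_id,
            anchor_time=anchor_time,
            fs=record.fs,
        )
        for ch in range(record.n_channels)
    ]


def extract_uc(
    record: EHGRecord, peak_time: float, duration: float = 60.0
) -> list[LabeledSegment]:
    """Extract the UC window symmetric around one TOCO peak, on every channel.

    Returns 16 segments for a conformant record, or an empty list (with a
    logged reason) if the window would cross a record boundary.
    """
    window_label = str(int(duration)) if float(duration).is_integer() else str(duration)
    return _make_segments(
        record,
        peak_time - duration / 2,
        duration,
        UC,
        window_label,
        anchor_time=peak_time,
    )


def nonuc_anchors(
    annotations: list[ContractionAnnotation],
    duration: float = 60.0,
    guard: float = DEFAULT_GUARD,
) -> list[float]:
    """Midpoints of adjacent-peak gaps wide enough for a non-UC window.

    A gap between peaks p1 < p2 qualifies when p2 - p1 >= duration + guard.
    """
    peaks = sorted(a.peak_time for a in annotations)
    anchors = []
    for p1, p2 in zip(peaks, peaks[1:]):
        if p2 - p1 >= duration + guard:
            anchors.append((p1 + p2) / 2)
        else:
            logger.info(
                "skipping non-UC gap [%.1f, %.1f]: gap %.1fs < %.1fs",
                p1,
                p2,
                p2 - p1,
                duration + guard,
            )
    return anchors


def extract_nonuc(
    record: EHGRecord,
    annotations: list[ContractionAnnotation] | None = None,
    duration: float = 60.0,
    guard: float = DEFAULT_GUARD,
) -> list[LabeledSegment]:
    """Extract non-UC windows centered between adjacent contractions.

    Requires at least two annotations; gaps narrower than duration + guard
    are skipped with a log entry.
    """
    annotations = record.annotations if annotations is None else annotations
    if len(annotations) < 2:
        raise ValueError("non-UC extraction needs at least two annotations")
    window_label = str(int(duration)) if float(duration).is_integer() else str(duration)
    out: list[LabeledSegment] = []
    for mid in nonuc_anchors(annotations, duration, guard):
        out.extend(
            _make_segments(
                record, mid - duration / 2, duration, NONUC, window_label, anchor_time=mid
            )
        )
    return out


def extract_positional(
    record: EHGRecord,
    anchor_time: float,
    window: SegmentWindow,
    label: str = UC,
) -> list[LabeledSegment]:
    """Extract one positional window relative to an anchor, on every channel.

    For UC the anchor is the TOCO peak; for non-UC it is the gap midpoint,
    so each position label has matched examples of both classes.
    """
    start, _ = window.interval(anchor_time)
    return _make_segments(
        record, start, window.duration, label, window.label, anchor_time=anchor_time
    )
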