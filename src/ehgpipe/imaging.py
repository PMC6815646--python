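"""Rasterize waveform segments into fixed-size grayscale images.

Each extracted segment becomes the kind of image a clinician would see on a
strip chart: a dark trace on a plain light background, no axes or ticks.
The default raster is 482x482 pixels. Rendering is a pure deterministic
function of the samples:

* amplitude is min-max scaled per segment by default so the minimum maps to
  the bottom margin and the maximum to the top margin (5% margins); a
  constant segment renders as a centered horizontal line. Alternatively a
  fixed ``amplitude_range`` can be supplied (values outside it clip to the
  margins), which preserves amplitude contrast between segments — the
  pipeline uses a per-channel range derived from the whole recording so that
  windows of different durations remain comparable;
* time maps linearly to the horizontal axis;
* the trace is drawn 2 px thick on a double-resolution native raster
  (2*width x 2*height) with per-column vertical spans joining neighboring
  columns, then area-averaged down to the target size so the line is
  anti-aliased.

Intensities are in [0, 1]; background = 1 (white), trace = 0 (black).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .segmentation import LabeledSegment

__all__ = ["SegmentImage", "render_segment", "render_batch", "save_png", "load_png"]

DEFAULT_SIZE = 482
MARGIN = 0.05


@dataclass
class SegmentImage:
    """A rendered segment raster plus the metadata needed downstream."""

    pixels: np.ndarray  # (height, width) float32 in [0, 1]
    label: str  # UC / nonUC
    window_label: str
    channel_id: int
    recording_id: str
    subject_id: str
    anchor_time: float

    @property
    def group_key(self) -> tuple[str, float]:
        return (self.recording_id, self.anchor_time)


def _to_rows(values: np.ndarray, vmin: float, vmax: float, native_h: int) -> np.ndarray:
    """Map amplitudes to fractional row positions (max -> top margin)."""
    if vmax == vmin:
        frac = np.full(values.shape, 0.5)
    else:
        frac = (vmax - values) / (vmax - vmin)
    # snap away 1-ulp asymmetries so reversal == mirror holds exactly
    return np.round((MARGIN + (1 - 2 * MARGIN) * frac) * (native_h - 1), 6)


def _trace_spans(
    samples: np.ndarray,
    native_w: int,
    native_h: int,
    amplitude_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column fractional row span [low, high] of the drawn trace.

    The span combines (a) the linearly interpolated trace at column centers,
    joined to half-way toward each neighbor, and (b) for signals denser than
    the raster, the min/max envelope of every sample falling in the column
    (integer-exact binning), so dense high-frequency content renders as the
    filled band a strip-chart would show rather than being aliased away.
    """
    n = samples.size
    if amplitude_range is None:
        vmin = float(samples.min())
        vmax = float(samples.max())
    else:
        vmin, vmax = map(float, amplitude_range)
        if vmax < vmin:
            raise ValueError(f"invalid amplitude_range {amplitude_range}")
        samples = np.clip(samples, vmin, vmax)
    t = np.arange(native_w) * (n - 1) / (native_w - 1)
    rows = _to_rows(np.interp(t, np.arange(n), samples), vmin, vmax, native_h)

    mid_left = np.empty(native_w)
    mid_right = np.empty(native_w)
    mid_left[0] = rows[0]
    mid_left[1:] = (rows[:-1] + rows[1:]) / 2
    mid_right[-1] = rows[-1]
    mid_right[:-1] = mid_left[1:]
    lo = np.minimum(rows, np.minimum(mid_left, mid_right))
    hi = np.maximum(rows, np.maximum(mid_left, mid_right))

    if n >= native_w:
        r = _to_rows(samples, vmin, vmax, native_h)
        idx = np.arange(n)
        c0 = (idx * native_w) // n  # exact integer binning: mirror-symmetric
        c1 = ((idx + 1) * native_w - 1) // n
        for cc in (c0, c1):
            np.minimum.at(lo, cc, r)
            np.maximum.at(hi, cc, r)
    return lo, hi


def render_segment(
    segment: LabeledSegment | np.ndarray,
    width: int = DEFAULT_SIZE,
    height: int = DEFAULT_SIZE,
    amplitude_range: tuple[float, float] | None = None,
) -> SegmentImage:
    """Render one segment to a ``height x width`` grayscale raster."""
    if isinstance(segment, LabeledSegment):
        samples = np.asarray(segment.samples, dtype=float)
        meta = segment
    else:
        samples = np.asarray(segment, dtype=float)
        meta = None
    if samples.ndim != 1 or samples.size < 2:
        raise ValueError("segment must be a 1-D array of at least 2 samples")

    native_w, native_h = 2 * width, 2 * height
    span_lo, span_hi = _trace_spans(samples, native_w, native_h, amplitude_range)
    lo = np.clip(np.floor(span_lo).astype(int), 0, native_h - 1)
    hi = np.clip(np.floor(span_hi).astype(int) + 1, 0, native_h - 1)

    native = np.ones((native_h, native_w), dtype=np.float32)
    # column-wise fill via a cumulative marker array (vectorized interval paint)
    marks = np.zeros((native_h + 1, native_w), dtype=np.int32)
    np.add.at(marks, (lo, np.arange(native_w)), 1)
    np.add.at(marks, (hi + 1, np.arange(native_w)), -1)
    inked = np.cumsum(marks[:-1], axis=0) > 0
    native[inked] = 0.0

    pixels = native.reshape(height, 2, width, 2).mean(axis=(1, 3))
    return SegmentImage(
        pixels=pixels.astype(np.float32),
        label=meta.label if meta else "",
        window_label=meta.window_label if meta else "",
        channel_id=meta.channel_id if meta else 0,
        recording_id=meta.recording_id if meta else "",
        subject_id=meta.subject_id if meta else "",
        anchor_time=meta.anchor_time if meta else 0.0,
    )


def render_batch(
    segments: list[LabeledSegment],
    width: int = DEFAULT_SIZE,
    height: int = DEFAULT_SIZE,
    amplitude_ranges: dict[tuple[str, int], tuple[float, float]] | tuple | None = None,
) -> list[SegmentImage]:
    """Render a list of segments, order-preserving (one image per segment).

    ``amplitude_ranges`` may be a single (lo, hi) pair for all segments or a
    mapping from (recording_id, channel_id) to a per-channel pair; omitted
    entries fall back to per-segment min-max scaling.
    """
    out = []
    for s in segments:
        if isinstance(amplitude_ranges, dict):
            rng = amplitude_ranges.get((s.recording_id, s.channel_id))
        else:
            rng = amplitude_ranges
        out.append(render_segment(s, width, height, amplitude_range=rng))
    return out


def save_png(image: SegmentImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(np.round(image.pixels * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def load_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back to float [0, 1]."""
    from PIL import Image

    return np.asarray(Image.open(Path(path)).convert("L"), dtype=np.float32) / 255.0
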