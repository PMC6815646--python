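"""TOCO-peak-anchored windows: the positional grid and segment extraction."""

import numpy as np
import pytest

from ehgpipe.records import ContractionAnnotation, EHGRecord
from ehgpipe.segmentation import (
    SegmentWindow,
    extract_nonuc,
    extract_positional,
    extract_uc,
    nonuc_anchors,
    position_grid,
)


def _ramp_record(duration=700.0, fs=20.0, peaks=()):
    n = int(duration * fs)
    ehg = np.tile(np.arange(n, dtype=float), (16, 1))
    return EHGRecord(
        ehg=ehg,
        toco=np.zeros(n),
        fs=fs,
        annotations=[ContractionAnnotation(p) for p in peaks],
        recording_id="ramp",
        subject_id="s",
    )


class TestPositionGrid:
    def test_has_22_windows_with_expected_labels(self):
        grid = position_grid()
        assert len(grid) == 22
        labels = {w.label for w in grid}
        expected = (
            {f"10_L{k}" for k in range(1, 7)}
            | {f"10_R{k}" for k in range(1, 7)}
            | {f"20_L{k}" for k in range(1, 4)}
            | {f"20_R{k}" for k in range(1, 4)}
            | {f"30_L{k}" for k in range(1, 3)}
            | {f"30_R{k}" for k in range(1, 3)}
        )
        assert labels == expected

    def test_adjacency_convention(self):
        by_label = {w.label: w for w in position_grid()}
        assert by_label["10_L1"].interval(300.0) == (290.0, 300.0)
        assert by_label["10_R1"].interval(300.0) == (300.0, 310.0)
        assert by_label["20_L1"].interval(300.0) == (280.0, 300.0)
        assert by_label["30_R2"].interval(300.0) == (330.0, 360.0)

    @pytest.mark.parametrize("duration", [10, 20, 30])
    def test_each_duration_tiles_the_120s_span_disjointly(self, duration):
        wins = sorted(
            (w for w in position_grid() if w.duration == duration),
            key=lambda w: w.offset_start,
        )
        assert wins[0].offset_start == -60.0
        assert wins[-1].offset_end == 60.0
        for a, b in zip(wins, wins[1:]):
            assert a.offset_end == b.offset_start  # contiguous, no overlap

    def test_side_invariants(self):
        for w in position_grid():
            side = w.label.split("_")[1][0]
            if side == "L":
                assert w.offset_start < 0 and w.offset_end <= 0
            else:
                assert w.offset_start >= 0
            assert -60 <= w.offset_start and w.offset_end <= 60


class TestExtractUC:
    def test_symmetric_window_indices_and_count(self):
        record = _ramp_record(peaks=[300.0])
        segs = extract_uc(record, 300.0, 60.0)
        assert len(segs) == 16
        for seg in segs:
            assert seg.samples.size == 1200
            assert seg.samples[0] == 270 * 20  # starts at peak-30s
            assert seg.label == "UC" and seg.window_label == "60"
        assert {s.channel_id for s in segs} == set(range(1, 17))

    def test_out_of_bounds_window_skipped(self):
        record = _ramp_record(duration=100.0)
        assert extract_uc(record, 20.0, 60.0) == []

    def test_group_key_shared_across_channels(self):
        record = _ramp_record(peaks=[300.0])
        segs = extract_uc(record, 300.0, 60.0)
        assert len({s.group_key for s in segs}) == 1


class TestExtractNonUC:
    def test_gap_midpoint_window(self):
        record = _ramp_record(peaks=[300.0, 500.0])
        segs = extract_nonuc(record, duration=60.0, guard=60.0)
        assert len(segs) == 16
        assert segs[0].anchor_time == 400.0
        assert segs[0].samples[0] == 370 * 20  # interval [370, 430)
        assert all(s.label == "nonUC" for s in segs)

    def test_narrow_gap_skipped(self):
        record = _ramp_record(peaks=[300.0, 380.0])
        assert extract_nonuc(record, duration=60.0, guard=60.0) == []

    def test_requires_two_annotations(self):
        record = _ramp_record(peaks=[300.0])
        with pytest.raises(ValueError, match="two annotations"):
            extract_nonuc(record)

    def test_synthetic_record_yields_one_candidate_per_gap(self, small_record):
        record, truth = small_record
        anchors = nonuc_anchors(record.annotations, 60.0)
        assert len(anchors) == len(truth.toco_peak_times) - 1

    def test_nonuc_never_overlaps_uc_windows(self, small_record):
        record, _ = small_record
        segs = extract_nonuc(record)
        peaks = [a.peak_time for a in record.annotations]
        for s in segs[:: record.n_channels]:
            lo, hi = s.anchor_time - 30.0, s.anchor_time + 30.0
            for p in peaks:
                assert hi <= p - 30.0 or lo >= p + 30.0


class TestExtractPositional:
    def test_window_arithmetic(self):
        record = _ramp_record(peaks=[300.0])
        w20 = SegmentWindow("20_L1", -20.0, 20.0)
        segs = extract_positional(record, 300.0, w20)
        assert segs[0].samples.size == 400
        assert segs[0].samples[0] == 280 * 20
        w30 = SegmentWindow("30_R2", 30.0, 30.0)
        segs = extract_positional(record, 300.0, w30)
        assert segs[0].samples.size == 600
        assert segs[0].samples[0] == 330 * 20

    def test_full_grid_at_one_peak_gives_352_segments(self):
        record = _ramp_record(peaks=[300.0])
        segs = [
            s for w in position_grid() for s in extract_positional(record, 300.0, w)
        ]
        assert len(segs) == 22 * 16

    def test_sample_count_exactness(self):
        record = _ramp_record(peaks=[300.0])
        for w in position_grid():
            for s in extract_positional(record, 300.0, w):
                assert s.samples.size == int(w.duration * 20)
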