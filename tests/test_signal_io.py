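import numpy as np
import pytest

from visimax import (
    BurstSegment,
    ParseError,
    SegmentationParams,
    TimeSeries,
    auto_segment,
    downsample,
    read_series,
    write_segments,
)


def _write(tmp_path, text, name="series.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSeries:
    def test_one_column_gets_index_time(self, tmp_path):
        s = read_series(_write(tmp_path, "1\n1.3\n1.7\n"))
        assert s.points() == [(0, 1.0), (1, 1.3), (2, 1.7)]

    def test_two_column_worked_example(self, tmp_path, worked_series):
        text = "\n".join(f"{t},{y}" for t, y in worked_series.points())
        s = read_series(_write(tmp_path, text))
        assert s.points() == worked_series.points()

    def test_whitespace_delimiter(self, tmp_path):
        s = read_series(_write(tmp_path, "0 1\n1 2\n", name="series.txt"))
        assert s.points() == [(0, 1.0), (1, 2.0)]

    def test_duplicate_time_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="strictly increasing"):
            read_series(_write(tmp_path, "0,1\n0,2\n"))

    def test_single_header_skipped_two_headers_fail(self, tmp_path):
        s = read_series(_write(tmp_path, "time,amp\n0,1\n1,2\n"))
        assert len(s) == 2
        with pytest.raises(ParseError, match="line 2"):
            read_series(_write(tmp_path, "time,amp\nt,a\n0,1\n"))

    def test_non_numeric_row_reports_line(self, tmp_path):
        with pytest.raises(ParseError, match="line 3"):
            read_series(_write(tmp_path, "0,1\n1,2\nx,y\n"))

    def test_empty_file(self, tmp_path):
        with pytest.raises(ParseError, match="no numeric data"):
            read_series(_write(tmp_path, "\n\n"))

    def test_format_mismatch(self, tmp_path):
        with pytest.raises(ParseError):
            read_series(_write(tmp_path, "0,1\n1,2\n"), format="one-column")


class TestTimeSeries:
    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            TimeSeries(np.array([0.0, 1.0]), np.array([np.nan, 1.0]))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            TimeSeries(np.array([0.0, 1.0]), np.array([1.0]))


class TestDownsample:
    def test_full_percent_is_identity(self, worked_series):
        out = downsample(worked_series, 100)
        assert out.points() == worked_series.points()

    def test_stride_two(self, worked_series):
        out = downsample(worked_series, 50)
        assert out.t.tolist() == [0, 2, 4, 6]

    def test_five_percent_is_stride_twenty(self):
        s = TimeSeries.from_amplitudes(np.arange(40.0))
        out = downsample(s, 5)
        assert out.t.tolist() == [0, 20]

    @pytest.mark.parametrize("percent", [0, -5, 100.5])
    def test_domain_errors(self, worked_series, percent):
        with pytest.raises(ValueError):
            downsample(worked_series, percent)

    def test_halving_twice_equals_quarter(self):
        s = TimeSeries.from_amplitudes(np.random.default_rng(0).normal(size=64))
        twice = downsample(downsample(s, 50), 50)
        assert twice.points() == downsample(s, 25).points()


def _pulse_train(peaks, n=400, width=10, height=2.0):
    y = np.zeros(n)
    for p in peaks:
        lo, hi = max(0, p - width), min(n, p + width)
        x = np.arange(lo, hi)
        y[lo:hi] += height * np.exp(-0.5 * ((x - p) / (width / 3)) ** 2)
    return TimeSeries.from_amplitudes(y)


class TestAutoSegment:
    params = SegmentationParams(
        upper_threshold=1.0, lower_threshold=0.2, segment_width=40,
        min_peak_distance=30,
    )

    def test_flat_series_yields_nothing(self):
        s = TimeSeries.from_amplitudes(np.zeros(100))
        assert auto_segment(s, self.params) == []

    def test_three_disjoint_bursts(self):
        s = _pulse_train([80, 200, 320])
        segs = auto_segment(s, self.params)
        assert len(segs) == 3
        for seg, peak in zip(segs, [80, 200, 320]):
            assert seg.source_offset <= peak < seg.source_offset + len(seg.points)
            assert seg.points.y.max() >= self.params.upper_threshold

    def test_close_peaks_suppressed_to_larger(self):
        y = np.zeros(100)
        y[40] = 1.5
        y[45] = 2.5
        s = TimeSeries.from_amplitudes(y)
        params = SegmentationParams(1.0, 0.2, 20, 10)
        segs = auto_segment(s, params)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.source_offset <= 45 < seg.source_offset + len(seg.points)

    def test_no_lower_crossing_merges_bursts(self):
        # two peaks above upper threshold on a pedestal that never drops
        # below the lower threshold: the later window is discarded
        y = np.full(200, 0.5)
        y[60] = 2.0
        y[140] = 1.8
        s = TimeSeries.from_amplitudes(y)
        params = SegmentationParams(1.0, 0.2, 30, 20)
        assert len(auto_segment(s, params)) == 1

    def test_count_monotone_in_upper_threshold(self):
        rng = np.random.default_rng(3)
        s = _pulse_train(list(range(50, 1000, 90)), n=1050)
        s = TimeSeries(s.t, s.y + rng.normal(0, 0.02, len(s)))
        counts = []
        for upper in (0.5, 1.0, 1.5, 1.9, 2.5):
            params = SegmentationParams(upper, 0.2, 40, 30)
            counts.append(len(auto_segment(s, params)))
        assert counts == sorted(counts, reverse=True)

    def test_segments_ordered_and_disjoint(self):
        s = _pulse_train([60, 120, 180], n=240)
        segs = auto_segment(s, SegmentationParams(1.0, 0.2, 80, 30))
        ends = [seg.source_offset + len(seg.points) for seg in segs]
        starts = [seg.source_offset for seg in segs]
        assert starts == sorted(starts)
        assert all(e <= s2 for e, s2 in zip(ends, starts[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(0.1, 0.2, 40, 30)
        with pytest.raises(ValueError):
            SegmentationParams(1.0, 0.2, 1, 30)
        with pytest.raises(ValueError):
            SegmentationParams(1.0, 0.2, 40, 0)


def test_write_segments_manifest(tmp_path):
    s = _pulse_train([80, 200])
    params = SegmentationParams(1.0, 0.2, 40, 30)
    segs = auto_segment(s, params)
    manifest = write_segments(segs, tmp_path / "out", source="x.csv", params=params)
    assert len(manifest["segments"]) == len(segs) == 2
    assert (tmp_path / "out" / "segments.json").exists()
    first = manifest["segments"][0]
    assert (tmp_path / "out" / first["file"]).exists()
    assert first["source_offset"] == segs[0].source_offset
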