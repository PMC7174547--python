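"""Reading, decimating and segmenting electrophysiological time series.

Recordings arrive as plain text with one numeric column (amplitude; the
sample index becomes the time axis) or two columns (time, amplitude),
separated by commas or whitespace.  A single non-numeric header line is
tolerated and skipped with a warning.

Downsampling is plain decimation: asking for ``percent`` of the original
sampling frequency keeps every k-th sample with ``k = round(100/percent)``.
No anti-alias filtering is applied — the visibility criterion compares raw
amplitudes, so the kept samples must be exact values from the input.

``auto_segment`` cuts a recording into candidate bursts from four
parameters: an upper amplitude threshold (a burst must peak above it), a
lower threshold (the trace must fall below it between two bursts for them
to count as separate events), a fixed window width, and a minimum distance
between peaks.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

_DELIM = re.compile(r"[,\s]+")


class ParseError(ValueError):
    """A recording file could not be parsed as numeric columns."""


@dataclass(frozen=True)
class TimeSeries:
    """Finite (t, y) samples with strictly increasing time.

    Parameters
    ----------
    t : array-like of float
        Sample times, strictly increasing. Arbitrary units.
    y : array-like of float
        Amplitudes, same length as ``t``. Arbitrary units.
    """

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if t.size and not (np.isfinite(t).all() and np.isfinite(y).all()):
            raise ValueError("time series contains non-finite values")
        if t.size >= 2 and not (np.diff(t) > 0).all():
            raise ValueError("time values must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @classmethod
    def from_amplitudes(cls, y) -> "TimeSeries":
        """Build a series from amplitudes alone; t becomes 0, 1, 2, ..."""
        y = np.asarray(y, dtype=float)
        return cls(np.arange(y.size, dtype=float), y)

    def slice(self, start: int, stop: int) -> "TimeSeries":
        """Contiguous sub-series [start, stop)."""
        return TimeSeries(self.t[start:stop], self.y[start:stop])

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.t.tolist(), self.y.tolist()))


@dataclass(frozen=True)
class SegmentationParams:
    """The four auto-segmentation inputs.

    ``segment_width`` and ``min_peak_distance`` are in samples.
    """

    upper_threshold: float
    lower_threshold: float
    segment_width: int
    min_peak_distance: int

    def __post_init__(self) -> None:
        if not self.upper_threshold > self.lower_threshold:
            raise ValueError("upper_threshold must exceed lower_threshold")
        if self.segment_width < 2:
            raise ValueError("segment_width must be at least 2 samples")
        if self.min_peak_distance < 1:
            raise ValueError("min_peak_distance must be at least 1 sample")


@dataclass(frozen=True)
class BurstSegment:
    """A contiguous slice of a parent recording holding one candidate burst."""

    source_offset: int
    points: TimeSeries
    label: str | None = None


def read_series(path, format: str = "auto") -> TimeSeries:
    """Read a one- or two-column plain-text recording.

    Parameters
    ----------
    path : path-like
        ``.txt`` or ``.csv`` file, comma- or whitespace-delimited.
    format : {"auto", "one-column", "two-column"}
        Expected layout; ``auto`` infers it from the first numeric row.

    Returns
    -------
    TimeSeries
        One-column input gets t = 0, 1, 2, ...; two-column input uses
        column 1 as time and column 2 as amplitude.
    """
    if format not in {"auto", "one-column", "two-column"}:
        raise ValueError(f"unknown format {format!r}")
    rows: list[list[float]] = []
    header_skipped = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f for f in _DELIM.split(line) if f]
            try:
                values = [float(f) for f in fields]
            except ValueError:
                if not rows and not header_skipped:
                    header_skipped = True
                    logger.warning(
                        "%s: skipping non-numeric header at line %d", path, lineno
                    )
                    continue
                raise ParseError(
                    f"{path}: non-numeric row at line {lineno}: {line!r}"
                ) from None
            if len(values) not in (1, 2):
                raise ParseError(
                    f"{path}: expected 1 or 2 columns at line {lineno}, "
                    f"got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no numeric data")
    widths = {len(v) for v in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: inconsistent column count across rows")
    ncols = widths.pop()
    if format == "one-column" and ncols != 1:
        raise ParseError(f"{path}: expected one column, found {ncols}")
    if format == "two-column" and ncols != 2:
        raise ParseError(f"{path}: expected two columns, found {ncols}")
    data = np.asarray(rows, dtype=float)
    if ncols == 1:
        return TimeSeries.from_amplitudes(data[:, 0])
    return TimeSeries(data[:, 0], data[:, 1])


def write_series(series: TimeSeries, path) -> None:
    """Write a series as two-column CSV (time, amplitude)."""
    np.savetxt(
        path,
        np.column_stack([series.t, series.y]),
        delimiter=",",
        fmt="%.10g",
    )


def downsample(series: TimeSeries, percent: float) -> TimeSeries:
    """Reduce the sampling frequency to ``percent`` of the original.

    Keeps samples at positions 0, k, 2k, ... with k = round(100/percent),
    ties rounding half away from zero. Kept samples retain their original
    t and y values.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    k = max(1, math.floor(100.0 / percent + 0.5))
    return TimeSeries(series.t[::k], series.y[::k])


def auto_segment(series: TimeSeries, params: SegmentationParams) -> list[BurstSegment]:
    """Cut a recording into candidate burst windows.

    The procedure: (1) local maxima with amplitude >= ``upper_threshold``
    are candidate peaks; (2) peaks are kept greedily in decreasing
    amplitude order, discarding any peak within ``min_peak_distance``
    samples of an already-kept one; (3) a peak is retained only if the
    trace falls strictly below ``lower_threshold`` somewhere between it
    and the previously retained peak (otherwise the two are not separate
    bursts and the later one is dropped); (4) each retained peak gets a
    window of ``segment_width`` samples centred on it, clipped at the
    recording bounds, and overlapping windows are truncated at the
    midpoint between their peaks.

    Returns segments ordered by position; an empty list when nothing
    crosses the upper threshold.
    """
    y = series.y
    peaks, _ = find_peaks(
        y, height=params.upper_threshold, distance=params.min_peak_distance
    )
    if peaks.size == 0:
        return []
    retained: list[int] = [int(peaks[0])]
    for p in peaks[1:]:
        gap = y[retained[-1] + 1 : p]
        if gap.size and gap.min() < params.lower_threshold:
            retained.append(int(p))
        else:
            logger.warning(
                "discarding peak at sample %d: trace never falls below the "
                "lower threshold after the peak at %d",
                p,
                retained[-1],
            )
    n = len(series)
    half = params.segment_width // 2
    windows = []
    for p in retained:
        start = max(0, p - half)
        stop = min(n, p - half + params.segment_width)
        windows.append([start, stop])
    for i in range(len(retained) - 1):
        if windows[i][1] > windows[i + 1][0]:
            mid = (retained[i] + retained[i + 1] + 1) // 2
            windows[i][1] = min(windows[i][1], mid)
            windows[i + 1][0] = max(windows[i + 1][0], mid)
    return [
        BurstSegment(source_offset=s, points=series.slice(s, e))
        for s, e in windows
    ]


def write_segments(
    segments: list[BurstSegment],
    out_dir,
    source=None,
    params: SegmentationParams | None = None,
) -> dict:
    """Write per-segment two-column CSVs plus a JSON manifest.

    Returns the manifest dict (also written to ``segments.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, seg in enumerate(segments):
        name = f"segment_{i:03d}.csv"
        write_series(seg.points, out / name)
        entries.append(
            {
                "file": name,
                "source_offset": int(seg.source_offset),
                "n_samples": len(seg.points),
                "label": seg.label,
            }
        )
    manifest = {
        "source": str(source) if source is not None else None,
        "params": asdict(params) if params is not None else None,
        "segments": entries,
    }
    (out / "segments.json").write_text(json.dumps(manifest, indent=2))
    return manifest
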