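"""Synthetic respiratory-rhythm recordings with known burst labels.

The generator emulates integrated hypoglossal (XII) nerve activity driven
by the pre-Botzinger complex: a normal monophasic inspiratory burst
("non-sigh") every 7-8 s, a larger biphasic burst ("sigh") replacing the
ordinary burst every 30-40 s, individual burst durations of 0.3-0.8 s,
all riding on low-amplitude baseline noise.

Waveform shapes are this package's own construction; only the timing, the
duration range, the amplitude ordering and the biphasic character of sighs
are physiologically prescribed:

* A non-sigh is a raised-cosine dome (``bump(t)**dome_power``) modulated
  by a gentle scallop: convex sub-lobes meeting at cusps every
  ``scallop_period`` seconds, emulating the sub-bursts of motor-unit
  recruitment within an ordinary inspiratory burst.  Each convex lobe
  collapses into a single large maxclique of the visibility graph, so
  non-sigh graphs have few maxcliques and a small, stable maxclique
  graph; the scallop curvature also keeps the waveform's local geometry
  well above the noise floor everywhere, which makes the graph features
  insensitive to the noise draw.
* A sigh is a broad flat-topped envelope (lengthened by the biphasic gap)
  carrying a smaller leading hump and a tall, narrow main peak, plus a
  band-limited stochastic *ripple* over the whole burst.  The ripple
  models the many small fluctuations that distinguish sighs from
  ordinary bursts in integrated nerve recordings; its local RMS is
  normalised so every sigh carries comparable fluctuation density.  This
  texture fragments a sigh's visibility graph into many small
  overlapping maxcliques, the signature the downstream classifier keys
  on.

All randomness flows through one ``numpy`` Generator seeded from
``SynthConfig.seed``.  Draw order per burst is fixed (duration, then
amplitude, then ripple, then additive noise) so fixtures stay stable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .signal_io import BurstSegment, SegmentationParams, TimeSeries, write_series

SIGH = "sigh"
NON_SIGH = "non-sigh"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic rhythm generator.

    Amplitude fields are (mean, jitter sd) pairs in arbitrary integrated-
    activity units; intervals and durations are (low, high) ranges in
    seconds, drawn uniformly.

    Notes
    -----
    ``sampling_rate`` defaults to 4 kHz, a typical acquisition rate for
    nerve recordings; after the usual reduction to 5% of the sampling
    frequency a one-burst analysis window holds ~60 samples.
    ``sigh_ripple`` is the ripple amplitude relative to the sigh's peak
    amplitude, and ``ripple_corr`` its correlation time in seconds.
    """

    sampling_rate: float = 4000.0
    duration: float = 60.0
    nonsigh_interval: tuple[float, float] = (7.0, 8.0)
    sigh_interval: tuple[float, float] = (30.0, 40.0)
    burst_duration: tuple[float, float] = (0.3, 0.8)
    nonsigh_amplitude: tuple[float, float] = (1.0, 0.1)
    sigh_amplitude: tuple[float, float] = (2.5, 0.25)
    sigh_biphasic_gap: float = 0.15
    sigh_ripple: float = 0.2
    ripple_corr: float = 0.015
    dome_power: float = 1.5
    nonsigh_scallop: float = 0.15
    scallop_period: float = 0.03
    noise_sd: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nonsigh_interval", "sigh_interval", "burst_duration"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an increasing positive range")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.sigh_amplitude[0] <= self.nonsigh_amplitude[0]:
            raise ValueError("mean sigh amplitude must exceed non-sigh amplitude")
        if self.noise_sd < 0 or self.sigh_ripple < 0:
            raise ValueError("noise_sd and sigh_ripple must be non-negative")
        if not 0 < self.sigh_biphasic_gap < 0.5:
            raise ValueError("sigh_biphasic_gap must be a fraction in (0, 0.5)")
        if self.ripple_corr <= 0 or self.scallop_period <= 0:
            raise ValueError("ripple_corr and scallop_period must be positive")
        if not 0 <= self.nonsigh_scallop < 1:
            raise ValueError("nonsigh_scallop must be a fraction in [0, 1)")


@dataclass(frozen=True)
class LabeledRecording:
    """A synthetic recording plus its ground truth.

    ``truth`` holds one (onset sample index, label) pair per burst, in
    temporal order.
    """

    series: TimeSeries
    truth: tuple[tuple[int, str], ...]


def _bump(x: np.ndarray) -> np.ndarray:
    """Raised-cosine dome on [0, 1], zero outside, peak 1 at x = 0.5."""
    return np.where(
        (x >= 0) & (x <= 1), 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(x, 0, 1))), 0.0
    )


def _textured_noise(rng: np.random.Generator, n: int, corr_samples: int) -> np.ndarray:
    """Smooth stochastic ripple with unit local RMS.

    Gaussian noise is low-pass filtered to the requested correlation
    length, then divided by its own local RMS so the fluctuation density
    is uniform along the burst (no stretch of a sigh is accidentally
    smooth).
    """
    corr_samples = max(corr_samples, 1)
    u = gaussian_filter1d(rng.normal(0.0, 1.0, n), corr_samples)
    local_rms = np.sqrt(gaussian_filter1d(u * u, 5 * corr_samples))
    return u / np.maximum(local_rms, 1e-12)


def _sigh_envelope(xt: np.ndarray, gap: float) -> np.ndarray:
    """Unit-peak biphasic sigh envelope on normalised time xt in [0, 1].

    A flat-topped plateau carries a leading hump (peak at 0.5 - gap) and
    a taller, narrow main peak at 0.5; with the ripple and noise off the
    envelope has exactly two local maxima above half-maximum.  The main
    peak is narrow so that a fixed analysis window centred on it is
    dominated by the rippled plateau rather than by the peak itself.
    """
    plateau = 0.5 * _bump(xt) ** 0.3
    first = 0.3 * _bump((xt - (0.4 - gap)) / 0.25)
    main = 0.5 * _bump((xt - 0.45) / 0.1) ** 2
    return plateau + first + main


def make_burst(label: str, config: SynthConfig, rng: np.random.Generator) -> TimeSeries:
    """Draw one burst waveform (times start at 0, step 1/sampling_rate).

    A non-sigh is a single unimodal dome of the drawn duration and
    amplitude, carrying the gentle scallop modulation (set
    ``nonsigh_scallop=0`` for the bare smooth pulse).  A sigh is the
    biphasic envelope (lengthened by the biphasic gap, so it is both
    taller and longer than a non-sigh) plus the stochastic ripple scaled
    by ``sigh_ripple`` and tapered to the burst's extent (set
    ``sigh_ripple=0`` for the bare envelope).  Zero-mean Gaussian noise
    of sd ``noise_sd`` is added to either waveform.
    """
    fs = config.sampling_rate
    d = rng.uniform(*config.burst_duration)
    if label == NON_SIGH:
        amp = abs(rng.normal(*config.nonsigh_amplitude))
        n = max(int(round(d * fs)), 4)
        x = np.arange(n) / (d * fs)
        t = np.arange(n) / fs
        # garland modulation: convex lobes between cusps, unit at the cusps
        fest = 4.0 * (np.mod(t / config.scallop_period, 1.0) - 0.5) ** 2
        scallop = 1.0 - config.nonsigh_scallop + config.nonsigh_scallop * fest
        y = amp * _bump(x) ** config.dome_power * scallop
    elif label == SIGH:
        amp = abs(rng.normal(*config.sigh_amplitude))
        gap = config.sigh_biphasic_gap
        n = max(int(round(d * (1.0 + gap) * fs)), 8)
        xt = np.arange(n) / (n - 1)
        env = amp * _sigh_envelope(xt, gap)
        ripple = _textured_noise(rng, n, int(round(config.ripple_corr * fs)))
        taper = np.clip(env / (0.15 * amp), 0.0, 1.0)
        y = env + config.sigh_ripple * amp * ripple * taper
    else:
        raise ValueError(f"unknown burst label {label!r}")
    y = y + rng.normal(0.0, config.noise_sd, y.size)
    return TimeSeries(np.arange(y.size) / fs, y)


def make_recording(config: SynthConfig) -> LabeledRecording:
    """Assemble a labelled recording from the configured timing statistics.

    Non-sigh bursts are spaced by uniform draws from ``nonsigh_interval``;
    an independent sigh clock advances by draws from ``sigh_interval``,
    and whenever a burst slot falls due past the sigh clock that slot
    becomes a sigh (sighs replace, not add to, the ordinary rhythm).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_total = int(round(config.duration * fs))
    y = rng.normal(0.0, config.noise_sd, n_total)
    next_sigh = rng.uniform(*config.sigh_interval)
    t_next = rng.uniform(*config.nonsigh_interval)
    truth: list[tuple[int, str]] = []
    prev_end = -1
    while True:
        label = SIGH if t_next >= next_sigh else NON_SIGH
        onset = int(round(t_next * fs))
        burst = make_burst(label, config, rng)
        if onset + len(burst) > n_total:
            break
        if onset <= prev_end:
            raise ValueError(
                "bursts overlap at this configuration; lengthen the "
                "inter-burst intervals or shorten burst_duration"
            )
        y[onset : onset + len(burst)] += burst.y
        truth.append((onset, label))
        prev_end = onset + len(burst) - 1
        if label == SIGH:
            next_sigh += rng.uniform(*config.sigh_interval)
        t_next += rng.uniform(*config.nonsigh_interval)
    if not truth:
        raise ValueError(
            "duration too short for a single burst; increase `duration`"
        )
    return LabeledRecording(
        series=TimeSeries(np.arange(n_total) / fs, y),
        truth=tuple(truth),
    )


def default_segmentation(config: SynthConfig) -> SegmentationParams:
    """Segmentation parameters matched to the generator's scales.

    The upper threshold sits at half the mean non-sigh amplitude and the
    lower threshold just above the baseline noise.  The window width
    equals the shortest burst duration, so windows stay inside their
    bursts (a stretch of burst-free baseline inside a window would add
    spurious clique structure).  Peak separation is half the shortest
    inter-burst interval.
    """
    fs = config.sampling_rate
    return SegmentationParams(
        upper_threshold=0.5 * config.nonsigh_amplitude[0],
        lower_threshold=max(3.0 * config.noise_sd, 0.01 * config.nonsigh_amplitude[0]),
        segment_width=int(round(config.burst_duration[0] * fs)),
        min_peak_distance=int(round(0.5 * config.nonsigh_interval[0] * fs)),
    )


def match_truth(
    segments: list[BurstSegment], recording: LabeledRecording
) -> list[str]:
    """Ground-truth label for each segment.

    A segment takes the label of the true burst whose onset falls inside
    its window; if none does, the nearest onset to the window centre.
    """
    onsets = np.array([o for o, _ in recording.truth])
    labels = [lab for _, lab in recording.truth]
    out = []
    for seg in segments:
        start = seg.source_offset
        stop = start + len(seg.points)
        inside = np.flatnonzero((onsets >= start) & (onsets < stop))
        if inside.size:
            idx = int(inside[0])
        else:
            idx = int(np.argmin(np.abs(onsets - (start + stop) / 2)))
        out.append(labels[idx])
    return out


def write_recording(
    recording: LabeledRecording, out_dir, config: SynthConfig | None = None
) -> None:
    """Write recording.csv (two columns) and truth.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_series(recording.series, out / "recording.csv")
    payload = {
        "truth": [{"onset": int(o), "label": lab} for o, lab in recording.truth],
        "config": asdict(config) if config is not None else None,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
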