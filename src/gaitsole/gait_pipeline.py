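"""vGRF gait-analysis pipeline.

From a raw 16-channel insole recording to gait statistics:

1. **Reconstruction** — each channel's ADC code is mapped back through the
   divider to a resistance and through the fitted power law to a weight;
   the 16 channels are summed per sample into one vGRF trace (kg).
2. **Body-weight normalization** — the subject stands on one foot for a few
   seconds; if the measured mean under-reads the known body weight the
   trace is scaled up by the ratio (never down).
3. **Segmentation** — stance phases are maximal runs of consecutive
   above-threshold samples; the first and last cycles of a trial are
   discarded as gait initiation/termination.
4. **Time normalization** — every stance segment is linearly resampled onto
   a common 512-point grid so cycles of different duration can be averaged.
5. **Ensemble statistics and metrics** — pointwise mean ± SD across cycles,
   peak/valley values and timings, stance fraction of the stride, and a
   left/right symmetry index.

A piezo-insole trace yields a single event per stance (no static response),
so the pipeline can also turn such traces into gait start/end event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .calibration import FsrCalibration, fsr_weight
from .insole_sim import InsoleRecording
from .signal_chain import AdcConfig, DividerConfig, adc_dequantize, fsr_divider_inverse

__all__ = [
    "VgrfTrace",
    "StanceSegment",
    "EnsembleStats",
    "GaitMetrics",
    "reconstruct_vgrf",
    "bodyweight_scale_factor",
    "segment_gait",
    "resample_segment",
    "ensemble_stats",
    "gait_metrics",
    "symmetry_index",
    "detect_events_piezo",
]

N_POINTS_DEFAULT = 512


@dataclass
class VgrfTrace:
    """A single-foot vGRF time series in kg."""

    foot: str
    time: np.ndarray
    vgrf: np.ndarray
    sampling_rate: float
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vgrf = np.asarray(self.vgrf, dtype=float)
        if self.time.size != self.vgrf.size:
            raise ValueError("time and vgrf lengths differ")
        if np.any(self.vgrf < 0):
            raise ValueError("vgrf must be non-negative")


@dataclass
class StanceSegment:
    """One stance phase cut out of a vGRF trace."""

    start: int           # index of first above-threshold sample
    end: int             # exclusive index past the last one
    samples: np.ndarray  # kg

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class EnsembleStats:
    """Pointwise mean and sample SD of time-normalized stance cycles."""

    mean: np.ndarray
    sd: np.ndarray
    n_segments: int


@dataclass
class GaitMetrics:
    """Scalar gait variables for one foot (times as % of stance)."""

    stance_fraction: float        # % of stride spent in stance
    time_to_first_peak: float     # % of stance
    time_to_second_peak: float    # % of stance
    peak1: float                  # kg
    valley: float                 # kg
    peak2: float                  # kg
    shape_atypical: bool = False  # ensemble mean lacks the two-peak shape
    symmetry_index: float | None = None  # %, filled when both feet compared


def reconstruct_vgrf(
    rec: InsoleRecording,
    cal: FsrCalibration,
    chain: DividerConfig,
    adc: AdcConfig,
) -> VgrfTrace:
    """Sum the per-channel weights recovered from raw codes into one vGRF.

    Per channel: code -> bin-centre voltage -> FSR resistance (divider
    inverse) -> weight through the power law.  Code 0 is the open-circuit
    sentinel of an unloaded sensor and maps to exactly zero weight, so
    swing-phase samples are true zeros.  Output is in kg.
    """
    codes = rec.channels
    if np.any(codes < 0) or np.any(codes > adc.max_code):
        raise ValueError("codes outside the ADC range")
    v = adc_dequantize(codes, adc)
    loaded = codes > 0
    weight_g = np.zeros(codes.shape)
    if np.any(loaded):
        r_kohm = fsr_divider_inverse(v[loaded], chain) / 1e3
        weight_g[loaded] = fsr_weight(r_kohm, cal)
    vgrf_kg = weight_g.sum(axis=1) / 1000.0
    return VgrfTrace(
        foot=rec.foot, time=rec.time, vgrf=vgrf_kg, sampling_rate=rec.sampling_rate
    )


def bodyweight_scale_factor(
    trace: VgrfTrace,
    body_weight: float,
    standing_window: tuple[float, float],
) -> tuple[float, VgrfTrace]:
    """Scale the trace so single-foot standing reads the body weight.

    The mean vGRF over the standing window (seconds) is compared with the
    known body weight; when it under-reads, the whole trace is multiplied
    by ``body_weight / mean``.  An over-reading trace is left untouched
    (factor 1.0) — the correction only ever scales up.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    t0, t1 = standing_window
    sel = (trace.time >= t0) & (trace.time <= t1)
    if not np.any(sel):
        raise ValueError("standing_window contains no samples")
    mean = float(np.mean(trace.vgrf[sel]))
    if mean <= 0:
        raise ValueError("standing-window mean is zero: degenerate signal")
    factor = body_weight / mean if mean < body_weight else 1.0
    scaled = VgrfTrace(
        foot=trace.foot,
        time=trace.time,
        vgrf=trace.vgrf * factor,
        sampling_rate=trace.sampling_rate,
        scale_factor=factor,
    )
    return factor, scaled


def segment_gait(
    trace: VgrfTrace,
    zero_threshold: float = 0.5,
    min_samples: int = 10,
    discard_edges: int = 2,
) -> list[StanceSegment]:
    """Cut the trace into stance phases: maximal runs of loaded samples.

    A stance is a run of consecutive samples above ``zero_threshold`` (kg)
    at least ``min_samples`` long; ``discard_edges`` runs are dropped from
    each end of the trial (gait initiation and termination cycles).
    """
    if discard_edges < 0 or min_samples < 1:
        raise ValueError("discard_edges must be >= 0 and min_samples >= 1")
    above = trace.vgrf > zero_threshold
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    segments = [
        StanceSegment(start=s, end=e, samples=trace.vgrf[s:e].copy())
        for s, e in zip(starts, ends)
        if e - s >= min_samples
    ]
    if discard_edges:
        segments = segments[discard_edges:len(segments) - discard_edges]
    return segments


def resample_segment(
    seg: StanceSegment | np.ndarray, n_points: int = N_POINTS_DEFAULT
) -> np.ndarray:
    """Linearly interpolate a stance segment onto ``n_points`` samples.

    The grid spans the segment inclusively, so both endpoints are
    preserved exactly and a segment already of length ``n_points`` is
    returned unchanged.
    """
    y = seg.samples if isinstance(seg, StanceSegment) else np.asarray(seg, dtype=float)
    if y.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    if y.size == n_points:
        return y.astype(float).copy()
    x_old = np.linspace(0.0, 1.0, y.size)
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, y)


def ensemble_stats(segments, n_points: int = N_POINTS_DEFAULT) -> EnsembleStats:
    """Pointwise mean and sample SD across time-normalized segments.

    Accepts StanceSegments (resampled on the fly) or ready-made
    ``n_points`` vectors.  SD uses the n-1 normalization; a single segment
    has zero SD by convention.
    """
    if len(segments) == 0:
        raise ValueError("need at least 1 segment")
    mat = np.stack([resample_segment(s, n_points) for s in segments])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(n_points)
    return EnsembleStats(mean=mean, sd=sd, n_segments=mat.shape[0])


def _ensemble_peaks(mean: np.ndarray, min_separation_frac: float = 0.2):
    """Two largest local maxima of the ensemble mean, at least 20% apart."""
    idx, props = find_peaks(mean, distance=max(1, int(min_separation_frac * mean.size)))
    if idx.size < 2:
        return None
    order = np.argsort(mean[idx])[::-1][:2]
    two = np.sort(idx[order])
    return two


def gait_metrics(
    segments,
    stride_durations,
    sampling_rate: float,
    n_points: int = N_POINTS_DEFAULT,
) -> GaitMetrics:
    """Scalar gait variables from one foot's segmented stance phases.

    ``stride_durations`` are the stride times (s) giving the stance/stride
    denominator; stance duration is the mean segment length.  Peaks are the
    two largest local maxima of the ensemble mean (>=20% of stance apart),
    the valley is the minimum between them.  Traces whose ensemble mean
    lacks two local maxima (e.g. piezo insoles, which collapse the stance
    into a single event) are flagged shape-atypical.
    """
    if len(segments) == 0:
        raise ValueError("need at least 1 segment")
    stats = ensemble_stats(segments, n_points)
    stance_s = float(
        np.mean([s.n_samples if isinstance(s, StanceSegment) else len(s) for s in segments])
    ) / sampling_rate
    stride_s = float(np.mean(np.asarray(stride_durations, dtype=float)))
    stance_fraction = 100.0 * stance_s / stride_s
    peaks = _ensemble_peaks(stats.mean)
    if peaks is None:
        m = float(stats.mean.max())
        return GaitMetrics(
            stance_fraction=stance_fraction,
            time_to_first_peak=float(np.argmax(stats.mean)) / (n_points - 1) * 100.0,
            time_to_second_peak=float("nan"),
            peak1=m,
            valley=float(stats.mean.min()),
            peak2=float("nan"),
            shape_atypical=True,
        )
    i1, i2 = int(peaks[0]), int(peaks[1])
    valley = float(stats.mean[i1:i2 + 1].min())
    return GaitMetrics(
        stance_fraction=stance_fraction,
        time_to_first_peak=i1 / (n_points - 1) * 100.0,
        time_to_second_peak=i2 / (n_points - 1) * 100.0,
        peak1=float(stats.mean[i1]),
        valley=valley,
        peak2=float(stats.mean[i2]),
    )


def symmetry_index(left: float, right: float) -> float:
    """Bilateral symmetry index SI = 200 * |L - R| / (L + R) %.

    Zero for perfect symmetry.  The choice of formula is a package
    convention (several exist in the gait literature); it is applied to a
    chosen scalar such as the first vGRF peak of each foot.
    """
    if left + right == 0:
        return 0.0
    return 200.0 * abs(left - right) / (left + right)


def detect_events_piezo(
    signal,
    sampling_rate: float,
    threshold: float = 0.1,
    refractory: float = 0.5,
) -> np.ndarray:
    """Gait event times from a piezo-insole trace: threshold crossings.

    A piezo insole reports one impulse per stance, so upward crossings of
    ``threshold`` — with closer crossings suppressed within the
    ``refractory`` period — mark gait-cycle starts.  Returns event times in
    seconds.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        return np.array([])
    crossings = np.flatnonzero((x[1:] >= threshold) & (x[:-1] < threshold)) + 1
    events = []
    last = -np.inf
    for i in crossings:
        t = i / sampling_rate
        if t - last >= refractory:
            events.append(t)
            last = t
    return np.asarray(events)
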