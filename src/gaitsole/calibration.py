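"""Sensor calibration fitters.

Three sensor families, three procedures, all referenced to the load cell:

* **FSR** — staircase loading (500 g steps, 0 → 5000 g and back).  The mean
  divider voltage on each plateau is converted to a resistance and a power
  law ``W = a * R**b`` (weight in grams, resistance in kΩ, b < 0) is fitted
  in log-log space, separately for the loading and off-loading branches so
  the hysteresis between them can be quantified.
* **Ceramic piezo** — static weights are useless (no static response), so
  calibration pairs the voltage peak of each fast press/release event with
  the simultaneous load-cell weight peak and fits a line
  ``W_kg = m * V + c``.
* **MEMS piezo film** — the same press procedure, but because the film
  responds with signed amplitude to force components along all three axes,
  repeated trials may flip the sign or attenuate the slope.  The
  repeatability diagnostic quantifies this and flags the sensor as
  axis-ambiguous when trials disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .signal_chain import DividerConfig, fsr_divider_inverse

__all__ = [
    "StaircaseRecording",
    "FsrCalibration",
    "PiezoCalibration",
    "PressEvent",
    "MemsRepeatabilityReport",
    "extract_plateau_means",
    "staircase_points",
    "fit_fsr_power_law",
    "fsr_weight",
    "fsr_resistance_for_weight",
    "hysteresis_error",
    "detect_press_events",
    "fit_piezo_line",
    "mems_repeatability",
]

#: A plateau boundary is a jump in the reference weight larger than half a
#: 500 g staircase step between consecutive load-cell samples.
STEP_DETECT_THRESHOLD_G = 250.0


@dataclass
class StaircaseRecording:
    """Paired load-cell / sensor-voltage time series from a staircase session."""

    time: np.ndarray              # seconds, strictly increasing
    reference_weight: np.ndarray  # grams
    sensor_voltage: np.ndarray    # volts
    direction: np.ndarray = field(default=None)  # "loading" / "offloading" per sample

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.reference_weight = np.asarray(self.reference_weight, dtype=float)
        self.sensor_voltage = np.asarray(self.sensor_voltage, dtype=float)
        if not (self.time.size == self.reference_weight.size == self.sensor_voltage.size):
            raise ValueError("time, reference_weight and sensor_voltage lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.direction is None:
            # loading up to the weight maximum, offloading after it
            peak = int(np.argmax(self.reference_weight))
            d = np.array(["loading"] * self.time.size, dtype=object)
            d[peak + 1:] = "offloading"
            self.direction = d
        else:
            self.direction = np.asarray(self.direction, dtype=object)


@dataclass(frozen=True)
class FsrCalibration:
    """Fitted FSR weight model W[g] = a * (R[kΩ])**b."""

    coefficient_a: float
    exponent_b: float
    phase: str = "offloading"          # branch the fit came from
    fit_r2: float = float("nan")
    hysteresis_metric: float = float("nan")

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0:
            raise ValueError("coefficient_a must be positive")


@dataclass(frozen=True)
class PiezoCalibration:
    """Fitted piezo weight model W[kg] = m * V + c."""

    slope_m: float
    intercept_c: float
    fit_r2: float = float("nan")


@dataclass(frozen=True)
class PressEvent:
    """One press/release: piezo voltage peak paired with the weight peak."""

    time: float            # seconds, at the piezo peak
    piezo_peak: float      # volts
    reference_peak: float  # grams


def extract_plateau_means(
    rec: StaircaseRecording, settle_time: float = 1.0
) -> list[tuple[float, float, str]]:
    """Average each constant-weight plateau of a staircase recording.

    Plateau boundaries are load-cell jumps larger than half a step
    (250 g); the first ``settle_time`` seconds after each boundary are
    discarded so mechanical settling does not bias the means.  Returns
    ``(mean_weight_g, mean_voltage, direction)`` per plateau in time order.
    """
    w = rec.reference_weight
    boundaries = np.flatnonzero(np.abs(np.diff(w)) > STEP_DETECT_THRESHOLD_G) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [w.size]))
    durations = rec.time[ends - 1] - rec.time[starts]
    if not np.any(durations > settle_time):
        raise ValueError(f"no plateau longer than settle_time={settle_time} s found")
    out: list[tuple[float, float, str]] = []
    for s, e in zip(starts, ends):
        t0 = rec.time[s]
        keep = np.arange(s, e)[rec.time[s:e] >= t0 + (settle_time if s > 0 else 0.0)]
        if keep.size == 0:
            continue
        out.append(
            (
                float(np.mean(w[keep])),
                float(np.mean(rec.sensor_voltage[keep])),
                str(rec.direction[keep[-1]]),
            )
        )
    if not out:
        raise ValueError(f"no plateau longer than settle_time={settle_time} s found")
    return out


def staircase_points(
    rec: StaircaseRecording,
    chain: DividerConfig,
    settle_time: float = 1.0,
    phase: str | None = None,
) -> list[tuple[float, float]]:
    """Plateau means converted to (weight_g, resistance_kΩ) fit points.

    Zero-weight plateaus are dropped (open circuit / log-undefined), as are
    plateaus outside the requested loading/offloading ``phase``.
    """
    pts = []
    for weight, volts, direction in extract_plateau_means(rec, settle_time):
        # the smallest loaded plateau is one 500 g step; anything below half
        # a step is the unloaded (open-circuit) plateau, which cannot enter
        # a log-log fit and whose voltage sits at the rail
        if weight < STEP_DETECT_THRESHOLD_G or volts <= 0:
            continue
        if phase is not None and direction != phase:
            continue
        r_kohm = fsr_divider_inverse(volts, chain) / 1e3
        pts.append((weight, r_kohm))
    return pts


def _log_log_fit(w: np.ndarray, r: np.ndarray) -> tuple[float, float, float]:
    b, log_a = np.polyfit(np.log(r), np.log(w), 1)
    pred = log_a + b * np.log(r)
    ss_res = float(np.sum((np.log(w) - pred) ** 2))
    ss_tot = float(np.sum((np.log(w) - np.mean(np.log(w))) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(np.exp(log_a)), float(b), r2


def fit_fsr_power_law(
    points, phase: str = "offloading", hysteresis_metric: float = float("nan")
) -> FsrCalibration:
    """Fit W = a * R**b by least squares on log W vs log R.

    ``points`` are ``(weight_g, resistance_kΩ)`` pairs; at least three, all
    strictly positive (the zero-weight plateau cannot enter a log fit).
    Noise-free power-law data is recovered to machine precision.
    """
    pts = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit the power law")
    if np.any(pts <= 0):
        raise ValueError("weights and resistances must all be positive")
    a, b, r2 = _log_log_fit(pts[:, 0], pts[:, 1])
    return FsrCalibration(
        coefficient_a=a,
        exponent_b=b,
        phase=phase,
        fit_r2=r2,
        hysteresis_metric=hysteresis_metric,
    )


def fsr_weight(resistance_kohm, cal: FsrCalibration):
    """Predicted weight (grams) at a resistance (kΩ): a * R**b.

    Monotone decreasing for b < 0 and -> 0 as R -> inf (open circuit).
    """
    r = np.asarray(resistance_kohm, dtype=float)
    if np.any(np.isfinite(r) & (r <= 0)):
        raise ValueError("resistance must be positive")
    with np.errstate(over="ignore"):
        w = cal.coefficient_a * r**cal.exponent_b
    w = np.where(np.isinf(r) & (cal.exponent_b < 0), 0.0, w)
    return float(w) if np.ndim(resistance_kohm) == 0 else w


def fsr_resistance_for_weight(weight_g, cal: FsrCalibration):
    """Invert the power law: R[kΩ] = (W/a)**(1/b); +inf at zero weight."""
    w = np.asarray(weight_g, dtype=float)
    if np.any(w < 0):
        raise ValueError("weight must be non-negative")
    with np.errstate(divide="ignore"):
        r = np.where(w > 0, (w / cal.coefficient_a) ** (1.0 / cal.exponent_b), np.inf)
    return float(r) if np.ndim(weight_g) == 0 else r


def hysteresis_error(
    loading: FsrCalibration,
    offloading: FsrCalibration,
    r_range: tuple[float, float] = (0.5, 20.0),
) -> float:
    """Worst-case relative disagreement between the two fitted branches.

    Evaluated on a 100-point log-spaced resistance grid:
    ``max |W_load - W_offload| / max(W_load, W_offload)``.  0 for identical
    fits, 0.5 when one coefficient is doubled.
    """
    lo, hi = r_range
    if lo <= 0 or hi <= lo:
        raise ValueError("r_range must be a positive increasing interval")
    grid = np.logspace(np.log10(lo), np.log10(hi), 100)
    wl = fsr_weight(grid, loading)
    wo = fsr_weight(grid, offloading)
    return float(np.max(np.abs(wl - wo) / np.maximum(wl, wo)))


def detect_press_events(
    time,
    piezo_voltage,
    reference_weight,
    threshold: float = 0.1,
    window: float = 0.5,
) -> list[PressEvent]:
    """Locate press events and pair them with load-cell weight peaks.

    Piezo events are local maxima above ``threshold`` volts separated by at
    least ``window`` seconds (the larger of two closer peaks wins); each is
    paired with the maximum reference weight within ±window/2 around it.
    Both series must share the ``time`` base (resample the slower channel
    first if the rates differ).  An empty or flat signal yields no events.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(piezo_voltage, dtype=float)
    w = np.asarray(reference_weight, dtype=float)
    if t.size == 0:
        return []
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    distance = max(1, int(round(window / dt)))
    idx, _ = find_peaks(v, height=threshold, distance=distance)
    events = []
    for i in idx:
        half = window / 2.0
        sel = (t >= t[i] - half) & (t <= t[i] + half)
        events.append(
            PressEvent(
                time=float(t[i]),
                piezo_peak=float(v[i]),
                reference_peak=float(np.max(w[sel])),
            )
        )
    return events


def fit_piezo_line(events: list[PressEvent]) -> PiezoCalibration:
    """Least-squares line W[kg] = m * V + c through the press events.

    Event reference peaks are recorded in grams and converted to kilograms
    for the fit (the conventional scale for these coefficients).  Exact on
    collinear data; all-identical voltage peaks are degenerate.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 press events")
    v = np.array([e.piezo_peak for e in events], dtype=float)
    w = np.array([e.reference_peak for e in events], dtype=float) / 1000.0
    if np.unique(v).size < 2:
        raise ValueError("all piezo peaks identical: cannot fit a line")
    m, c = np.polyfit(v, w, 1)
    pred = m * v + c
    ss_tot = float(np.sum((w - np.mean(w)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((w - pred) ** 2)) / ss_tot
    return PiezoCalibration(slope_m=float(m), intercept_c=float(c), fit_r2=r2)


@dataclass(frozen=True)
class MemsRepeatabilityReport:
    """Across-trial slope diagnostics for a MEMS piezo film sensor."""

    slopes: tuple[float, ...]
    sign_consistency: float       # fraction of trials sharing the majority sign
    slope_cv: float               # sd/|mean| of the slopes
    flagged: bool                 # axis-ambiguous, unsuitable for vGRF
    reason: str = ""


def mems_repeatability(
    trial_points, cv_limit: float = 0.30
) -> MemsRepeatabilityReport:
    """Assess slope repeatability across repeated MEMS calibration trials.

    ``trial_points`` is a list of per-trial point sets, each a sequence of
    ``(voltage, weight)`` pairs; a line is fitted per trial.  The sensor is
    flagged axis-ambiguous when trial slopes disagree in sign (a press whose
    force vector tips into another axis flips the output polarity) or when
    the slope coefficient of variation exceeds ``cv_limit``.
    """
    if len(trial_points) < 2:
        raise ValueError("need at least 2 trials")
    slopes = []
    for pts in trial_points:
        arr = np.asarray(pts, dtype=float)
        m, _ = np.polyfit(arr[:, 0], arr[:, 1], 1)
        slopes.append(float(m))
    s = np.asarray(slopes)
    signs = np.sign(s)
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    sign_consistency = max(n_pos, n_neg) / s.size
    mean = float(np.mean(s))
    cv = float("inf") if mean == 0 else float(np.std(s, ddof=1) / abs(mean))
    reasons = []
    if n_pos and n_neg:
        reasons.append("trial slopes disagree in sign")
    if cv > cv_limit:
        reasons.append(f"slope CV {cv:.2f} exceeds limit {cv_limit:.2f}")
    return MemsRepeatabilityReport(
        slopes=tuple(slopes),
        sign_consistency=sign_consistency,
        slope_cv=cv,
        flagged=bool(reasons),
        reason="axis-ambiguous, unsuitable for vGRF: " + "; ".join(reasons)
        if reasons
        else "",
    )
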