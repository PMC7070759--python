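"""Synthetic smart-insole data generator.

Emulates everything the hardware would record so that every stage of the
calibration and gait pipeline can be exercised and validated without a
bench or subjects:

* M-shaped stance-phase vGRF curves with heel-strike and toe-off peaks
  near body weight (peaks within ±10% of it) and a mid-stance valley;
* a 16-sensor-per-foot layout covering heel, metatarsal heads, hallux and
  toes (the medial arch is left uninstrumented, as it bears little load),
  with a piecewise-linear heel-to-toe load transfer across stance;
* forward sensor models — FSR power-law resistance with optional
  hysteresis and voltage noise, ceramic piezo as a differentiator plus
  first-order high-pass (no static response, negative rebound on release),
  and a 3-axis MEMS film whose 1-D readout is the dot product of its axis
  gains with the force vector;
* bench calibration sessions: the 500 g staircase (0 -> 5000 g and back)
  and the press-and-release piezo session.

All randomness flows through a seed; identical seeds give identical
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import FsrCalibration, StaircaseRecording, fsr_resistance_for_weight
from .signal_chain import (
    INSOLE,
    AdcConfig,
    ChainPreset,
    DividerConfig,
    PiezoDividerConfig,
    adc_quantize,
    fsr_divider_forward,
    piezo_divider_forward,
)

__all__ = [
    "GaitProfile",
    "SensorLayout",
    "FsrSensorModel",
    "PiezoSensorModel",
    "MemsSensorModel",
    "InsoleRecording",
    "FSR_SENSOR_PRESETS",
    "PIEZO_LINE_PRESETS",
    "default_layout",
    "synth_vgrf_stance",
    "distribute_pressure",
    "simulate_fsr_channel",
    "simulate_piezo_channel",
    "simulate_staircase",
    "simulate_press_session",
    "simulate_mems_press",
    "simulate_mems_trials",
    "synth_walk",
]


@dataclass(frozen=True)
class GaitProfile:
    """Subject and gait-timing parameters driving the vGRF generator.

    Defaults describe a normal adult walk: 0.7 s stance in a ~1.15 s
    stride, vGRF peaks 5% above body weight (the physiological bound is
    ±10%) and a mid-stance valley at 75% of it.  ``body_weight`` defaults
    to the study population's mean female weight.
    """

    body_weight: float = 77.3        # kg
    stance_duration: float = 0.7     # s
    stride_duration: float = 1.15    # s
    peak_ratio: float = 1.05         # peak vGRF / body weight
    valley_ratio: float = 0.75       # mid-stance vGRF / body weight
    cadence_jitter_sd: float = 0.0   # fractional sd on per-cycle durations
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stance_duration < self.stride_duration:
            raise ValueError("need 0 < stance_duration < stride_duration")
        if abs(self.peak_ratio - 1.0) > 0.10:
            raise ValueError("peak_ratio must stay within ±10% of body weight")
        if self.body_weight < 0:
            raise ValueError("body_weight must be non-negative")


# Region load shares across normalized stance time (rows sum to 1): the heel
# carries essentially all load at contact, hands over to the metatarsal heads
# through mid-stance, and the hallux/toes take over at push-off.
_REGION_ORDER = ("heel", "metatarsal", "hallux", "toe")
_REGION_PHASE_TABLE = np.array(
    [
        # t, heel, metatarsal, hallux, toe
        [0.00, 1.00, 0.00, 0.00, 0.00],
        [0.15, 0.85, 0.15, 0.00, 0.00],
        [0.40, 0.30, 0.55, 0.10, 0.05],
        [0.60, 0.05, 0.60, 0.25, 0.10],
        [0.80, 0.00, 0.40, 0.40, 0.20],
        [1.00, 0.00, 0.10, 0.55, 0.35],
    ]
)


@dataclass(frozen=True)
class SensorLayout:
    """Sixteen sensors per foot assigned to plantar regions (no medial arch)."""

    regions: tuple[str, ...] = (
        ("heel",) * 6 + ("metatarsal",) * 6 + ("hallux",) * 2 + ("toe",) * 2
    )

    def __post_init__(self) -> None:
        if len(self.regions) != 16:
            raise ValueError("layout must have exactly 16 sensors")
        bad = set(self.regions) - set(_REGION_ORDER)
        if bad:
            raise ValueError(f"unknown regions {bad}; medial arch is uninstrumented")

    def region_counts(self) -> dict[str, int]:
        return {r: self.regions.count(r) for r in _REGION_ORDER}


def default_layout() -> SensorLayout:
    return SensorLayout()


@dataclass(frozen=True)
class FsrSensorModel:
    """Ground-truth FSR: W[g] = a * (R[kΩ])**b, plus hysteresis and noise."""

    coefficient_a: float = 5035.2
    exponent_b: float = -1.72
    hysteresis_factor: float = 0.05  # fractional resistance shift when unloading
    voltage_noise_sd: float = 0.005  # volts

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0 or self.exponent_b >= 0:
            raise ValueError("need coefficient_a > 0 and exponent_b < 0")

    def as_calibration(self) -> FsrCalibration:
        return FsrCalibration(
            coefficient_a=self.coefficient_a, exponent_b=self.exponent_b
        )


#: Ground-truth FSR presets named after the bench calibration trials they
#: reproduce (weight in grams at resistance in kΩ).
FSR_SENSOR_PRESETS = {
    "fsr-trial1": FsrSensorModel(5035.2, -1.72),
    "fsr-trial2": FsrSensorModel(3436.5, -1.895),
    "fsr-trial3": FsrSensorModel(8111.8, -2.589),
}

#: Ground-truth press-response lines W[kg] = m*V + c for the piezo sensors,
#: named after the bench trials.
PIEZO_LINE_PRESETS = {
    "piezo1-trial1": (0.42867, -0.19123),
    "piezo1-trial2": (0.41110, 0.0081012),
    "piezo1-trial3": (0.39321, 0.084656),
    "piezo2-trial1": (0.34619, 0.4105),
    "piezo2-trial2": (0.27242, 0.57351),
    "piezo2-trial3": (0.35564, 0.30325),
    "piezo2-trial4": (0.31765, 0.36416),
}


@dataclass(frozen=True)
class PiezoSensorModel:
    """Dynamic ceramic-piezo model: differentiator into a high-pass filter.

    The element converts the *rate* of force change to voltage
    (``charge_gain`` volts per kg/s) and the divider RC network high-passes
    the result, so static loads decay to zero, a press yields a positive
    peak and the release a negative rebound.
    """

    charge_gain: float = 0.5        # volts per (kg/s)
    highpass_cutoff: float = 1.47   # Hz
    rebound: bool = True            # keep the negative undershoot on release
    clip_negative_at_adc: bool = True

    def __post_init__(self) -> None:
        if self.highpass_cutoff <= 0:
            raise ValueError("highpass_cutoff must be positive")


@dataclass(frozen=True)
class MemsSensorModel:
    """3-axis MEMS film with a scalar readout: v = gains . force_vector."""

    axis_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)  # volts/kg per axis


@dataclass
class InsoleRecording:
    """Per-foot 16-channel raw recording (integer ADC codes)."""

    foot: str                      # "left" | "right"
    time: np.ndarray               # seconds
    channels: np.ndarray           # (n_samples, 16) int codes
    sampling_rate: float = 60.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 2 or self.channels.shape[1] != 16:
            raise ValueError("channels must be (n_samples, 16)")
        if self.channels.shape[0] != self.time.size:
            raise ValueError("time and channels lengths differ")


def synth_vgrf_stance(
    profile: GaitProfile,
    sampling_rate: float = 60.0,
    n_samples: int | None = None,
) -> np.ndarray:
    """One stance phase of vGRF (kg), sampled uniformly.

    The curve is the positive part of a sum of two narrow Gaussian bumps
    (heel-strike and push-off peaks near 20% and 80% of stance) and one
    broad mid-stance bump, with short linear tapers forcing zero at both
    ends.  Coefficients are solved so the curve passes through the peak and
    valley targets, then the whole curve is rescaled so its sampled maximum
    equals exactly ``peak_ratio * body_weight``.  Samples sit strictly
    inside (0, 1) of normalized stance so every sample carries load.
    """
    if n_samples is None:
        n_samples = int(round(profile.stance_duration * sampling_rate))
    if n_samples < 2:
        raise ValueError("stance must span at least 2 samples")
    t = (np.arange(n_samples) + 1.0) / (n_samples + 1.0)
    if profile.body_weight == 0:
        return np.zeros(n_samples)

    centers = np.array([0.20, 0.80, 0.50])
    widths = np.array([0.12, 0.12, 0.18])

    def basis(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.exp(-((x[:, None] - centers) ** 2) / (2.0 * widths**2))

    targets = profile.body_weight * np.array(
        [profile.peak_ratio, profile.peak_ratio, profile.valley_ratio]
    )
    coef = np.linalg.solve(basis(centers), targets)
    curve = basis(t) @ coef
    taper = np.clip(t / 0.05, 0.0, 1.0) * np.clip((1.0 - t) / 0.05, 0.0, 1.0)
    curve = np.clip(curve * taper, 0.0, None)
    peak_target = profile.peak_ratio * profile.body_weight
    m = curve.max()
    if m > 0:
        curve *= peak_target / m
    return curve


def distribute_pressure(vgrf: np.ndarray, layout: SensorLayout) -> np.ndarray:
    """Split a stance vGRF series across the 16 sensors, conserving the sum.

    Region shares follow the piecewise-linear heel-to-toe transfer table
    (interpolated over normalized stance time, last region's share defined
    as one minus the others so the shares sum to one exactly); the share of
    a region is split equally among its sensors.  At every sample the 16
    sensor forces add back to the input vGRF.
    """
    vgrf = np.asarray(vgrf, dtype=float)
    n = vgrf.size
    tn = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    shares = np.stack(
        [np.interp(tn, _REGION_PHASE_TABLE[:, 0], _REGION_PHASE_TABLE[:, 1 + j])
         for j in range(len(_REGION_ORDER) - 1)],
        axis=1,
    )
    shares = np.column_stack([shares, 1.0 - shares.sum(axis=1)])
    counts = layout.region_counts()
    out = np.zeros((n, 16))
    for i, region in enumerate(layout.regions):
        j = _REGION_ORDER.index(region)
        out[:, i] = vgrf * shares[:, j] / counts[region]
    return out


def simulate_fsr_channel(
    force_kg: np.ndarray,
    model: FsrSensorModel,
    chain: DividerConfig,
    adc: AdcConfig,
    rng: np.random.Generator | None = None,
    unloading: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-simulate one FSR channel from force (kg) to ADC codes.

    Force -> resistance through the inverted power law (+inf when
    unloaded), optionally shifted by the hysteresis factor on unloading
    samples, -> divider voltage, + Gaussian noise on loaded samples
    (an unloaded sensor is an open circuit reading a clean 0 V, so the
    zero-load code is exactly 0), -> quantized code.
    """
    force_kg = np.asarray(force_kg, dtype=float)
    if np.any(force_kg < 0):
        raise ValueError("forces must be non-negative")
    r_ohm = fsr_resistance_for_weight(force_kg * 1000.0, model.as_calibration()) * 1e3
    if model.hysteresis_factor != 0:
        if unloading is None:
            unloading = np.gradient(force_kg) < 0
        r_ohm = np.where(unloading, r_ohm * (1.0 + model.hysteresis_factor), r_ohm)
    v = fsr_divider_forward(r_ohm, chain)
    if model.voltage_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        noise = rng.normal(0.0, model.voltage_noise_sd, size=v.shape)
        v = np.where(force_kg > 0, np.clip(v + noise, 0.0, chain.supply_voltage), v)
    return adc_quantize(v, adc)


def simulate_piezo_channel(
    force_kg: np.ndarray, model: PiezoSensorModel, sampling_rate: float
) -> np.ndarray:
    """Raw piezo element voltage for a force series: HP(charge_gain * dF/dt).

    A first-order Butterworth high-pass at the model cutoff follows the
    differentiator, so constant-force plateaus decay to zero, a loading
    edge gives a positive peak and an unloading edge a negative one.
    """
    from scipy.signal import butter, lfilter

    force_kg = np.asarray(force_kg, dtype=float)
    dfdt = np.gradient(force_kg) * sampling_rate
    raw = model.charge_gain * dfdt
    b, a = butter(1, model.highpass_cutoff, btype="highpass", fs=sampling_rate)
    out = lfilter(b, a, raw)
    if not model.rebound:
        out = np.clip(out, 0.0, None)
    return out


def default_staircase_protocol(
    max_weight: float = 5000.0, step: float = 500.0
) -> list[float]:
    """0 -> max_weight in `step` increments, then back down to 0 (21 levels)."""
    up = np.arange(0.0, max_weight + step / 2, step)
    down = up[-2::-1]
    return list(np.concatenate([up, down]))


def simulate_staircase(
    sensor: FsrSensorModel | PiezoSensorModel,
    chain: DividerConfig | PiezoDividerConfig,
    protocol: list[float] | None = None,
    step_duration: float = 4.0,
    sampling_rate: float = 10.0,
    adc: AdcConfig | None = None,
    loadcell_noise_sd_g: float = 0.0,
    rng: np.random.Generator | None = None,
) -> StaircaseRecording:
    """Simulate a dead-weight staircase calibration session.

    ``protocol`` is the sequence of plateau weights in grams (default
    0 -> 5000 -> 0 in 500 g steps, 4 s per plateau).  The load-cell and
    sensor channels share one time base at ``sampling_rate``.  The sensor
    voltage is stored as the analog acquisition-input voltage; pass an
    ``AdcConfig`` to round it through the converter instead.
    """
    if protocol is None:
        protocol = default_staircase_protocol()
    if rng is None:
        rng = np.random.default_rng()
    n_per = int(round(step_duration * sampling_rate))
    weights = np.repeat(np.asarray(protocol, dtype=float), n_per)
    n = weights.size
    time = np.arange(n) / sampling_rate
    peak = int(np.argmax(weights))
    direction = np.array(["loading"] * n, dtype=object)
    direction[peak + 1:] = "offloading"

    if isinstance(sensor, FsrSensorModel):
        r_ohm = (
            fsr_resistance_for_weight(weights, sensor.as_calibration()) * 1e3
        )
        if sensor.hysteresis_factor != 0:
            r_ohm = np.where(
                direction == "offloading",
                r_ohm * (1.0 + sensor.hysteresis_factor),
                r_ohm,
            )
        v = fsr_divider_forward(r_ohm, chain)
        if sensor.voltage_noise_sd > 0:
            noise = rng.normal(0.0, sensor.voltage_noise_sd, size=n)
            v = np.where(weights > 0, np.clip(v + noise, 0.0, chain.supply_voltage), v)
    else:
        raw = simulate_piezo_channel(weights / 1000.0, sensor, sampling_rate)
        v = piezo_divider_forward(raw, chain)

    if adc is not None:
        from .signal_chain import adc_dequantize

        v = adc_dequantize(adc_quantize(v, adc), adc)

    ref = weights
    if loadcell_noise_sd_g > 0:
        ref = weights + rng.normal(0.0, loadcell_noise_sd_g, size=n)
    return StaircaseRecording(
        time=time, reference_weight=ref, sensor_voltage=v, direction=direction
    )


def _unit_peak_pulse(fs: float, width: float = 0.05) -> np.ndarray:
    """Biphasic press/release pulse (derivative-of-Gaussian) with max +1."""
    tt = np.arange(-4 * width, 4 * width, 1.0 / fs)
    pulse = -tt * np.exp(-(tt**2) / (2.0 * width**2))
    return pulse / pulse.max()


def simulate_press_session(
    weights_kg,
    line: tuple[float, float],
    sampling_rate: float = 1000.0,
    spacing: float = 2.0,
    piezo_noise_sd: float = 0.005,
    loadcell_noise_sd_g: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a press-and-release piezo calibration session.

    The sensor ground truth is the linear peak model ``W[kg] = m*V + c``
    (``line = (m, c)``): each press of weight W produces a biphasic piezo
    pulse whose positive peak is exactly ``(W - c)/m`` volts, paired with a
    load-cell weight bump peaking at W.  Returns ``(time, piezo_voltage,
    reference_weight_g)`` on a shared time base.
    """
    m, c = line
    weights_kg = np.asarray(weights_kg, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    n = int(round((spacing * (weights_kg.size + 1)) * sampling_rate))
    time = np.arange(n) / sampling_rate
    piezo = np.zeros(n)
    ref = np.zeros(n)
    pulse = _unit_peak_pulse(sampling_rate)
    bump_w = 0.08
    for k, w in enumerate(weights_kg):
        center = int(round((k + 1) * spacing * sampling_rate))
        v_peak = (w - c) / m
        s = center - np.flatnonzero(pulse == pulse.max())[0]
        e = min(s + pulse.size, n)
        piezo[s:e] += v_peak * pulse[: e - s]
        bump = np.exp(-((time - time[center]) ** 2) / (2.0 * bump_w**2))
        ref = np.maximum(ref, w * 1000.0 * bump / bump.max())
    if piezo_noise_sd > 0:
        piezo = piezo + rng.normal(0.0, piezo_noise_sd, size=n)
    if loadcell_noise_sd_g > 0:
        ref = ref + rng.normal(0.0, loadcell_noise_sd_g, size=n)
    return time, piezo, ref


def simulate_mems_press(
    model: MemsSensorModel, force_magnitudes, orientations
) -> np.ndarray:
    """Scalar voltage peaks of MEMS presses: gains . (magnitude * orientation).

    Pure-z presses give sign-consistent peaks proportional to magnitude;
    mixed-axis force vectors can attenuate or flip the sign of the readout.
    """
    mags = np.asarray(force_magnitudes, dtype=float)
    orient = np.asarray(orientations, dtype=float)
    if orient.shape != (mags.size, 3):
        raise ValueError("orientations must be (n, 3) unit vectors")
    norms = np.linalg.norm(orient, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("orientations must be unit vectors")
    gains = np.asarray(model.axis_gains, dtype=float)
    return (mags[:, None] * orient) @ gains


def simulate_mems_trials(
    model: MemsSensorModel,
    n_trials: int = 5,
    n_presses: int = 8,
    orientation_mode: str = "random",
    rng: np.random.Generator | None = None,
) -> list[list[tuple[float, float]]]:
    """Per-trial (voltage_peak, weight_kg) point sets for repeatability tests.

    ``orientation_mode="z"`` presses straight down every time (the well-
    behaved 1-D case); ``"random"`` draws a random force direction per
    press, reproducing the axis ambiguity seen on the bench.
    """
    if rng is None:
        rng = np.random.default_rng()
    trials = []
    for _ in range(n_trials):
        mags = rng.uniform(1.0, 5.0, size=n_presses)
        if orientation_mode == "z":
            orient = np.tile([0.0, 0.0, 1.0], (n_presses, 1))
        elif orientation_mode == "random":
            raw = rng.normal(size=(n_presses, 3))
            orient = raw / np.linalg.norm(raw, axis=1, keepdims=True)
        else:
            raise ValueError("orientation_mode must be 'z' or 'random'")
        peaks = simulate_mems_press(model, mags, orient)
        trials.append([(float(v), float(w)) for v, w in zip(peaks, mags)])
    return trials


def synth_walk(
    profile: GaitProfile,
    n_cycles: int,
    layout: SensorLayout | None = None,
    fsr_model: FsrSensorModel | None = None,
    chain: ChainPreset = INSOLE,
) -> tuple[InsoleRecording, InsoleRecording]:
    """Simulate a two-foot walking trial as raw 16-channel recordings.

    Each foot produces ``n_cycles`` stance phases, one per stride, the
    right foot phase-shifted by half a stride (symmetric gait); swing-phase
    samples read the zero-load code.  Per-cycle stance/stride durations are
    jittered by ``profile.cadence_jitter_sd``.  Deterministic for a fixed
    ``profile.seed``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if layout is None:
        layout = default_layout()
    if fsr_model is None:
        fsr_model = FSR_SENSOR_PRESETS["fsr-trial1"]
    fs = chain.adc.sampling_rate
    rng = np.random.default_rng(profile.seed)
    lead_in = 0.2
    duration = lead_in + (n_cycles + 0.75) * profile.stride_duration
    n = int(round(duration * fs))
    time = np.arange(n) / fs

    recordings = []
    for foot, offset in (("left", 0.0), ("right", 0.5 * profile.stride_duration)):
        force = np.zeros((n, 16))
        t_cursor = lead_in + offset
        for _ in range(n_cycles):
            jit = 1.0 + (
                rng.normal(0.0, profile.cadence_jitter_sd)
                if profile.cadence_jitter_sd > 0
                else 0.0
            )
            stance = profile.stance_duration * jit
            stride = max(profile.stride_duration * jit, stance + 1.0 / fs)
            s = int(round(t_cursor * fs))
            n_stance = int(round(stance * fs))
            vgrf = synth_vgrf_stance(
                replace(profile, stance_duration=stance), fs, n_samples=n_stance
            )
            per_sensor = distribute_pressure(vgrf, layout)
            e = min(s + n_stance, n)
            force[s:e] += per_sensor[: e - s]
            t_cursor += stride
        codes = np.stack(
            [
                simulate_fsr_channel(
                    force[:, i], fsr_model, chain.divider, chain.adc, rng=rng
                )
                for i in range(16)
            ],
            axis=1,
        )
        recordings.append(
            InsoleRecording(
                foot=foot,
                time=time,
                channels=codes,
                sampling_rate=fs,
                metadata={
                    "chain": chain.name,
                    "seed": profile.seed,
                    "n_cycles": n_cycles,
                    "body_weight_kg": profile.body_weight,
                },
            )
        )
    return recordings[0], recordings[1]
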