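"""Analog/digital acquisition-chain models for insole force sensors.

Every stage between the physical sensor state and the recorded ADC code is
modelled as a pure function with an explicit inverse where one exists:

* an FSR sits in the lower leg of a resistive voltage divider, so the output
  voltage rises as force squeezes the resistance down;
* a ceramic piezo element drives a high-impedance divider which both scales
  its (up to ~20 V) output into the microcontroller range and, together with
  the element's equivalent capacitance, forms a first-order high-pass filter;
* a MEMS piezo film produces a signed voltage, so its divider output is
  re-centred on half the supply rail by an adder stage before acquisition;
* a SAR ADC quantizes the conditioned voltage to an integer code.

Forward functions map physics to voltage/codes (used by the simulator);
inverse functions map recorded values back (used by the gait pipeline).
All voltage/resistance arguments accept scalars or numpy arrays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DividerConfig",
    "PiezoDividerConfig",
    "AmplifierDesign",
    "OffsetStageConfig",
    "AdcConfig",
    "ChainPreset",
    "CALIBRATION_RIG",
    "INSOLE",
    "fsr_divider_forward",
    "fsr_divider_inverse",
    "piezo_divider_forward",
    "piezo_recover_voltage",
    "hpf_cutoff",
    "design_inamp",
    "mems_condition",
    "adc_quantize",
    "adc_dequantize",
]

#: Internal gain-setting resistance constant of the AD620 instrumentation
#: amplifier family (ohms): G = 1 + 49.4k/RG, conventionally quoted 49.9k.
INAMP_RG_CONSTANT = 49.9e3


@dataclass(frozen=True)
class DividerConfig:
    """FSR voltage divider: Vout = Vcc * R / (R + FSR)."""

    supply_voltage: float = 5.0      # Vcc, volts
    fixed_resistance: float = 11e3   # R, ohms

    def __post_init__(self) -> None:
        if self.supply_voltage <= 0:
            raise ValueError("supply_voltage must be positive")
        if self.fixed_resistance <= 0:
            raise ValueError("fixed_resistance must be positive")


@dataclass(frozen=True)
class PiezoDividerConfig:
    """High-impedance divider across a ceramic piezo element.

    r1 is the lower (tapped) leg, r2 the upper, so the static gain is
    r1/(r1+r2); with the defaults 3 MΩ / 9 MΩ the gain is 0.25 and a 20 V
    peak maps to 5 V.  The element's equivalent capacitance in series with
    r1+r2 makes the network a first-order high-pass filter.
    """

    r1: float = 3e6
    r2: float = 9e6
    equivalent_capacitance: float = 9e-9
    max_piezo_voltage: float = 20.0

    def __post_init__(self) -> None:
        if min(self.r1, self.r2, self.equivalent_capacitance) <= 0:
            raise ValueError("r1, r2 and equivalent_capacitance must be positive")

    @property
    def gain(self) -> float:
        return self.r1 / (self.r1 + self.r2)


@dataclass(frozen=True)
class AmplifierDesign:
    """Instrumentation-amplifier design point: gain and gain resistor."""

    full_scale_voltage: float
    max_input_voltage: float
    gain: float
    gain_resistor: float  # ohms; +inf sentinel at unity gain


@dataclass(frozen=True)
class OffsetStageConfig:
    """Divider + adder stage mapping a signed MEMS voltage into [0, Vcc].

    The divider scales ±max_piezo_voltage to ±Vcc/2 and the adder re-centres
    the signal on Vcc/2, so the full bipolar swing fits the ADC range.
    """

    supply_voltage: float = 5.0
    divider_gain: float = 0.25
    max_piezo_voltage: float = 10.0

    def __post_init__(self) -> None:
        if self.supply_voltage <= 0:
            raise ValueError("supply_voltage must be positive")

    @property
    def offset(self) -> float:
        return self.supply_voltage / 2.0


@dataclass(frozen=True)
class AdcConfig:
    """Successive-approximation ADC: resolution, reference and rate."""

    bits: int = 10
    reference_voltage: float = 5.0
    sampling_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError("bits must be >= 1")
        if self.reference_voltage <= 0 or self.sampling_rate <= 0:
            raise ValueError("reference_voltage and sampling_rate must be positive")

    @property
    def max_code(self) -> int:
        return 2**self.bits - 1

    @property
    def lsb(self) -> float:
        return self.reference_voltage / 2**self.bits


@dataclass(frozen=True)
class ChainPreset:
    """A named, self-consistent acquisition chain (rails, divider, ADC)."""

    name: str
    divider: DividerConfig
    piezo_divider: PiezoDividerConfig
    adc: AdcConfig
    loadcell_rate: float | None = None  # Hz, reference channel if present


#: Bench calibration rig: Arduino 5 V rail, 10-bit ADC, 1 kHz for piezo
#: press sessions; the load-cell reference channel updates at 10 Hz.
CALIBRATION_RIG = ChainPreset(
    name="calibration-rig",
    divider=DividerConfig(supply_voltage=5.0, fixed_resistance=11e3),
    piezo_divider=PiezoDividerConfig(),
    adc=AdcConfig(bits=10, reference_voltage=5.0, sampling_rate=1000.0),
    loadcell_rate=10.0,
)

#: Wearable insole: Simblee 3.3 V rail, 10-bit ADC, 60 Hz per channel.
INSOLE = ChainPreset(
    name="insole",
    divider=DividerConfig(supply_voltage=3.3, fixed_resistance=11e3),
    piezo_divider=PiezoDividerConfig(),
    adc=AdcConfig(bits=10, reference_voltage=3.3, sampling_rate=60.0),
)

CHAIN_PRESETS = {p.name: p for p in (CALIBRATION_RIG, INSOLE)}


def fsr_divider_forward(fsr_resistance, cfg: DividerConfig):
    """Divider output voltage for a given FSR resistance (ohms).

    ``Vout = Vcc * R / (R + FSR)``; strictly decreasing in the FSR
    resistance.  An infinite resistance (open circuit, i.e. unloaded
    sensor) maps to exactly 0 V.
    """
    r = np.asarray(fsr_resistance, dtype=float)
    if np.any(np.isfinite(r) & (r <= 0)) or np.any(np.isnan(r)):
        raise ValueError("fsr_resistance must be positive (or +inf for open circuit)")
    with np.errstate(invalid="ignore"):
        v = cfg.supply_voltage * cfg.fixed_resistance / (cfg.fixed_resistance + r)
    v = np.where(np.isinf(r), 0.0, v)
    return float(v) if np.ndim(fsr_resistance) == 0 else v


def fsr_divider_inverse(v_out, cfg: DividerConfig):
    """Recover FSR resistance (ohms) from the divider output voltage.

    Exact algebraic inverse of :func:`fsr_divider_forward`; valid only for
    ``0 < v_out < Vcc``.  Voltages at or beyond the rails indicate a
    saturated or disconnected channel and raise ``ValueError``.
    """
    v = np.asarray(v_out, dtype=float)
    if np.any(v <= 0) or np.any(v >= cfg.supply_voltage):
        raise ValueError(
            "v_out must lie strictly between 0 and the supply voltage "
            "(saturated or disconnected channel)"
        )
    r = cfg.supply_voltage * cfg.fixed_resistance / v - cfg.fixed_resistance
    return float(r) if np.ndim(v_out) == 0 else r


def piezo_divider_forward(v_piezo, cfg: PiezoDividerConfig):
    """Static divider attenuation of the piezo voltage: gain * v_piezo."""
    v = np.asarray(v_piezo, dtype=float) * cfg.gain
    return float(v) if np.ndim(v_piezo) == 0 else v


def piezo_recover_voltage(v_out, cfg: PiezoDividerConfig):
    """Undo the divider attenuation: v_out / gain (4x at the defaults)."""
    v = np.asarray(v_out, dtype=float) / cfg.gain
    return float(v) if np.ndim(v_out) == 0 else v


def hpf_cutoff(cfg: PiezoDividerConfig) -> float:
    """-3 dB corner (Hz) of the piezo RC network: 1 / (2*pi*(r1+r2)*C)."""
    return 1.0 / (2.0 * math.pi * (cfg.r1 + cfg.r2) * cfg.equivalent_capacitance)


def design_inamp(full_scale: float, max_input: float) -> AmplifierDesign:
    """Size an instrumentation amplifier to map max_input onto full_scale.

    ``G = full_scale / max_input`` and ``RG = 49.9 kΩ / (G - 1)``; a unity
    gain needs no gain resistor and is reported as ``RG = +inf``.
    """
    if max_input <= 0:
        raise ValueError("max_input must be positive")
    if max_input > full_scale:
        raise ValueError("max_input must not exceed full_scale (gain >= 1)")
    gain = full_scale / max_input
    rg = math.inf if gain == 1.0 else INAMP_RG_CONSTANT / (gain - 1.0)
    return AmplifierDesign(
        full_scale_voltage=full_scale,
        max_input_voltage=max_input,
        gain=gain,
        gain_resistor=rg,
    )


def mems_condition(v_piezo, cfg: OffsetStageConfig):
    """Divider + half-rail offset: divider_gain * v + Vcc/2, clamped to rails.

    Inputs beyond ±max_piezo_voltage are clamped at the rails with a
    warning, mirroring the hard saturation of the real adder stage.
    """
    v = np.asarray(v_piezo, dtype=float)
    if np.any(np.abs(v) > cfg.max_piezo_voltage):
        warnings.warn(
            "MEMS input exceeds the offset stage design range; clamping to rails",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.clip(cfg.divider_gain * v + cfg.offset, 0.0, cfg.supply_voltage)
    return float(out) if np.ndim(v_piezo) == 0 else out


def adc_quantize(v, cfg: AdcConfig):
    """Quantize a voltage to an integer code: floor(v/Vref * 2^bits), clamped."""
    x = np.floor(np.asarray(v, dtype=float) / cfg.reference_voltage * 2**cfg.bits)
    code = np.clip(x, 0, cfg.max_code).astype(np.int64)
    return int(code) if np.ndim(v) == 0 else code


def adc_dequantize(code, cfg: AdcConfig):
    """Bin-centre voltage of a code: (code + 0.5) * Vref / 2^bits."""
    v = (np.asarray(code, dtype=float) + 0.5) * cfg.lsb
    return float(v) if np.ndim(code) == 0 else v
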