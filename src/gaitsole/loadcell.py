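"""Load-cell reference scale: the weight ground truth behind all calibrations.

A 5 kg bar load cell (strain-gauge bridge) is linear in applied weight and
resolves ~1 g, which makes it the anchor for calibrating the nonlinear force
sensors.  Two bench configurations are modelled: the HX711-digitized rig
(raw full-scale output ~5 mV, slow 10 Hz channel) used for FSR staircases,
and the instrumentation-amplifier rig (~40 mV full scale feeding a fast
Arduino ADC) used for piezo press sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LoadCellModel",
    "CalibrationFactor",
    "LOADCELL_40MV",
    "LOADCELL_5MV",
    "estimate_calibration_factor",
    "loadcell_to_weight",
    "fit_loadcell_line",
]


@dataclass(frozen=True)
class LoadCellModel:
    """Linear load-cell forward model: output = sensitivity * weight + noise."""

    sensitivity: float          # volts (or counts) per gram
    max_load: float = 5000.0    # grams
    max_output: float = 0.04    # volts at max_load
    noise_sd: float = 0.0       # volts

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.sensitivity * self.max_load > self.max_output * (1 + 1e-9):
            raise ValueError("output at max_load exceeds max_output")

    def output(self, weight_g, rng: np.random.Generator | None = None):
        """Forward-simulate the cell output for a weight series (grams)."""
        v = np.asarray(weight_g, dtype=float) * self.sensitivity
        if self.noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            v = v + rng.normal(0.0, self.noise_sd, size=np.shape(v))
        return float(v) if np.ndim(weight_g) == 0 else v


#: Amplified rig cell: 40 mV at 5 kg (feeds the in-amp design, gain 125).
LOADCELL_40MV = LoadCellModel(sensitivity=0.04 / 5000.0, max_output=0.04)
#: Bare bridge output: 5 mV at 5 kg (HX711 path).
LOADCELL_5MV = LoadCellModel(sensitivity=0.005 / 5000.0, max_output=0.005)


@dataclass(frozen=True)
class CalibrationFactor:
    """Scale factor converting raw cell units to grams: W = (x - tare)/factor."""

    factor: float  # units per gram
    tare: float = 0.0

    def __post_init__(self) -> None:
        if self.factor == 0:
            raise ValueError("factor must be nonzero")


def estimate_calibration_factor(
    tare_readings, loaded_readings, known_mass: float
) -> CalibrationFactor:
    """Single-point calibration against an object of known mass.

    The factor is the per-gram change in reading between the unloaded (tare)
    window and the window with the known mass on the platform — i.e. the
    slope of the reading-vs-weight line through those two operating points.

    Parameters
    ----------
    tare_readings, loaded_readings
        Raw reading windows (counts or volts) with the platform empty and
        with the known mass resting on it.
    known_mass
        Mass of the reference object in grams; must be positive.
    """
    if known_mass <= 0:
        raise ValueError("known_mass must be positive")
    tare = float(np.mean(tare_readings))
    loaded = float(np.mean(loaded_readings))
    if loaded == tare:
        raise ValueError("loaded reading equals tare: degenerate signal")
    return CalibrationFactor(factor=(loaded - tare) / known_mass, tare=tare)


def loadcell_to_weight(reading, cf: CalibrationFactor):
    """Convert raw readings to grams: (reading - tare) / factor."""
    w = (np.asarray(reading, dtype=float) - cf.tare) / cf.factor
    return float(w) if np.ndim(reading) == 0 else w


def fit_loadcell_line(weights, voltages) -> tuple[float, float]:
    """Least-squares line voltage = slope * weight + intercept.

    Used for the dead-weight recalibration of the amplified rig: a few
    known masses are placed in turn and the cell outputs recorded.  Requires
    at least two distinct weights; exact on collinear data.
    """
    w = np.asarray(weights, dtype=float)
    v = np.asarray(voltages, dtype=float)
    if w.size < 2 or np.unique(w).size < 2:
        raise ValueError("need at least 2 distinct weights to fit a line")
    slope, intercept = np.polyfit(w, v, 1)
    return float(slope), float(intercept)
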