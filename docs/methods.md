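# Methods

## Acquisition-chain models

Every analog stage is a pure function with an explicit inverse where one
exists, so the simulator (physics → codes) and the pipeline (codes →
physics) share one set of equations.

**FSR divider.** The sensor forms the upper leg of a divider with a fixed
R = 11 kΩ: `Vout = Vcc·R/(R+FSR)`. The inverse `FSR = Vcc·R/Vout − R` is
valid only strictly inside the rails; voltages at 0 or Vcc indicate a
disconnected or saturated channel and raise. An unloaded FSR is treated as
an open circuit (R = +∞ → 0 V → code 0), which is what lets the segmenter
see true zeros between stance phases.

**Piezo divider.** 3 MΩ/9 MΩ gives static gain 0.25 (20 V peak → 5 V); the
element's ~9 nF equivalent capacitance in series with the 12 MΩ makes a
first-order high-pass with corner 1/(2π·12 MΩ·9 nF) ≈ 1.47 Hz. The chain
module exposes only the static gain and the corner formula; the dynamic
response lives in the simulator.

**Instrumentation amplifier.** For a load cell putting out at most 40 mV at
5 kg, the gain to fill a 5 V channel is G = 125 and the AD620-family gain
resistor RG = 49.9 kΩ/(G−1) ≈ 402 Ω. `design_inamp` computes both; unity
gain maps to RG = +∞ (no resistor fitted).

**MEMS offset stage.** The signed film voltage is scaled by 0.25 and shifted
by Vcc/2, mapping ±10 V affinely onto [0, 5] V; inputs beyond the design
range clamp at the rails with a warning.

**ADC.** `code = clamp(floor(v/Vref·2^bits), 0, 2^bits−1)`, dequantized to
the bin centre. Floor-with-clamp is the convention of common MCU SAR ADCs;
fixing it makes the quantization tests exact, and the round trip is bounded
by one LSB.

Two chain presets ship: `calibration-rig` (5 V rail, 10-bit, 1 kHz sensor
channel, 10 Hz load-cell channel) and `insole` (3.3 V rail, 10-bit, 60 Hz).
Because calibration recovers the *resistance*–weight law, a calibration
taken on the 5 V rig transfers to the 3.3 V insole unchanged.

## Load-cell reference

A 5 kg strain-gauge bar cell is linear to ~1 g. Two raw full-scale presets
are provided — 40 mV (instrumentation-amplifier rig; this is the value the
G = 125 design above assumes) and 5 mV (bare bridge into an HX711-style
digitizer) — because both configurations are plausible for this class of
cell and the two bench setups differ. Single-point calibration takes a tare
window and a known-mass window and returns units-per-gram; the dead-weight
line fit (≥2 distinct masses) is an ordinary least-squares polyfit. The
dead weights for the rig recalibration are 500/2500/5000 **grams** — the
cell itself is a 5 kg part, so tonne-scale masses would be nonsensical.

## Calibration fitters

**FSR staircase.** Weights are added in 500 g steps, 0 → 5000 g and back
(21 plateaus, ~4 s each). Plateau boundaries are load-cell jumps > 250 g
(half a step) between consecutive samples; the first 1 s after each
boundary is dropped as settling time. The protocol timing in the source
procedure is given only loosely ("every 3–4 s"), so both values are
configurable. Plateau (weight, mean-voltage) pairs are converted to
resistance through the divider inverse and fitted as `log W = log a +
b·log R` by least squares. Units are grams and kΩ: with the printed trial-1
coefficients this puts ~5 kg at 1 kΩ, which is dimensionally sensible for a
5 kg staircase; the choice is recorded in the calibration JSON. The
zero-weight plateau cannot enter a log fit and is excluded. Loading and
off-loading branches are fitted separately; the hysteresis metric is the
maximum relative gap between the two fitted curves over a 100-point
log-spaced resistance grid.

**Piezo press sessions.** Press events are local maxima of the piezo
voltage above a threshold (default 0.1 V), at least one window (default
0.5 s) apart, each paired with the maximum load-cell weight within half a
window. The fit is an ordinary line `W[kg] = m·V + c`; kilograms per volt
makes the printed slopes (~0.43 kg/V at up to 20 V) correspond to plausible
finger-press forces. Negative predicted weights are clamped to zero in
pipeline use; the stored fit is unclamped.

**MEMS repeatability.** Per-trial lines are fitted to (voltage, weight)
point sets; the sensor is flagged "axis-ambiguous, unsuitable for vGRF"
when trial slopes disagree in sign or their coefficient of variation
exceeds 0.30. The default limit was chosen so that slope spreads of the
magnitude seen in bench characterizations of this sensor class (CV ≈ 0.3
across trials with consistent sign) are flagged, matching the practical
judgement that such a sensor cannot anchor a weight conversion.

## Synthetic-data generator

The generator is first-class, tested code: it defines the ground truth every
pipeline stage is validated against.

**Stance vGRF.** No closed form is published for the M-shaped curve, so the
package uses the minimal smooth family with a controllable two-peak
structure: three Gaussian bumps (narrow at 20% and 80% of stance, σ = 0.12;
broad at mid-stance, σ = 0.18) whose coefficients are solved linearly so the
curve passes through peak_ratio·BW at both peak loci and valley_ratio·BW at
mid-stance, multiplied by 5% linear end tapers, clipped at zero, and finally
rescaled so the sampled maximum equals peak_ratio·BW exactly. Defaults:
body weight 77.3 kg (study-population mean), stance 0.7 s, stride 1.15 s,
peak ratio 1.05 (inside the physiological ±10% band), valley ratio 0.75.
Samples are placed strictly inside (0, 1) of normalized stance so every
stance sample carries load — at 60 Hz a 0.7 s stance is exactly 42 loaded
samples.

**Pressure distribution.** A piecewise-linear region-share table moves load
heel → metatarsals → hallux/toes across normalized stance (heel share 1.0 at
contact, >0.8 through the first ~10%); the last region's share is defined as
one minus the others so the 16 per-sensor forces sum to the input vGRF
identically. The table is a package invention, conservation-constrained and
documented here; real feet differ in rollover pattern.

**Sensor forward models.** FSR: force → resistance through the inverted
power law, 5% multiplicative resistance shift on unloading samples
(hysteresis, matching the "slight difference" between branches seen on the
bench), 5 mV Gaussian voltage noise on loaded samples, divider, ADC.
Ceramic piezo: `HP(charge_gain · dF/dt)` — no static response, positive
press peak, negative release rebound. Press *calibration* sessions instead
use the calibration line itself as ground truth (peak voltage = (W−c)/m on
a canonical biphasic pulse), the exact analogue of the staircase using the
power law as ground truth, so fitter recovery can be asserted to machine
precision. MEMS: scalar readout `g⃗·(m·û)` for unit press directions û.

**Walking trials.** Per foot, one stance per stride, right foot offset half
a stride (symmetric gait; asymmetry is injected by scaling one foot's
profile), optional per-cycle duration jitter (default 0 — the defaults
describe a metronomic walker; real cadence varies by a few percent), swing
samples at code 0. Identical seeds give identical recordings byte-for-byte
in CSV.

**What the simulator does not emulate:** shear forces, shoe–insole
mechanical coupling, FSR creep under long static load, temperature drift,
inter-sensor sensitivity spread, and multiplexer timing. Passing tests
therefore demonstrate the correctness of the computational stack, not the
field accuracy of any particular hardware build.

## Gait pipeline

Reconstruction maps each code through bin-centre voltage → divider inverse
→ power law and sums the 16 channels; code 0 short-circuits to zero weight.
Body-weight normalization computes `factor = BW / mean(vGRF over the
standing window)` and applies it only when the insole under-reads (factor ≥
1 always — the correction compensates sensors that miss load, and must not
shrink a valid signal). Segmentation takes maximal runs of samples above
0.5 kg (a literal non-zero rule is fragile against ADC noise; the threshold
is configurable) of at least 10 samples, and drops `discard_edges` (default
2, sensible range 1–3) runs at each end as gait initiation/termination.
Resampling is linear interpolation onto an inclusive uniform grid of 512
points — endpoint-preserving, idempotent on the 512 grid, and exactly
testable on ramps. Ensemble SD uses the sample (n−1) form, zero by
convention for a single segment. Peaks of the ensemble mean are the two
largest local maxima at least 20% of stance apart, the valley the minimum
between them; a mean with fewer than two local maxima (the piezo-insole
failure mode, where a whole stance collapses into one event) is flagged
`shape_atypical`. The symmetry index `SI = 200·|L−R|/(L+R)` % is one of
several conventions in the gait literature; it is a package choice, applied
by default to the first peak, and labelled as such in reports.

Piezo event detection is an upward threshold crossing with refractory
suppression. For stance/stride geometry like the defaults the refractory
period should slightly exceed the stance duration, so that the release
rebound of the same stance is suppressed but the next heel strike is not.

## Numerical and design notes

* All fits are ordinary least squares via `numpy.polyfit`; the power-law
  fit is exact (machine precision) on noise-free data, and is cross-checked
  in the tests against a brute-force grid search on the squared
  log-residuals.
* The staircase simulator stores the analog acquisition-input voltage by
  default; pass an `AdcConfig` to round it through the converter. The
  bench-printed calibration coefficients carry more precision than a 10-bit
  code grid, so the analog default keeps fitter-recovery checks meaningful.
* Degenerate inputs fail loudly: non-positive resistances/weights in a log
  fit, identical press peaks, fewer than two distinct line-fit weights,
  empty segment lists, a zero standing-window mean.
* Whether one shared calibration serves all 16 channels or each channel has
  its own file is configurable; shared is the default (the bench procedure
  calibrates sampled sensors, not each installed one).

## Limitations

Ensemble outputs can only be validated against synthetic ground truth — no
per-sample reference recordings of human trials are bundled. The pipeline
assumes the 512-point normalization spans stance only (segments end at
toe-off). The MEMS stage is characterized and diagnosed but deliberately
not wired into the vGRF path: its axis ambiguity makes a weight conversion
unreliable, which is precisely what the repeatability flag reports.
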