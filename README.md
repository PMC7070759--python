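# gaitsole

Signal-chain modelling, force-sensor calibration and vertical ground reaction
force (vGRF) analysis for low-cost smart insoles.

A smart insole instruments a shoe with 16 force sensors (over the heel,
metatarsal heads, hallux and toes — the medial arch bears little load) and
records each channel through an analog conditioning chain and a 10-bit ADC at
60 Hz. From those raw codes, the vGRF trace, gait-cycle statistics and
left/right symmetry can be computed anywhere a subject can walk, without a
force plate or motion-capture lab. `gaitsole` implements that full
computational stack for three sensor families:

* **FSR (force-sensitive resistor)** — resistance falls nonlinearly with
  force; read through a voltage divider `Vout = Vcc·R/(R + FSR)` and
  calibrated against a 5 kg load cell with a 500 g staircase protocol,
  yielding a power law `W = a·R^b` (e.g. trial 1: `W = 5035.2·R^-1.72`,
  grams vs kΩ). The workhorse sensor for vGRF.
* **Ceramic piezoelectric** — responds only to *changes* in force (modelled
  as a differentiator followed by the first-order high-pass formed by its
  equivalent capacitance and the 3 MΩ/9 MΩ divider, cutoff
  `f_c = 1/(2π(R1+R2)C) = 1.47 Hz`). Calibrated by press-and-release events
  against the load cell: `W = m·V + c` (kg vs V). Useful for detecting gait
  events, not for the vGRF waveform.
* **MEMS piezo film** — a 3-axis-sensitive film with a 1-D readout
  `v = g·F⃗`; repeated calibration trials flip sign or attenuate when the
  press direction wanders, so the package's repeatability diagnostic flags
  it as axis-ambiguous for vGRF use.

The gait pipeline sums the 16 reconstructed channel weights into a vGRF
trace, optionally rescales it so single-foot standing reads the known body
weight (scale-up only), segments stance phases as runs of consecutive loaded
samples (discarding the first/last cycles of a trial), time-normalizes each
stance to 512 points, and reports ensemble mean ± SD plus scalar metrics
(stance fraction of stride, peak/valley values and timings, symmetry index
`SI = 200·|L−R|/(L+R)` %).

A built-in simulator generates every input the hardware would produce —
M-shaped stance vGRF with peaks within ±10% of body weight, per-sensor
pressure distribution, staircase and press calibration sessions — so the
whole stack is testable end to end with known ground truth.

## Worked example

Simulate an 8-cycle walk, calibrate an FSR from a simulated staircase
session, and produce a gait report:

```
$ gaitsole simulate --cycles 8 --seed 7 --out-dir .
$ gaitsole simulate-staircase --noise-sd 0 --hysteresis 0 --out stairs.csv
$ gaitsole calibrate --type fsr --input stairs.csv --out cal.json
$ gaitsole report --left left.csv --right right.csv --calibration cal.json --out metrics.json
```

`metrics.json` then contains (abridged):

```json
{
  "feet": {
    "left": {
      "n_segments": 4,
      "peak1_kg": 75.8,
      "valley_kg": 53.8,
      "peak2_kg": 79.4,
      "stance_fraction_pct": 60.9,
      "time_to_first_peak_pct": 24.3,
      "time_to_second_peak_pct": 78.1
    }
  },
  "symmetry_index_pct": 1.15
}
```

Eight simulated cycles yield 4 analyzed segments after discarding two at
each end of the trial. The two vGRF peaks sit near the 77.3 kg default body
weight (heel strike ~24% and push-off ~78% of stance), the mid-stance valley
near 0.75× body weight, stance occupies ~61% of the stride, and the
left/right symmetry index of ~1% reflects the sensor noise and hysteresis in
the default simulation. The same steps can be driven from Python via
`gaitsole.insole_sim`, `gaitsole.calibration` and `gaitsole.gait_pipeline`.

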