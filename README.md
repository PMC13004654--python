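# hptaxis

A minimal, fully calibrated feedback model of the hypothalamic–pituitary–
thyroid (HPT) axis, built to ask one question quantitatively: **does it
matter where in a negative feedback loop the signal amplification sits?**

The package is for endocrine modellers and systems biologists who want a
small, transparent model of hormone homeostasis — steady states, local
sensitivity, loop-gain analytics and virtual populations — rather than a
full physiological simulator.

## The model

Three state variables — TRH (hypothalamus), TSH (anterior pituitary) and
TH (thyroid hormone, primarily T4) — are coupled by four Hill-type
regulatory steps and first-order clearance (time in hours, concentrations
in arbitrary units):

```
dTRH/dt = k5 · Kd5^n5 / (Kd5^n5 + TH^n5)                          − k6·TRH
dTSH/dt = k3 · Kd3^n3 / (Kd3^n3 + TH^n3) · TRH^n7 / (Kd7^n7 + TRH^n7) − k4·TSH
dTH/dt  = k1 · TSH^n1 / (Kd1^n1 + TSH^n1)                         − k2·TH
```

TH feeds back on TSH both directly (coefficient n3) and indirectly via
TRH (n5 then n7), so the loop's maximal percentage gain composes as
**(n5·n7 + n3)·n1**. Two presets place the same total gain of 8 at
opposite ends of the loop:

* **design_A** — amplifier in the brain: n1=1, n3=4, n5=2, n7=2
  ((2·2 + 4)·1 = 8);
* **design_B** — amplifier in the thyroid: n1=4, n3=n5=n7=1
  ((1·1 + 1)·4 = 8).

Everything else is shared and derived from physiological constraints:
clearance constants from half-lives (TRH 6 min, TSH 1 h, TH 6 days),
affinities such that every Hill step sits at 10% activity at the basal
operating point, and production rates such that the basal steady state is
(TRH, TSH, TH) = (1, 1, 15). `design_A_printed` / `design_B_printed`
carry the rounded constants as conventionally quoted.

## Worked example

```python
from hptaxis import (PopulationSpec, fit_log_linear, gain_from_population,
                     get_preset, sample_population, steady_state)

base = get_preset("design_A")
print(tuple(steady_state(base)))          # (1.0, 1.0, 15.0)

pop = sample_population(PopulationSpec(
    base=base, varied=(("k1", 0.2),), n_individuals=500, seed=42))
slope, intercept, r = fit_log_linear(pop)
print(round(slope, 4), round(r, 3))       # -0.4557 -1.0
print(round(gain_from_population(pop), 3))  # 6.836
```

Varying the thyroid's secretory capacity `k1` (log-normal, CV 0.2) across
500 virtual individuals reproduces the inverse log-linear TSH–TH
relationship observed in human cohorts: ln(TSH) falls by 0.456 per TH
unit with r ≈ −1.00, and the population logarithmic gain of 6.84 matches
the local feedback-arm slope n3·0.9 + (n5·0.9)(n7·0.9) = 6.84. Placing the
same variability on the pituitary side (`k3`) flips the association
positive — the signature that clinical variability originates mainly in
the thyroid, not the brain.

The `examples/` directory holds one short narrative script per
capability (steady state & stability, sensitivity analysis, loop-gain
analytics, virtual populations); each prints its numbers with a line on
what they mean. The same operations are scriptable from a shell:

```
hptaxis steady --design A
hptaxis sensitivity --design B --out sens_B.csv
hptaxis population --design A --vary k1 --cv 0.2 --n 500 --seed 42
```

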