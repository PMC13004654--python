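# Methods

## Model

The HPT axis is reduced to a three-variable negative feedback loop: TRH
stimulates TSH, TSH stimulates TH, and TH inhibits both TRH and TSH
production. Each regulatory step is a Hill function (stimulatory
`x^n/(Kd^n+x^n)` or inhibitory `Kd^n/(Kd^n+x^n)`), each hormone is
cleared by first-order kinetics, and production terms multiply where two
regulators converge (the TSH equation). The single TH variable stands
primarily for T4; T4/T3 interconversion, deiodinases, binding proteins,
transport delays and pulsatility are deliberately out of scope — the
model exists to compare amplifier placements, not to fit clinical
kinetics.

Assumptions worth stating explicitly:

* regulation is instantaneous (no delays) and deterministic;
* clearance is linear in the hormone level;
* the two feedback arms act independently and multiply into the TSH
  production term;
* concentrations are arbitrary units; time is hours.

## Calibration

A full parameter set derives from four constraint groups, applied in
order:

1. **Clearances from half-lives**: k = ln2/t½ with defaults TRH 6 min
   (k6 = 6.93 h⁻¹), TSH 1 h (k4 = 0.693 h⁻¹), TH 6 days (k2 = 0.00481 h⁻¹).
   These are literature-scale human values; the ~3-order-of-magnitude
   timescale separation is what keeps a loop gain of 8 stable (see
   below). One published tabulation pairs the half-life *list* with the
   clearance constants in the opposite order from what the constants
   themselves imply; this package trusts the numeric constants (TH is
   the slow pool, TRH the fast one), which is also the physiological
   ordering.
2. **Affinities from basal activity**: every Hill step is required to sit
   at 10% of maximum at the basal state, i.e. the step's *value* is 0.1 —
   for the inhibitory feedback arms this means 90% receptor occupancy.
   This is the only reading consistent with all eight quoted affinity
   constants (e.g. Kd3 = 15·(0.1/0.9)^(1/4) = 8.66). Keeping every step
   near the foot of its response curve leaves each arm most of its
   dynamic range and puts the local slope at 90% of its maximum n.
3. **Production rates from the steady-state balance**: k_prod =
   k_clear·y_ss / (product of Hill activities), with target state
   (TRH, TSH, TH) = (1, 1, 15). The TSH equation carries two Hill factors,
   hence k3 = 0.693·1/0.01 = 69.3.
4. **Hill coefficients choose the design**: (n1, n3, n5, n7) = (1, 4, 2, 2)
   for the brain-amplified design A, (4, 1, 1, 1) for the
   thyroid-amplified design B; both compose to (n5·n7 + n3)·n1 = 8.

The calibration uses unrounded values (k2 = ln2/144 = 0.004813…).
Presets with the conventionally quoted roundings (0.0048, 8.66, 1.7321,
1.6667) are shipped as `design_A_printed` / `design_B_printed`; their
steady states deviate from (1, 1, 15) by <0.5%, and tests allow 1% for
them. Whether the rounded or unrounded constants were used in prior
simulations of this system is not documented; providing both makes the
question moot.

## Numerics

* Hill functions are evaluated as `1/(1+exp(n·(ln Kd − ln x)))`, which is
  exact to machine precision and immune to overflow for large
  `n·|ln(x/Kd)|` (clamped beyond ±700). `x = 0` returns the exact limit
  value; derivatives at 0 are not guaranteed for n < 1.
* Integration uses LSODA with rtol 1e−9, atol 1e−12. The system is stiff:
  the Jacobian eigenvalues at the basal state span −6.93 to −0.036 h⁻¹
  (ratio ≈ 190).
* Steady states come from a Powell-hybrid root solve; convergence is
  judged dimensionlessly, |dX/dt| < tol·(k_clear·X + 1e−12) with
  tol = 1e−9, so the criterion is meaningful at small concentrations. On
  failure the system is first relaxed along the flow for 20 TH half-lives
  and the solve retried; an unconverged result raises rather than
  returning a bad root. Mono-stability is asserted (and tested from
  multiple starts) only for the built-in presets, not for arbitrary
  user parameters.
* The analytic Jacobian uses dH/dx = ±(n/x)·H·(1−H) and therefore
  requires strictly positive states; it is cross-checked against central
  finite differences in the tests.

## Sensitivity analysis

`finite_difference_sensitivity` implements the one-at-a-time protocol:
each of the 14 constants is perturbed by ±10% (Hill coefficients
multiplicatively, like every other constant), the steady state is
re-solved starting from the unperturbed one, and the relative
sensitivity S = (Δy/y)/(Δp/p) is reported for both directions plus their
mean ("symmetric"); whether published bar charts of this protocol
average the two directions is not stated, so all three are kept.
`analytic_sensitivity` is the independent oracle: log-differentiating
the three balance equations gives a 3×3 linear system whose coefficients
are the local logarithmic slopes n·(1−f) / −n·(1−h) of the four steps;
solving it for each parameter's forcing vector yields the infinitesimal
sensitivities in closed form. The two routes agree to <1e−3 absolute at
δ = 1e−4 for both presets (tested), and the δ = 0.1 protocol deviates
from the analytic values by only a few percent — the classification
threshold of 0.3 sits well clear of both.

The design comparison that motivates the package: in design A the only
TH-sensitive constants (|S| ≥ 0.3) are brain-side (Kd3, Kd5, n5), while
thyroid and clearance perturbations are damped to |S| ≈ 0.14 ≈ 1/(1+L)
with local loop gain L = 0.9·(3.6 + 1.8·1.8) = 6.156; in design B the
pattern inverts — TH is insensitive only to k1, k2, n1.

## Loop-gain analytics

Step gains are local logarithmic slopes, signed by regulation mode; the
loop gain composes as |TSH→TH|·(|TH⊣TSH| + |TH⊣TRH|·|TRH→TSH|), the two
feedback pathways summing before the thyroid step. The structural
maximum (n5·n7 + n3)·n1 is attained only in the zero-saturation limit;
at the 10%-activity basal state the local gain is 0.9²·… = 6.156 for
both designs. The loop gain is defined here off the basal state by the
standard local-slope extension; only its basal value is constrained by
the calibration. Complementary fold-change tools: `log2_gain` (gain per
input doubling), `hill_dynamic_range` (81^(1/n)-fold input change for a
10→90% response swing) and `exponential_feedback_gain` (−φ·TH, the
non-constant gain of the exponential feedback laws used in several
published thyroid models, equal in magnitude to 1 exactly at φ·TH = 1).

## Virtual populations

Each individual copies the base parameter set with selected constants
drawn independently log-normally (median at the base value, log-SD
√ln(1+CV²) — log-normal because rates are positive and multiplicative
variation is the natural null model; no distribution is prescribed by
the underlying argument). Each individual is solved to steady state;
non-convergent individuals are excluded with a count, and >5% failures
abort. ln(TSH) is regressed on TH to mirror the clinical logTSH–fT4
convention; the ln–ln variant (negated slope) estimates the feedback
gain. Parameters are varied one at a time with no covariance, matching
the single-site argument being tested.

What the generator emulates: interindividual parameter variability at a
chosen anatomical site, and nothing else. It omits measurement noise,
within-individual temporal variation, covariation between parameters,
assay nonlinearity and cohort selection effects — so a passing test
shows the *mechanistic* sign/gain structure, not that real cohort data
would be fit quantitatively. The default CV of 0.2 is illustrative; no
quantitative interindividual CV is claimed for real populations.

## Design choices that were genuinely open

* **Sensitivity directions**: report both one-sided coefficients and
  their mean rather than picking one.
* **Gain reporting**: signed at step level, magnitude at loop level (the
  loop gain is conventionally quoted positive).
* **Steady-state protocol**: root-finding first with an integration
  fallback, rather than integration alone — faster and it makes the
  convergence criterion explicit instead of "ran long enough".
* **Config schema**: exactly one parameter source (preset | inline
  constants | calibration spec) with unknown keys rejected, so a typo
  cannot silently produce a default run.
* **Problem sizes**: populations of 500 (300–400 in convergence tests)
  and 14×2 steady-state solves per sensitivity table; each table or
  population takes well under a second, so the full suite runs in a few
  seconds.

## Known limitations

* No allostatic scheduling: setpoint shifts must be imposed by editing
  brain-side parameters by hand.
* No bifurcation analysis; stability is checked only at located steady
  states.
* The model cannot distinguish T4 from T3 effects, so quantitative
  comparison with fT3 data is out of scope.
* Local (±10%) sensitivity only; no global (Sobol/Morris) methods.
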