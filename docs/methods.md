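# Methods

## Measurement model

A dry granular fraction of nominal mass `m1 = 2 g` is degassed in two
stages in an initial liquid volume `V3 = 2 mL` (passive saline soak,
then active ultrasonic treatment in citric acid). The recovered volumes
`V1` (after the passive stage) and `V2` (after the active stage) and the
wet masses `m2` (liquid retained in intergranular spaces) and `m3`
(intergranular liquid drained) define the indicators

    AC_A = (V3 − V1) + (V1 − V2)           [mL]
    W_mA = (m2 − m1) / m1 × 100            [%]
    W_mB = (m3 − m1) / m1 × 100            [%]

`AC_A` is computed as the literal two-term stage sum; the telescoping
identity `AC_A = V3 − V2` is asserted by property tests rather than used
as the implementation, so the per-stage contributions remain reportable.

### Pore regime and the true capacity

Micropores (BJH volume per gram) are too small for growth-factor-scale
adsorbates, so the apparent capacity is corrected by regime:

* MACRO (micropore volume < 1 cm³/g): `AC_T = AC_A`;
* MIXED (1–10 cm³/g, closed interval): `AC_T = AC_A × ((W_mA − W_mB)
  + 0.85 W_mB) / W_mA` — 85 % of the drained-state uptake is
  attributed to macropores;
* MICRO (> 10 cm³/g): `AC_T = AC_A × (W_mA − W_mB) / W_mA`.

Both band edges (exactly 1 and exactly 10 cm³/g) classify as MIXED; the
thresholds and the 0.85 factor are configurable (`PoreRegimeConfig`).
A `regime_override` field exists because regime assignment is ultimately
a judgement combining porosimetry with SEM observations: one study
fraction (Xenograft Collagen, 10.945 cm³/g) is treated under the mixed
rule despite sitting just above the nominal band, and ships with its
override pinned accordingly.

Recomputing `AC_T` from the published per-sample values reproduces the
published column to within one unit in the third decimal; exact
3-decimal equality is not attainable because the published inputs are
themselves rounded (the two corrected rows recompute to 0.3867 and
0.8958 against printed 0.386 and 0.895). MACRO rows are exact by
construction.

### Capacity gain

`gain = 100 × AC_A / V3`, reported both raw and rounded to the nearest
integer. One published per-sample gain figure (17 % for the most
microporous fraction) is not derivable from its published capacity
(which gives 35 %) and is deliberately not reproduced.

## Compaction coefficient

The chain of derived quantities is evaluated literally as specified on
the bench sheet: bed volume `V = (π r² h)/4` (a cylinder only if `r` is
the bore diameter; the field is kept as `r`, and the geometric factor
cancels), bulk/tapped densities, water adsorption by mass and by volume,
and the dependency coefficients `d = W_vE/W_mE`, `d_max = W_vC/W_mC`.
Algebraically `d = ρ_e`, `d_max = ρ_c` and

    C_C = d_max / d = ρ_c / ρ_e = V_E / V_C = h1 / h2,

a Hausner-style tapped-to-bulk ratio. Property tests assert the full
chain and each reduction agree to 1e−12 relative error, and that `C_C`
is invariant to the bore and the saturation masses. Zero uptake
(`m4 = m1`) is rejected rather than silently falling back to the
height ratio, so the literal chain and the reduced form can never
disagree. Replicates are summarized mean ± sample SD (n−1).

## Degassing kinetics

The remaining liquid percentage follows the 4-parameter logistic

    f(t) = d + (c − d) / (1 + exp(−a (t − b))),

evaluated through the logistic sigmoid (`expit`) so large `|a (t − b)|`
saturates at the asymptotes without overflow. `d` is fixed at 100 % by
default (series are normalized to the initial volume); `d_fixed=None`
frees it for non-normalized data.

Fitting is unweighted nonlinear least squares (`scipy.optimize.curve_fit`,
parameter/function tolerances 1e−10, max 500 iterations worth of
function evaluations) on all replicate points; with balanced replicates
this equals fitting the per-time means (pure-error decomposition),
asserted on synthetic data. Initial guesses: `c` at the series minimum,
`b` at the time of the observation nearest the half level, `a = 0.5`/min
— robust for monotone release curves. Standard errors come from the
Jacobian-based covariance at the optimum; R² is the unadjusted nonlinear
`1 − SS_res/SS_tot` over the fitted points and may be negative for a
model worse than the flat mean. Fewer than four distinct times or a
constant series raise typed errors rather than returning a degenerate
fit.

Per-time replicate summaries report mean, sample SD, SEM and the
two-sided Student-t interval `mean ± t_{n−1, 1−α/2} · SEM` (default
95 %); a single replicate yields an undefined SD (reported as null) and
a point interval.

## Synthetic-measurement generator

Generators invert the forward formulas so that at zero noise the
pipeline returns the fixture targets exactly:

* adsorption bench: `m2 = m1 (1 + W_mA/100)`, `m3 = m1 (1 + W_mB/100)`,
  `V2 = V3 − AC_A`, and `V1 = V3 − p·AC_A` with the passive-stage share
  `p = 0.38/0.56 ≈ 0.679` taken from the reference two-stage
  measurement (configurable per fixture; downstream indicators are
  independent of the split);
* compaction bench: `h2 = 1 cm`, `h1 = C_C`, `r = 1 cm`,
  `m4 = m5 = m1 (1 + W_mA/100)`;
* degassing series: `pct = f(t) + N(0, σ²)` per replicate.

Noise placement follows the measurement process. The dry mass and the
dispensed `V3` are protocol constants, so replicate scatter is
multiplicative (relative SD, default 0.01) on the measured quantities
`m2, m3, V1, V2` (and `m4, m5, h1, h2`). With that placement the
implied SD of `AC_A` is `0.01 × V2 ≈ 0.013–0.014 mL`, matching the
±0.015 scale of the published replicate SDs; noise on `V3` as well
would inflate it to ≈0.025. Raw replicate noise magnitudes were never
published, so the 0.01 default is a calibration choice. Degassing noise
is additive on the percentage scale (default σ = 0.7 %), calibrated to
the published 95 % confidence-interval half-widths, which show no
strong trend with time (homoscedastic Gaussian). Every generator takes
one explicit integer seed (`numpy.random.default_rng`); no global state.

What the generator does *not* emulate: drift or autocorrelation between
replicates, heteroscedastic pipetting error, evaporation, operator
entry mistakes (exercised separately via hand-built invalid sheets),
or any structural misfit of the logistic form. Passing tests therefore
demonstrate correctness of the computational pipeline under the stated
statistical model, not the field validity of that model.

## Problem sizes and numerical checks

The recovery study runs 200 seeded simulated experiments (nine time
points, triplicates, σ = 0.7 %) and checks the median absolute
parameter errors against the published standard errors (0.04, 0.17,
0.35); Monte-Carlo SD propagation uses 10⁴ replicates per fixture
against a first-order delta-method prediction at 10 % relative
tolerance. Property suites sample 100–300 cases per invariant
(derandomized). These sizes keep the full suite under a few seconds
while leaving the stochastic margins wide.

## Design choices in open territory

* `V3` is always an explicit field (default 2.0 mL), never inferred
  from bed height; the bench protocol's volume wording is ambiguous.
* Report rounding: volumes half-to-even to 3 decimals, percentages to
  2, matching the published precision; raw values are always retained
  alongside.
* Validation is strict by default; `--lenient` downgrades row-level
  invariant violations to logged warnings and skips the rows, keeping
  the skipped line numbers in the report.
* The planner reads `C_C` as a multiplier on the dry volume ordered for
  a defect (`dry = defect × C_C`, `bgf = dry × AC_T per mL`). This is
  an interpretation of how the coefficient enters surgical planning and
  is flagged as interpretive in the CLI output.
* JSON for machine reports, CSV for table-style exports; each report
  carries a provenance block (input SHA-256, config, tool version).

## Known limitations

* Regime classification consumes porosimetry scalars and SEM booleans;
  no isotherm or image processing is performed.
* The unweighted least-squares loss is an assumption; the original fit
  was produced by a commercial statistics package whose exact weighting
  is unstated.
* `C_C` summaries assume replicate independence; vibratory-table
  physics is out of scope.
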