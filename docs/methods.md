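# Methods

## Scope and model chain

`fluorisk` models chronic dietary fluoride exposure from coal-roasted
foods as a chain of small, separately testable computations:
bioavailability estimation → deterministic dose/hazard arithmetic →
distribution fitting → Monte Carlo propagation → intake-limit inversion.
The wet-lab side (digestion chemistry, cell culture, electrode
measurement) is out of scope; assay records enter as data, with the TEER
monolayer-integrity outcome carried as a boolean QC flag, not modelled.

## Bioavailability

A transwell assay measures apical-side depletion:
`RBA = (C_IV − C_AV)·V_IV / (T_S·M_S)`. The quantity is dimensionless
only when `C_IV`, `C_AV` are concentrations in mg/L, `V_IV` a volume in
L, `T_S` the food's total fluoride in mg/kg and `M_S` the digested mass
in kg; that assignment is the one implemented. Note the operational
assumption: depletion on the apical side is equated with transport.
Whether all depleted fluoride truly crosses the monolayer (rather than,
say, adsorbing to it) is an interpretation left to the user.

Numerical policies:

* RBA lives in the code as a fraction in [0, 1]; percent appears only in
  CSV columns suffixed `_percent`. This prevents double-×100 errors.
* `c_av > c_iv` (negative raw RBA) is measurement noise near zero
  absorption, not an invalid input: the value is clamped to 0 with a
  warning. Non-positive `v_iv`, `t_s`, `m_s` are rejected outright.
* Per-stage aggregation is the arithmetic mean of per-assay RBA
  fractions (not a pooled-concentration ratio), and the absorbed dose is
  mean concentration × mean RBA. Assays with `teer_ok = false` are
  excluded by default, overridable per call.

## Exposure arithmetic

`ADD = C·IR·EF·ED/(BW·AT)` with `HQ = ADD/RfD` and `HI = Σ HQ`. Default
parameters: exposure frequency 365 d/a; averaging time `ED × 365` d
(under which the chain reduces exactly to `C·IR/BW`); fluoride oral
reference dose 0.06 mg/kg/d. Two population groups ship as defaults —
children (BW 25.9 kg, ED 9 a) and adults (BW 56.8 kg, ED 70 a) — with
per-food median and (min, max) daily intakes from a household survey in
a fluorosis-endemic area. The children's intakes are the survey medians
themselves; no adult-halving rule is applied.

`IR_max` inverts the chain at a hazard target (default 1, exposed as a
parameter since the threshold is one point of a family). The
bioavailability-corrected variant divides by RBA: only absorbed fluoride
counts toward dose, so the allowable intake of a food with 10%
bioavailability is 10× higher. Substituting the returned intake back
into the forward chain recovers the target exactly (tested to 1e-12).

Stage-level point estimates use the mean over the (three) replicate
concentrations at each food × day. Report output rounds HQ/HI to 2 and
IR_max to 3 decimals; internal computation is never rounded.

## Distribution fitting and selection

Five two-parameter candidate families: normal, lognormal, logistic,
Gumbel in the maximum convention (the "maximum extreme value" family in
commercial risk software), Weibull. Normal/lognormal MLEs are closed
form (moments of the data or its log, population-variance convention).
The other three minimise the negative log-likelihood with L-BFGS-B
(≤ 200 iterations, objective tolerance 1e-8) from method-of-moments
starting values — deterministic and seed-free; non-convergence returns a
flagged result rather than an error. Zero intakes (the survey minima
include 0) are dropped with a warning before fitting positive-support
families and retained for real-line families. Degenerate (zero-variance)
samples are rejected.

Candidates are ranked by the Anderson–Darling statistic
`A² = −n − (1/n) Σ (2i−1)[ln u_(i) + ln(1 − u_(n+1−i))]` on the fitted
CDF values, clipped to [1e-12, 1−1e-12] if they reach the boundary.
A² is tail-weighted, appropriate when the upper tail drives risk. It is
a ranking score only: case-0 critical values are invalid once parameters
are estimated, so no p-value is attached by default; a seeded
parametric-bootstrap p-value is available explicitly
(`ad_bootstrap_pvalue`). Ties within 1e-9 break by higher log-likelihood,
then family name. With only three replicate concentrations per roasting
stage, concentration is modelled as normal with the sample mean and SD,
screened (not gated) by Shapiro–Wilk.

## Monte Carlo

Per iteration, concentration and intake are drawn independently
(inverse-CDF on a seeded uniform stream) and pushed through the HQ
chain; the hazard index sums the per-food draws within an iteration,
independent across foods. No correlation structure is imposed — the
minimal assumption, and a known limitation: shared cooking habits could
correlate intakes across foods.

* **Negative draws** are retained by default. A normal concentration
  model with CV near 1 has ~16% of its mass below zero, so the 5th HQ
  percentile is legitimately negative; `truncate_negative=True` clips
  draws at zero, which can only raise the mean and the lower percentile.
* **Quantiles** use linear interpolation (k-th order statistic at
  probability (k−1)/(n−1)), fixed and documented for reproducibility.
* **Streams**: one master seed plus a SHA-256 hash of
  (food, roast day, group, role) keys an independent substream per
  scenario component, so adding a scenario never perturbs another's
  draws, and identical configurations give bit-identical summaries.
  A consequence: the hazard index uses the same per-food draws as the
  per-food HQ runs, so its mean equals the sum of the HQ means exactly.
* Default 10,000 iterations; fewer than 20 with percentile requests
  triggers an instability warning.

## Synthetic study generator

The generator emulates the study design — 4 foods × roasting days
{0, 5, 10, 15, 20, 25, 30} × 3 replicates (84 records), two population
groups — with known ground truth, written alongside the data as
`ground_truth.json`.

* **Accumulation curve**: `C(t) = c0 + (c_asym − c0)(1 − e^(−rt))`, with
  the asymptote back-solved so the mean hits the observed end-of-roast
  concentration exactly at day 30 (fresh/day-30 pairs: corn 1.72→308.24,
  chili 8.56→869.82, pork 6.47→141.59, tofu 6.19→265.70 mg/kg). Chili
  carries a compact half-sine mid-roast dip (30% deep over days
  12.5–20), emulating the transient drop some foods show; the dip never
  touches day 0 or day 30. The curve is generator-only — it is never
  fitted or used for inference.
* **Replicate noise** is multiplicative normal with CV 5% (clamped at
  0). The measurement method alone has RSD ≈ 2%; 5% adds biological
  spread. Real per-stage dispersions are unknown, so this is a stand-in,
  flagged as such in the manifest.
* **Assays** invert the RBA equation with digestion constants
  `m_s = 0.0001` kg and `v_iv = 0.0005` L: `c_iv` is set to the fully
  released level `t_s·m_s/v_iv` (so any target ≤ 1 is representable) and
  `c_av = c_iv(1 − target)`. Noise-free assays reproduce their target
  through the forward computation to 1e-9 (machine precision in
  practice). Per-day RBA targets ramp linearly across the observed
  (fresh, end-of-roast) ranges: chili 2.18→12.00%, corn 3.92→12.42%,
  pork 3.79→9.76%, tofu 2.20→11.63%.
* **Intake surveys** draw from the families the study setting selects —
  Gumbel-max for chili and tofu, logistic for corn, Weibull for pork —
  with distribution means placed at the survey median intakes (Gumbel
  scale = median/5, logistic scale = median/5, Weibull shape 1.5). These
  yield risk magnitudes of the right order without claiming to
  reproduce any published stochastic summary, whose generating
  parameters are unpublished. Clamping to the survey (min, max) is
  available but off by default, because clamping biases the MLE recovery
  the bundle exists to test.

What passing tests show — and do not. Ground-truth recovery on this
generator demonstrates that the estimation chain is self-consistent:
correct formulas, correct seeding, correct inversion. It does not
validate the normality of real concentration replicates, the
independence assumptions, or the biological interpretation of apical
depletion as absorption.

## Problem sizes and tolerances

Parameter recovery is checked at 5,000 draws (±5% relative), family
selection at 1,000 draws (≥ 80/100 seeded trials), the Monte Carlo
analytic-mean bridge at 10,000 iterations over 20 seeds (3-SE bound),
and the convergence-rate diagnostic over n ∈ {10², 10³, 10⁴, 10⁵}
(log-log slope −0.5 ± 0.15). Degenerate (zero-variance) Monte Carlo must
match the deterministic point estimates to 1e-12. The default analysis
bundle uses 500 survey draws per group-food — enough for stable fits,
small enough to keep the full pipeline interactive.

## Known limitations

* Concentration-normality at n = 3 per stage is asserted, not tested.
* Independence of concentration and intake, and of intakes across
  foods, is assumed throughout.
* The accumulation curve and the linear RBA trajectory are generator
  conveniences, not mechanistic models of fluoride deposition.
* Only the chronic non-carcinogenic oral pathway is modelled: no dermal
  or inhalation routes, no slope-factor (carcinogenic) risk, no
  age-interpolated exposure durations.
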