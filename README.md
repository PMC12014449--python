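# fluorisk

Dietary fluoride risk assessment for foods roasted over high-fluoride coal.

In parts of Southwest China, households roast staple foods (corn, chili,
pork, tofu) over briquettes made from high-fluoride coal. Airborne fluoride
deposits on the food, so fluoride intake — and fluorosis risk — depends on
how long food is roasted, how much of it people eat, and how much of the
accumulated fluoride the gut actually absorbs. `fluorisk` implements the
full assessment chain for this setting, for exposure scientists and public
health analysts:

1. **Relative bioavailability (RBA)** from Caco-2 transwell transport
   assays on in-vitro digestive fluid, via apical-side depletion:

   `RBA = (C_IV − C_AV) · V_IV / (T_S · M_S)`

   with apical fluoride concentrations before/after incubation (mg/L),
   applied volume (L), the food's total fluoride (mg/kg) and the digested
   sample mass (kg).

2. **Deterministic risk arithmetic** (EPA chronic oral exposure):

   `ADD = C·IR·EF·ED / (BW·AT)`, `HQ = ADD/RfD`, `HI = Σ_foods HQ`,

   with per-food contribution shares `HQ_i / HI`, and the inversion

   `IR_max = HQ_target·RfD·BW·AT / (C·EF·ED)`

   — the maximum allowable daily intake of a contaminated food, optionally
   bioavailability-corrected by replacing `C` with `C·RBA`.

3. **Distribution fitting and selection**: maximum-likelihood fits of
   normal, lognormal, logistic, Gumbel (maximum convention) and Weibull
   families to intake surveys, ranked by the Anderson–Darling statistic,
   with a Shapiro–Wilk normality screen for the small per-stage
   concentration samples.

4. **Seeded Monte Carlo**: per-iteration draws of concentration and intake
   propagated through the HQ/HI chain (default 10,000 iterations),
   summarised as mean, 5th/95th percentiles and Pr(HQ > 1). Negative
   concentration draws are retained by default (the normal stage model has
   real mass below zero); truncation at zero is an explicit option.

5. **A synthetic study generator** with known ground truth — saturating
   accumulation curves per food, assays constructed by inverting the RBA
   equation, surveys drawn from named families — so every stage is testable
   end to end without any external data.

## Worked example

```python
from fluorisk import (exposure_parameters, average_daily_dose,
                      hazard_quotient, ir_max)

children_corn = exposure_parameters("children", "corn")  # survey defaults
hq = hazard_quotient(average_daily_dose(308.24, children_corn))
print(round(hq, 2))            # 1.98  -> children eating peak-roast corn
print(round(ir_max(1.72, children_corn), 2))    # 0.9  kg/d, fresh corn
print(round(ir_max(869.82,
      exposure_parameters("children", "chili")), 3))    # 0.002 kg/d
```

A child eating median amounts of corn roasted for 30 days is at nearly
twice the hazard threshold (HQ 1.98 ≥ 1), and a daily intake of only 2 g
of peak-roast chili already reaches HQ = 1, against 900 g of fresh corn.

The numbered scripts under `analysis/` run the whole study on a synthetic
bundle and narrate their findings:

```sh
python analysis/01_simulate_study.py     # seeded study bundle -> results/study/
python analysis/02_bioavailability.py    # RBA and absorbed dose per food/day
python analysis/03_point_risk.py         # deterministic HQ/HI + shares
python analysis/04_fit_intake_distributions.py
python analysis/05_monte_carlo_risk.py   # 10k-iteration HQ/HI summaries
python analysis/06_intake_limits.py      # IR_max with/without bioavailability
```

The same stages are exposed as a CLI (`fluorisk simulate-data | rba | risk |
fit-dist | mc-risk | irmax | report`); `report` runs everything and writes
the merged CSV set plus a plain-text summary. Commands that draw random
numbers require an explicit `--seed`.

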