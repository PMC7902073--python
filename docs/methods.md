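# Methods

## Model structure

A cohort of men with metastatic hormone-sensitive prostate cancer
enters a three-state transition model in the progression-free (PFS)
state and moves to progressed disease (PD) and death over 1-month
cycles for 240 cycles (20 years). Two strategies are compared:
enzalutamide 160 mg daily plus ADT versus a conventional non-steroidal
antiandrogen plus ADT.

State occupancy is **curve-tracking** (partitioned-survival
consistent): at every cycle boundary `pfs(t) = S_pfs(t)`,
`dead(t) = 1 − S_os(t)`, `pd(t) = S_os(t) − S_pfs(t)`. This uses only
the two published survival curves per arm and avoids inventing a
post-progression hazard, at the price of not modelling how death is
split between the PFS→death and PD→death routes (the split does not
affect costs or QALYs under state-membership accounting). The
equivalent per-cycle transition probabilities
`p_i = 1 − S((i+1)c)/S(ic)` are exported for audit, and a forward
Markov recursion driven by them reproduces the trace to machine
precision. A run aborts with a structural-inconsistency error naming
the first offending cycle if the PFS curve ever rises above the OS
curve, which can happen with incompatible user-supplied evidence (or
extreme PSA draws; see below).

## Survival evidence

All efficacy evidence is carried by two-parameter Weibull survival
functions `S(t) = exp(−(t/λ)^k)` (t in months). Two calibration routes:

* **landmark + HR** (default): the standard-care curve is solved in
  closed form through its published 3-year landmark
  (`λ = t/(−ln S)^{1/k}`), and the enzalutamide curve derived under
  proportional hazards, `S_enza = S_soc^{HR}`, which preserves the
  shape and multiplies the scale by `HR^{−1/k}`. One landmark cannot
  identify two parameters, so the shape is an explicit configuration
  default, `k = 1` (exponential). This route uses only published
  numbers and is exactly reproducible.
* **digitized**: ordinary least squares on the complementary-log-log
  linearization `ln(−ln S) = k ln t − k ln λ` of a digitized
  Kaplan–Meier point series (points with S = 1 or t = 0 excluded;
  ≥ 3 usable points required; R² of the linear fit attached to the
  returned curve). This mirrors how the original evidence was actually
  produced; the package consumes such series from CSV or from the
  synthetic generator, never from images.

The base case drives progression with **clinical PFS** (landmarks
68 %/41 %, HR 0.40); PSA-progression evidence (67 %/37 %, HR 0.39) is
selectable by configuration. Note the published clinical-PFS landmarks
are not internally PH-consistent (0.41^0.40 ≈ 0.700 ≠ 0.68), so under
the default route the modeled enzalutamide clinical-PFS landmark is
70 %, not 68 %; the OS evidence is consistent (0.72^0.67 ≈ 0.803 ≈ 80 %).

## Discounting and accumulation

Costs and QALYs are discounted with the compound-equivalent monthly
factor `(1 + r)^{−i/12}` (r = 3.5 %/yr US, 3 %/yr China). Each cycle
contributes occupancy-weighted utility (`u_pfs`, `u_pd`; death 0) times
1/12 year, and occupancy-weighted state costs, using start-of-cycle
membership; an optional half-cycle correction (averaging adjacent
boundaries) is off by default. One-off costs are charged undiscounted
at entry.

## Costing

Per-cycle PFS cost = oral drug (units/day × 30.4375 days/cycle × unit
price) + ADT backbone (mix-weighted depot price per cycle) + monitoring
(laboratory panel, PSA test every cycle; CT and bone scan every third
cycle) + follow-up. Per-cycle PD cost = best-supportive care +
follow-up + the same monitoring schedule; drug acquisition stops at
progression. One-off entry costs: a docetaxel course (75 mg/m² × BSA,
rounded up to whole 20 mg vials, 6 × 3-weekly administrations) for the
docetaxel fraction of the cohort, applied identically in both arms;
plus expected grade 3–4 adverse-event management cost (Σ incidence ×
unit cost over febrile neutropenia, hypertension, decreased neutrophil
count, fatigue — cumulative incidences, hence one-off, not per-cycle).
A resource without a country price (nilutamide and histrelin are not
marketed in China) raises a missing-price error rather than costing 0.

Defaults a practitioner may want to change, all in `ModelConfig` and
echoed in every run's audit log:

| parameter | default | rationale |
|---|---|---|
| `weibull_shape` | 1.0 | least-assumption shape under one-landmark calibration |
| `pfs_endpoint` | clinical_PFS | clinical progression is the conventional transition trigger |
| `antiandrogen` | bicalutamide | most widely used first-generation agent |
| `lhrh_mix` | 100 % goserelin | single monthly depot; fully configurable mix incl. orchiectomy |
| `docetaxel_fraction` | 0.45 | trial stratified by planned early docetaxel; applied symmetrically |
| monitoring schedule | labs/PSA/visit monthly, CT + bone scan every 3 cycles | typical mHSPC surveillance; unpublished in the source costing |
| `days_per_cycle` | 30.4375 | 365.25/12, exact average month |
| `half_cycle_correction` | off | state-membership accounting, documented |

The unpublished monitoring frequencies and the docetaxel fraction are
the main reason the original publication's absolute cost totals cannot
be reproduced exactly; the package's contract is therefore the
cost-effectiveness *verdicts* plus full auditability, not the totals.

## Sensitivity analyses

**One-way (tornado).** Each parameter is set to its low and high bound
with everything else at base, the whole pipeline re-run, and entries
sorted by ICER swing. Bounds: the published ±20 % ranges for unit
costs; ±20 % for utilities, capped at 1; ±20 % for the discount rate;
±20 % on the logit scale for the standard-care survival landmarks
(keeps them probabilities). Hazard ratios are not in the default
tornado set (they are the enzalutamide-arm efficacy input varied in the
PSA); with the default set, the PFS utility and the enzalutamide price
produce the two largest swings in both perspectives.

**Probabilistic.** 1,000 Monte Carlo iterations; each draws all
uncertain parameters jointly — gamma for costs, beta for utilities and
landmark fractions, log-normal for hazard ratios — with spreads
moment-matched to a uniform over the respective range
(sd = range/√12), so the conventional and the strictly range-faithful
`uniform` family (selectable) have equal first two moments. The
discount rate is structural and held fixed. Joint draws that make the
PFS curve cross above the OS curve (≈ 1 % of draws, from independent
landmark/HR sampling) are rejected and redrawn deterministically under
the seed; the count is reported. The CEAC reports, per WTP value, the
fraction of iterations with strictly positive incremental net monetary
benefit (an exact tie counts as not cost-effective).

## Synthetic digitized curves

The generator emulates manual digitization of published Kaplan–Meier
figures: evenly spaced time points (default 10 over 6–60 months,
matching ~3-year trial follow-up plus short extrapolation), true
Weibull survival plus additive Gaussian noise on the survival fraction
(default sd 0.01, the order of pixel-reading error), clamped to (0, 1]
and monotonized by cumulative minimum. It does **not** emulate
at-risk-table-informed reconstruction, censoring structure, or
correlated digitization errors along a curve — so parameter-recovery
results here show the fitting machinery works, not that any real
figure was digitized accurately. Ground truth is kept alongside the
series (sidecar JSON), enabling closed-loop recovery tests (noiseless:
exact to 1e−6; sd 0.01: median parameter error < 10 % across seeds).

## Numerical choices

* Transition probabilities and trace occupancy are computed through
  cumulative hazards, so survival ratios stay accurate when S is tiny.
* Conservation (pfs + pd + dead = 1), monotonicity of death/PFS
  occupancy and entry conditions are asserted at 1e−10 inside the
  trace container itself.
* ICER sign cases are mapped to flags (`dominant`, `dominated`,
  `undefined` at ΔE = 0) rather than raising or returning ±inf; for
  tornado ordering, dominance maps to signed infinity.
* Calibration rejects landmarks of exactly 0 or 1 (no finite Weibull
  passes through them at positive time).

## Limitations

* With the default exponential shape, 23 % of the enzalutamide cohort
  is still alive at the 20-year horizon (11 % standard care), so the
  horizon truncates some tail; the original fitted shapes are
  unpublished. The audit log reports `dead_at_horizon` per arm.
* No treatment switching or subsequent-line therapy on progression, no
  tunnel states, no age-dependent background mortality, no grade 1–2 or
  rare (< 5 %) adverse events, and payer-perspective costs only —
  matching the scope of the source analysis.
* Only Weibull curves are supported (no splines or piecewise hazards),
  and digitized fitting uses point series, not individual-patient-data
  reconstruction.
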