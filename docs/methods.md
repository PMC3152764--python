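# Methods

This note documents the model implemented by `adscreensim`: its assumptions,
parameters, numerical choices, the synthetic inputs it ships, and what the
test suite does and does not establish.

## Model structure

The simulation is a continuous-time, individual-level time-to-event model,
not a cycle-based Markov model. Each patient carries three latent times
drawn once and shared by both arms (common random numbers):

1. **sex** — Bernoulli, 46% male;
2. **scheduled AD onset age** — first event of a non-homogeneous Poisson
   process built from age/sex annual onset probabilities;
3. **all-cause death age** — inverse-transform sample from an age/sex life
   table, treated as independent of the AD clock given age and sex (the
   incidence source is already adjusted for competing mortality, and the
   model resolves the competition by whichever event comes first).

The no-screening arm realizes the scheduled onset if it precedes both death
and age 100. The screening arm runs the screening policy and, on a positive,
starts therapy; treatment delays the onset (below), and an onset pushed past
death or the cap becomes an avoided case. Ties are broken against the AD
case: onset exactly at death or exactly at age 100 is not a case.

### Incidence → event times

Annual probabilities are stratum-constant inputs (5-year age bands, zero
below 65, constant from 85 to the age-100 cap). Each probability becomes a
hazard rate `λ = −ln(1 − p)`, which preserves the per-year event probability
exactly. Two readings of the cumulative curve are available:

* `piecewise_exponential` (default method): the survival function is
  `exp(−H(t))` with `H` piecewise linear — exact for piecewise-constant
  hazards, and it captures the jump in incidence between adjacent strata;
* `piecewise_linear`: the cumulative *probability* is interpolated linearly
  between knots. Both agree exactly at every stratum boundary; they differ
  only inside strata, and negligibly where the hazard is low.

**Anchored smoothing (default on).** Each stratum is labelled with an anchor
age ("value at age 77 in distribution"). In the default mode the hazard rate
is interpolated linearly between anchor ages (evaluated per 1-year
sub-interval at its midpoint), with the terminal constant stratum anchored
at its start (85) and the curve flat beyond it. This is the "smoother
approximation between adjacent strata" described with the published model.
It matters: the smooth ramp from the 80–84 band (0.0074/y for women) up to
the 85+ level (0.03/y) moves onset mass into the early-to-mid 80s, where
survival is still substantial. With stratum-constant rates instead
(`anchored_incidence=False`), the no-screening case count falls by roughly
12% and no realistic mortality table reproduces the published base-case
results; with anchoring and a realistic mortality slope, essentially every
published outcome lands within ~2% (see *Calibration*). We therefore treat
the anchored reading as the base case and keep the stratum-constant reading
available as an option.

Sampling is a pure function of the curve and one uniform draw per event
schedule: `t` solves `S(t) = u`. Draws with total event probability below
`1 − u` return "never" — patients scheduled past the cap do not get AD.

### Mortality and the bundled fixture

The original analysis used census mortality whose numbers were never
printed. The package therefore ships a **synthetic** stand-in
(`DEFAULT_FIXTURE_SPEC`), generated — not tabulated — from a Gompertz–
Makeham law `μ(x) = c + b·e^{g(x−50)}` per sex, discretized to annual `q`,
ages 50–99, with an open age of 100 (`q = 1`; everyone alive there is
censored, matching the model cap).

**Calibration.** Two facts about the published no-screening arm are
reproducible targets: ~13.68 AD-free years per person from age 70, and
~113 AD cases per 1000. The fixture fixes the slope at `g = 0.092/y` (a
mortality doubling time of ~7.5 years, typical of adult period tables), the
Makeham constant at 0.0005/y, and a female–male life-expectancy gap at 70 of
2.5 years; the per-sex baseline is then the one free lever, solved by
root-finding so that remaining life expectancy at 70 hits the calibration
targets (male 13.05 y, female 15.55 y). Those targets were themselves chosen
analytically — no simulation in the loop — so the closed-form mixed-cohort
AD-free expectancy `E[min(T_AD, T_death, 100) − 70]` equals 13.68 y. The
generator verifies the achieved expectancy to ±0.05 y and fails loudly
otherwise. Users with a real census table can substitute it via
`MortalityFixtureSpec(model="tabular", ...)` or a CSV.

### Screening

A screen at age `a` sees a patient whose scheduled onset is within
`duration_of_sensitivity` years (boundary inclusive) as a true prospective
case and fires with probability equal to the sensitivity; everyone else —
onset further out or never — screens positive at `1 − specificity`. This is
the hard-window idealization of a biomarker whose detectability depends on
time-to-onset; the window boundary convention (closed) is ours, as the
sources leave it open.

The policy screens at the first-screen age and then every
`rescreen_interval` years, stopping at the first positive (treatment starts;
the treated are never rescreened), at clinical onset, at death, or at the
stop age (default: cap minus one interval). Each screen performed consumes
exactly one uniform from a dedicated per-patient, per-screen-index
substream, so changing test parameters cannot reshuffle unrelated draws.

### Treatment

Therapy with effectiveness `e ∈ [0, 1)` runs the disease clock at `1 − e`
while on treatment. With residual `r = onset − start` and on-therapy
duration `d`:

* onset on therapy (`d(1−e) ≥ r`): delayed onset = `start + r/(1−e)`;
* otherwise: delayed onset = `start + d + (r − d(1−e))`.

The total delay is `e/(1−e)` × disease time consumed on therapy, which for
`e = ½` yields the t/2 + t/4 + … → t limit. Effectiveness is deliberately
independent of how far before onset therapy begins, and therapy delays —
never directly prevents — onset: prevention is emergent when the delay
crosses death or the cap.

**Persistence.** Discontinuation uses two first-year blocks (probabilities
of stopping in the first and second six months) and a long-term rule. Within
a block the stop time is uniform — the sources pin only block totals, and
the uniform is the maximum-entropy completion. The base pattern (17%, then
5.1%) gives the quoted ~22% first-year discontinuation
(1 − 0.83·0.949 = 0.2123); survivors of year 1 persist until onset. Presets
cover the two cholinesterase-inhibitor patterns (0%/68%, 0%/47%), the ACE
inhibitor pattern (25%/4%), and unending persistence; after-year-one annual
discontinuation is available but defaults to persist-until-onset, since the
published patterns specify only the first year. Treatment-years accrue until
discontinuation, (delayed) onset, death, or the cap — for false positives
that means until discontinuation or death, which is what makes the
treatment-year total large relative to the treated-case count.

**Adverse events** arrive from a piecewise-constant annual-rate schedule
(10% in year 1, 2%/y thereafter to year 20) via sequential cumulative-hazard
inversion. In the base case they are counted only; the
`discontinue_on_ae` flag truncates therapy at the first monitoring visit
(every 0.5 y in year 1, annually after) at or after the first event. When
that flag is on, events are sampled over the pre-truncation horizon and the
stop applied once — an approximation that can only shorten therapy,
exact for the first event, which is the only one that matters to the rule.

### Random-number architecture

All draws come from per-purpose substreams spawned from the master seed
(`SeedSequence(seed, spawn_key=(purpose[, index]))`): sex, onset, death, one
stream per screen index, three persistence draws, and a per-patient adverse-
event stream. Patient `i`'s draws are identical whatever the cohort size and
whatever *other* parameters change, which is what makes paired arms, tornado
bars and two-way cells quiet at desk-scale cohort sizes. Results are
bit-reproducible given (config, seed).

## Outcomes and sensitivity analyses

Eight outcomes are reported per 1000 screened: AD-free years (both arms and
incremental), AD cases (both arms and avoided), treatment person-years,
number recommended for treatment, NNS, NNT, AD-FY gain per treatment-year,
and cases avoided per treatment-year. NNS/NNT divide raw counts before any
rounding; with zero cases avoided they are reported as an explicit undefined
sentinel. The share of the incremental AD-free years accruing to complete
avoiders (~61% in the base case) is tracked patient-by-patient.

A 3%/year continuous-time discount is implemented but **off by default**:
the published per-person scale (~13.7 undiscounted years from age 70) is
inconsistent with discounted accrual, so the rate is exposed but not applied
to the reproduction targets.

One-way analysis varies each of five inputs alone — effectiveness,
first-screen age, rescreen interval, duration of sensitivity, persistence —
under a common master seed and reports the per-outcome range (tornado
ordering). The shipped extremes use values stated with the base analysis
where they exist (screen age 50–80, window up to 25 y); the rest are package
defaults, flagged as such.

The two-way analysis sweeps test sensitivity × specificity for a 15-year
window and reports cases avoided per 100,000 screened. The published surface
screens repeatedly from age 70, but the rescreen interval behind it is not
printed; a single screen cannot reach onsets more than one window beyond the
screen age and caps the surface an order of magnitude too low. The reference
configuration therefore uses **5-yearly rescreening**, a reconstruction
under which the surface reproduces the published bands — (0.90, 0.90) ≈
6,500–7,500 per 100,000, a perfect test with unending persistence ≈ 9,000
against a published 7,000–8,000 — and is labelled as a package choice.

## Problem sizes and tolerances

The reproduction runs use 100,000 paired patients (a few seconds each); unit
and property tests use 500–30,000 patients with 4-standard-error Monte Carlo
bands; inverse-sampling correctness is checked against a brute-force
0.01-year grid inversion with a Kolmogorov–Smirnov bound at n = 10⁵. The
fixture calibration identity and the analytic AD-free/case-probability
oracles are closed-form sums over merged piecewise-constant-hazard grids,
independent of the sampling path they check.

## What the synthetic inputs do and do not show

The incidence table, test characteristics, persistence blocks and AE
schedule are published inputs; the mortality fixture is not, and absolute
totals inherit its shape. Calibrating its level to the AD-free-years scale
pins the first moment, and with anchored incidence the case count follows,
but higher moments (post-onset survival tails, very-old-age hazards) remain
stand-in choices: outcomes that weight them — the avoider share, gains from
very long detection windows — carry a few extra percent of fixture
uncertainty. Passing tests show the *mechanism* (sampling, windowed
screening, clock slowdown, accrual rules) is right and that the published
figures are recovered under a defensible mortality stand-in, not that the
original census table has been recovered.

Known limitations, by design: no post-onset disease staging or
AD-attributable excess mortality; no covariates beyond age/sex and no
high-risk subpopulations; no dose-level adherence below the persistence
patterns; no costs, anxiety or quality-of-life adjustments; the detection
window is a hard boundary rather than a smooth function of time-to-onset.
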