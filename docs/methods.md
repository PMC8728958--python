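# Methods

## Study design being modelled

The pipeline estimates *period life expectancy at age 65* by medication
exposure in an elderly chronic-disease cohort observed through claims data.
Exposure is time-varying: a person contributes person-time to a medication
group exactly while covered by that group, may contribute to several groups
at once (mesalamine and steroids are not exclusive of anything; combination
therapy is exclusive of the two monotherapies it is built from), and
contributes to "no therapy" whenever no studied class is active. Deaths are
attributed to every group active on the death date. Age- and sex-specific
mortality rates per group are then converted into an abridged period life
table, under the usual period assumption that current rates stay constant
over a hypothetical cohort's remaining life. The hypothetical cohort has no
other characteristics; life expectancy here is a transformation of observed
rates into years, not a causal forecast for any individual.

## Conventions

* All intervals are half-open `[start, end)` at day resolution.
* Person-years = days / 365.25, the single conversion constant used
  everywhere (including the generator's age-to-date arithmetic).
* Age bands: 65–69, 70–74, 75–79, 80–84, 85–89, 90+ (open), cut at
  calendar birthdays (Feb 29 anniversaries fall back to Feb 28).
* Follow-up: entry = max(65th birthday, diagnosis date, study start);
  exit = min(death, emigration, study end), with ties resolved
  death > emigration > administrative end. The default study window is
  1997-07-01 .. 2017-06-30, pooled (no calendar-period stratification).

## Exposure-episode construction

Each dispensing covers `[dispense_date, dispense_date + days_supplied)`.
Within one drug code, a successor dispensing starting no more than the
class's grace window after the running coverage end is bridged into the
same episode and the bridged gap counts as exposed; the episode ends at the
last coverage end (no grace tail). Grace windows: 30 days for
non-biologics, 84 days (12 weeks) for biologics on a typical 8-week
schedule, 42 days (6 weeks) for other biologics. Per-class coverage is the
plain union of that class's per-code episodes — the grace logic is
agent-specific, the union is not.

"Combination therapy" is operationalised as the day-level intersection of
the grace-bridged immunomodulator and biologic coverages. This is the
unambiguous, conservative reading of "prescriptions of both classes within
three months of each other": with typical days-supplied, any such pair
produces overlap after bridging. A looser reading (combination status for
adjacent but non-overlapping use) would need an explicit adjacency
threshold; where such a threshold is exposed in configuration it defaults
to 90 days, but the default analysis never uses it. Monotherapy intervals
are the class coverage minus the intersection, so no calendar day is both
combination and a monotherapy.

"No therapy" means no active coverage from any of the five studied classes;
medications outside the study set are ignored. A death falling on the last
covered day of an episode (interval end = death date) is attributed to that
episode's group — a death on the last supplied day belongs to the therapy.
A death inside a bridged gap likewise belongs to the bridged therapy, since
bridged gaps are defined as exposed.

Subtype classification uses the last nine outpatient-visit diagnosis
labels: CD (or UC) when at least five of nine agree. With fewer than nine
visits the rule is undefined; a simple majority of the available visits is
used and ties (including no visits) are left unclassified.

## Life table

For closed 5-year bands with rate `m`, width `n = 5` and fraction-of-band
lived by decedents `a`:

* `q = n·m / (1 + n(1−a)·m)` (Chiang hyperbolic, default) or
  `q = 1 − exp(−n·m)` (exponential option),
* `l_{x+n} = l_x (1 − q)`, radix `l_65 = 1`,
* `L = n·l_{x+n} + a·n·(l_x − l_{x+n})`,
* open interval: `q = 1`, `L_ω = l_ω / m_ω` (exponential closure — the only
  closure consistent with a constant hazard beyond the last cut point).
  The closure is a registered, named option (`OPEN_CLOSURES`) so an
  alternative treatment of the last age group can be dropped in without
  touching the table builder.
* `T` by back-summation, `e_x = T_x / l_x`.

`a` defaults to 1/2 (the standard abridged-table midpoint). The
`constant_hazard` option instead solves `a = 1/(n·m) − 1/expm1(n·m)` from
the band rate, which makes the table *exact* when the true hazard is
piecewise constant: with exponential `q` and this `a`, every band term
equals the closed-form integral, so the life table reproduces the
analytical life expectancy to machine precision on exact rates. The
midpoint default overstates `L` (and hence `e_65`) when band hazards are
large — at `m = 0.2–0.3/y` the bias reaches several percent — which is an
inherent property of the conventional abridged construction, kept as the
default because it is what the applied literature computes. All oracle and
calibration experiments therefore use the exponential/constant-hazard
estimator, which is unbiased for the generator's piecewise-exponential
truth.

### Variance and intervals

`Var(q) = q²(1−q)/D` per closed band (`0` when `D = 0`, an acknowledged
underestimate surfaced as a run warning), and

```
Var(e_65) = [ Σ_closed l_x² ((1−a)n + e_{x+n})² Var(q_x)  +  l_ω²/(m_ω² D_ω) ] / l_65²
```

— Chiang's decomposition plus a Silcocks-type term for the open interval.
The 95% CI is `e_65 ± 1.96·SE`. Because the CI construction used by
applied studies is rarely stated, a parametric bootstrap
(`D* ~ Poisson(D)` per band, person-years fixed, percentile 2.5/97.5) is
provided as an independent cross-check; replicates whose open band draws
zero deaths cannot close and are redrawn, with the count reported.
Differences between groups use `SE = sqrt(Var_a + Var_b)` (independent
strata) and are flagged significant when the CI excludes 0. The empirical
coverage of the analytic CI, measured over replicate simulated cohorts in
the acceptance suite, is consistent with the nominal 95%.

## Direct standardization

Reference weights are the per-sex age-band distribution of persons under
follow-up on a reference date (default 2016-07-01). Each sex is
standardized to its own prevalent distribution, matching the sex-specific
reporting of the rates. `ASR = 1000·Σ w·m` with
`Var = 1000²·Σ w² D/PY²`; the default interval is the Fay–Feuer gamma
method (valid at the low death counts of small medication groups,
non-negative lower bound), with a Wald interval as an option.

## Synthetic cohort generator

The generator emulates the structure of a provincial seniors' drug-benefit
claims system: complete outpatient dispensing records (with days supplied)
for everyone 65+, linked to demographics, death and emigration dates,
surgeries, and outpatient visits with CD/UC diagnosis labels.

* **Mortality truth.** Death is driven by piecewise-constant hazards per
  (sex, treatment state, 5-year age band). Remaining life expectancy under
  any schedule has the closed form
  `e(x) = Σ S_i (1 − e^{−μ_i n_i})/μ_i + S_ω/μ_ω`, used as the oracle for
  all recovery experiments. Sampling uses piecewise-exponential inversion;
  a zero cumulative-hazard draw is resampled so death is strictly after
  entry without biasing continuous draws.
* **Default schedules** are Gompertz-like ladders (hazard ×1.5 per band,
  roughly a doubling per decade) whose 65–69 levels were solved once
  against the closed form so the per-state true life expectancies at 65
  match values typical of elderly IBD cohorts — females: mesalamine 22.1 y,
  combination 20.5, no therapy 18.7, biologic monotherapy 16.4,
  immunomodulator monotherapy 15.4, systemic steroids 11.7; males: 19.6,
  16.6, 17.1, 14.6, 13.8, 10.3. The ordering (mesalamine longest —
  a marker of mild disease; steroids shortest — refractory disease,
  steroid risks, end-of-life use; immunomodulator ≈ biologic) mirrors what
  is observed in practice, and confounding by indication is deliberately
  baked into the truth rather than modelled.
* **Treatment dynamics.** A semi-Markov process over the six groups:
  initial-state probabilities (defaults approximate observed person-time
  shares: mesalamine 0.42, no therapy 0.40, immunomodulator 0.08,
  steroid 0.06, biologic 0.03, combination 0.01), exponential sojourns
  with per-state mean dwell times (0.4 y for steroid bursts, 1.5–3 y
  otherwise), and a uniform transition kernel over the other five states —
  the simplest kernel consistent with configuring only dwell means.
  Frozen-state configurations (`frozen_state_config`) pin every person to
  one state for oracle tests.
* **Dispensings.** While a drug state is active, the person receives
  dispensings of that state's class(es) with configurable days-supplied
  distributions and exponential refill gaps. Default gap means (10–30 d)
  put a tail of gaps beyond each grace window (about 5–13% of gaps),
  so episode merging and no-therapy slivers are genuinely exercised.
  Biologic users draw one agent class per person (8-weekly with
  probability 0.7).
* **Demographics.** Birth years uniform on 1915–1950 (so entry ages at the
  1997 study start span 65–82 and the oldest bands accrue person-time);
  62.5% diagnosed before 65 (uniform age 20–64), the rest at 65 plus an
  exponential excess (mean 5 y). Everyone in the table is an ascertained
  patient; mortality before 65 is not modelled, matching the entry
  condition. Emigration (default 0.005/PY) and surgery (default 0.01/PY)
  are constant competing hazards.
* **Post-surgery mortality.** `post_surgery_hazard_ratio` multiplies the
  death hazard from the first surgery onward; the default 1.0 means
  surgery is a pure marker. The surgery-censoring experiment sets it below
  1 (surgery resolving refractory disease), in which case censoring at
  surgery removes lower-than-average-mortality person-time and the
  life-expectancy estimate drops — the qualitative behaviour reported for
  this sensitivity analysis in practice.
* **Visits.** Poisson visit counts (1.5/PY) with the true subtype label
  flipped with probability 0.07; persons designated unclassified emit a
  short, exactly balanced CD/UC history.

What the generator does **not** emulate: disease-activity dynamics,
comorbidity, dose, adherence beyond the grace windows, correlated
prescribing across classes, seasonal or calendar trends, and
misclassification of the cohort definition itself. Passing tests therefore
demonstrate that the *estimation machinery* is correct under a known
exposure-dependent mortality process — not that any real-data estimate is
free of confounding by indication, which this design cannot address.

## Numerical and edge-case choices

* `a` from the constant-hazard formula switches to its series
  `1/2 − n·m/12` below `n·m = 1e-4` to avoid cancellation.
* A life table whose open-band rate is zero raises ("does not close")
  rather than returning an infinite expectancy; the closed-form oracle
  raises the analogous "infinite life expectancy" error.
* Zero-length follow-up (entry ≥ exit) excludes the person; zero-length
  intervals vanish in all interval algebra.
* Persons whose first surgery predates entry contribute nothing under
  censoring.
* Exposure intervals are validated to lie inside follow-up at tabulation
  time; a violation is a contract error, not silently clipped.
* 1.96 is used for the 95% normal quantile throughout.

## Experiment sizes

The acceptance suite runs the oracle-equivalence check on 25 random
schedules (hazards ≤ 0.3/y), parameter recovery and the designed 5-year
difference at n = 20,000 persons per cohort/arm, CI calibration over 400
replicate cohorts of n = 1,200, and the censoring experiment at
n = 15,000 — sizes chosen so each check has ample power while the whole
suite and the acceptance script each complete in a couple of minutes on a
single CPU.

## Known limitations

* The open-interval closure is a constant-hazard approximation; refined
  treatments of the last age group can be registered but are not built in.
* `Var(q) = 0` in zero-death bands slightly narrows CIs for sparse strata.
* The paper-style default (Chiang q, midpoint a) carries the conventional
  abridged-table discretization bias at high band hazards; the
  exponential/constant-hazard estimator is the internally consistent
  choice when the truth is piecewise-exponential.
* Strata with zero person-years in any band are skipped (with a manifest
  warning) rather than estimated with merged bands.
* The difference CI treats strata as independent; in reality a person can
  contribute person-time to both groups being compared, so overlapping
  groups share sampling noise the CI ignores.
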