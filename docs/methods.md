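# Methods

This note records the model's structure, the conventions chosen where the
source material left the wiring open, the synthetic-data design, and the
numerical details a maintainer needs. The package's own test suite and
`scripts/acceptance.py` compute every number referred to here.

## Cohorts and decision tree

Two strategies are compared on the same population: **current care** (GP
detects, assesses — 95% GP / 5% pelvic physiotherapist (PPT) — and treats
first line) and **new care** (a continence nurse specialist (NS) in the GP
practice detects, assesses and treats first line). Two cohorts run through
each arm and are mixed by national headcounts (incident 25,872/yr,
prevalent 58,306, i.e. weights 0.307/0.693):

* **Incident** patients enter the tree at detection: 50.4% (current) or
  64% (new) are detected; detected patients split over *treatment for
  cure* (37% / 39%), *containment only* (61%) and *self-management*
  (2% / 0%). The new-care detection rate is represented internally as the
  current rate plus an NS-attributable gain of 13.6 percentage points, so
  sensitivity analyses vary the gain rather than two correlated absolute
  rates; the base-case value is identical (0.640).
* **Prevalent** patients are distributed over the pathway by a warm-up:
  the current-care incident model runs for 4 cycles, the cumulative
  success mass leaves the pool, and the rest is renormalised. Improved
  patients whose treatment has ended rejoin the never-in-care incontinent
  pool (the prevalent cohort starts with no retained improvement, which is
  what the published outcome table shows for current care), non-referred
  failures keep insured containment, and the still-active cure mass is
  spread equally over the GP/PPT/specialist lanes (exact thirds,
  renormalised). Under new care, 14 percentage points of the never-detected
  pool are detected at model start and split 39/61 over cure/containment,
  and self-managers are re-engaged into treatment for cure; this
  reconstructs the published derived pool distribution to four decimals.
  The newly detected prevalent cure mass enters through the NS lane — they
  are the NS's own case findings — rather than the residual three-way
  provider split, which applies only to the current-care residue.

The warm-up removes about 8% of the cohort as successes after one year.
The alternative categorisations (improved patients counted as containment,
or removed together with successes) each miss the published pool shares by
several percentage points; the convention above is the only one that lands
within one percentage point, and it was fixed on that basis.

## Cure pathway

Patients treated for cure are propagated as mass fractions over compound
states (provider lane × treatment phase × health state) with three health
states: incontinent, improvement (≥50% fewer episodes) and success
(continent, absorbing). Conventions:

* **One attempt per cycle.** A treatment attempt occupies exactly one
  3-month cycle. An *immediate* referral (the GP's triage decision, 51%,
  split 57/43 PPT/specialist; the specialist's 40% pass-through to PPT) is
  resolved in the same cycle at the receiving provider, whose consultation
  is booked there. Referral *after a failed attempt* takes effect the next
  cycle.
* **Failure handling.** GP failures are referred onward with the same 51%
  probability as the triage split; PPT failures are all referred (33% GP,
  67% specialist); specialist failures all return to the GP; NS cycle-1
  failures continue with NS medication (40%) or are referred (60%, split
  33/67). Failures who are not referred stop active treatment and keep
  insured containment. This stopping rule is what drives the prevalent
  pool's near-empty cure residue after one year.
* **Medication persistence.** Improved medication users continue with
  probability 0.76 *per cycle* (the persistence estimate stems from
  9–12-month discontinuation data); of the continuing users 20% become
  continent and 80% remain improved and may continue again; discontinuers
  keep their improvement. Treating the 76% as a single second cycle
  instead underpredicts the published 3-year success shares by ~1.6
  percentage points in both arms while overpredicting improvement by the
  same amount, so the per-cycle reading was adopted.
* **Training continuation.** Improved PFMT/biofeedback patients all take a
  second training cycle (improvement 44%/success 56% under current care,
  46/54 under new care); afterwards improvement is retained without
  further treatment. Improvement converts to success only through these
  explicit continuation rules; there is no relapse from improvement or
  success.
* **Zero-mass branches** (GP-delivered training, specialist referral back
  to PPT) are wired but receive no mass in the base case.

A patient-level microsimulation (`synthetic.microsim_oracle`) re-implements
the same tree with per-patient random draws in a fixed node order, sharing
only the parameter values. Cohort occupancies match it within three
Monte-Carlo standard errors on the base case (n = 200,000) and on twenty
randomised valid parameter sets (n = 50,000 each); this validates the
cohort algebra (mass bookkeeping, continuation and referral wiring), not
the parameter readings themselves, which are anchored to the published
tables instead.

## Costing and QALYs

All costs are 2013 euros per patient. Event costs (consultations,
dispensings, procedures, travel per consultation) are booked in the cycle
they occur; state-dependent costs (pads; formal home care 47% of users;
informal care 43%; adverse events on the non-success mass: urinary tract
infection 7.575%/cycle unrounded — a display value of 8% can be forced via
`use_rounded_uti` — fracture 0.023%/cycle, skin damage 8%/cycle) are booked
on the end-of-cycle distribution. QALYs accrue 0.25 years at the state
utility per end-of-cycle occupancy; successes keep accruing the success
utility after leaving active care. No half-cycle correction and no
discounting (3-year horizon). The formal/informal care costs for improved
and success states are derived from the failure-state costs with the 10%
and 25% use reductions, so those assumptions stay live for sensitivity
analysis; the derived values reproduce the published state costs to the
cent.

Assessment consultations are booked for all newly detected patients
(GP/PPT split under current care, NS under new care; under new care the
initial treatment package adds three NS consultations). Detected
containment and cure patients have insured pads; never-detected and
self-managing patients pay out of pocket (the published out-of-pocket row
merges travel into it, and the results table mirrors that layout).

The one-off implementation cost per patient is the annual NS
training/education cost carried by this population divided by the modelled
pool (426,496 / 84,178 ≈ €5.07), booked once per patient in the new arm.
An accrual per patient-year would triple it and is incompatible with both
the published per-patient table and the full-implementation scenario
shift.

### Known residual

With these conventions the model reproduces, within the stated tolerances,
the published outcome shares, the occupancy-driven cost rows (home care,
informal care, containment, out-of-pocket), the QALY totals and all
incrementals. The *absolute* GP and specialist consultation rows land
lower than published (≈13 vs 20 and ≈11 vs 25 euros per patient) — the
consult-frequency conventions behind those rows are not printed — and the
gap largely cancels between arms. The same gap is the likely reason the
detection-only scenario's payer-cost increase comes out smaller than
published (≈ +12 vs +58 euros; the QALY gain, 0.004, matches exactly):
reproducing +58 would require a first-line pathway cost intensity that
contradicts the published per-patient consult rows themselves, so the
smaller value is reported rather than re-tuned.

## Scenarios

Scenarios are pure parameter transforms re-run through the same pipeline:
`full_implementation` sets the implementation share to 100%;
`detection_only` keeps the NS's consultations, allocation and costs but
replaces every treatment outcome probability with its GP-pathway
counterpart (NS package → GP lifestyle advice; UTI and medication branches
→ the GP's; PPT parameters revert to current care); `effectiveness_only`
zeroes the detection gain and the extra prevalent detection (and with it
the self-manager re-engagement) while keeping NS treatment. ICERs are
classified as dominant/dominated/equivalent before a ratio is reported.

## Sensitivity analysis

**One-way:** every non-structural parameter (the pathway probabilities of
both arms, adverse-event and care-use rates, unit costs, the incontinent
utility) is set to mean ± 40%; probabilities are capped at 1 and branch
groups renormalised; the tornado reports societal and payer cost and QALY
increments at both ends.

**Probabilistic:** parameters bounded in [0, 1] draw from beta
distributions with method-of-moments shapes at SD = 20% (or 40%) of the
mean; infeasible variances (SD² ≥ m(1−m)) are clamped to 95% of the
feasible maximum; degenerate means (0 or 1) stay fixed. Costs draw uniform
on mean ± the same fraction. Branch groups are closed the way a
spreadsheet tree closes them: the branch the input tables mark as the
difference/complement is computed as 1 − sum of its sampled siblings
(scaled down if the siblings exceed 1), which preserves the sampled
branches' full variance; the GP treatment mix, a full expert enumeration
whose nominal residual is a zero branch, is instead rescaled by its sum.
Two correlated rules replace independent draws: the new-care detection
rate is current detection plus the sampled gain, and the success utility
is the sampled incontinent utility plus the fixed base-case decrement
(0.0349). Sampling the absolute pairs independently makes new care detect
fewer patients than current care, or inverts the utility ordering, in a
large fraction of draws — structural sign flips that the published
uncertainty results exclude; the QALY difference depends on the decrement,
not the utility levels. Structural settings (horizon, cycle length,
population counts, implementation share) are never sampled. Draws are
reproducible from a single integer seed (`numpy.random.default_rng`).

## Budget impact

Year 1 contains the prevalent and incident cohorts at national headcount;
years 2 and 3 each add a fresh incident cohort whose cycles are truncated
at the 3-year window. At each completed cohort-year boundary the remaining
mass is attenuated by stratum-weighted survival from a demography table
and by the 4%/year nursing-home exit, uniformly across states; exited
patients accrue nothing further. With attrition set to zero the national
totals equal the population-scaled per-patient totals exactly (a test
enforces this identity).

The default demography is **synthetic**: Gompertz-shaped yearly death
probabilities `q(age) = q65 · exp(0.095 · (age − 65))` with q65 = 1.2%, a
female advantage (×0.8 vs ×1.15), small seeded jitter, and an age–sex
weight distribution skewed old and female. It is deliberately in the
plausible range for a multimorbid 65+ population but is not observed
life-table data; national totals computed with it are indicative (sign and
scale), and real tables can be supplied as CSV
(`age_band, sex, weight, q1, q2, q3` with cumulative death probabilities).

## Numerical conventions and degenerate inputs

* Mass conservation is enforced at 1e-9 per cycle; branch-group closure is
  validated at ±0.01; probabilities/utilities/fractions must lie in [0, 1]
  and costs be non-negative; a missing engine-required name is reported as
  an incomplete set.
* Decimal commas in source tables are normalised to points at load; config
  round-trips are bit-exact because only raw inputs are serialised and all
  derived quantities are recomputed on load.
* Ties and residues: the prevalent three-way provider split uses exact
  thirds renormalised; sampled branch groups that overshoot 1 are scaled
  down with the residual set to 0; a yearly adverse-event excess that
  samples negative is clamped to 0; horizon 0 returns the entry
  allocation unchanged.
* The synthetic-data generator's defaults are the study conditions; tests
  never adjust them. What passing tests show: the engine's bookkeeping and
  the published-anchor agreement under these inputs. What they do not
  show: transferability to real populations (no severity/aetiology
  heterogeneity, no relapse from success or improvement, no state-specific
  mortality, utilities from a general female population, effectiveness of
  nurse-led care taken from a single trial).

## Limitations

Beyond the residuals above: the model has no per-patient heterogeneity
inside the cohort engine; faecal incontinence, tailored containment
prescription and case-coordination effects are out of scope; mortality in
the budget impact is population-level and thus likely an underestimate for
a multimorbid group (documented, not modelled); and the 3-year horizon
truncates both late relapses and late gains.
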