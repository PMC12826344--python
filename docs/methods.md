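# Methods

`dmpacost` models the 12-month service cost of the three ways depot
medroxyprogesterone acetate (DMPA) is delivered in a public-sector
family-planning programme: provider-administered intramuscular injection
(DMPA-IM), provider-administered subcutaneous injection (PA DMPA-SC),
and client self-injection of DMPA-SC (SI). The analysis has four layers —
a synthetic longitudinal cohort, survival/transition estimation,
ingredient-based visit costing, and a recursive quarterly Markov cost
model with Monte-Carlo input uncertainty — topped by a break-even
analysis of the SI visit share.

## State space and observation scheme

Five method states are tracked: `IM`, `PA_SC`, `SI`, `OTHER_METHOD`
(a non-DMPA contraceptive) and `NONE` (no family-planning use). The
first three accrue DMPA person-years. Participants are observed at
enrolment (wave 0) and four quarterly follow-ups (waves 1–4, one cycle =
91 days); `MISSING` marks loss to follow-up and is an observation label,
never a model state.

## Synthetic cohort generator

The generator (`dmpacost.cohort`) emulates the cohort structure the
downstream estimators assume, so that the whole pipeline is testable
without restricted data. Each participant follows a first-order
per-cycle change process:

* while not self-injecting, she changes method status each cycle with
  her arm's probability `hazard_change` (h);
* a change is a transition to SI with probability `p_transition_si` (q),
  otherwise it is a switch to a non-DMPA method or full discontinuation,
  split 50/50 by default (`change_split_other`);
* transitions into SI from a provider-administered arm are absorbing
  within the window — the study definition of a transition is moving to
  SI *and staying there* — whereas women enrolled on SI discontinue with
  their own arm hazard;
* follow-up waves go missing independently with probability
  `1 − retention_per_wave`, monotonically (study exit).

Because the per-cycle SI entry probability is h·q from every non-SI
state, two closed forms hold exactly: the 12-month method-status-change
probability is `1 − (1−h)⁴` and the 12-month cumulative SI transition is
`1 − (1−h·q)⁴`. The default parameters invert these against the study's
printed 12-month statistics:

| quantity | target | derived default |
|---|---|---|
| cumulative SI transition, PA-SC arm | 47.1% | h·q = 1 − 0.529^0.25 ≈ 0.1472/cycle |
| cumulative SI transition, IM arm | 20.4% | h·q = 1 − 0.796^0.25 ≈ 0.0554/cycle |
| retention through wave 4 | 89% | r = 0.89^0.25 ≈ 0.9713/wave |
| method-change hazard ratio PA-SC:IM | 2.01 | h_PA-SC = 1 − (1−F_IM)^(2.01/4) |
| method-change hazard ratio SI:IM | 0.61 | h_SI = 1 − (1−F_IM)^(0.61/4) |

The IM arm's 12-month method-status-change probability F_IM is not
printed; it is fixed at 0.45, which together with the hazard ratio of
2.01 under a complementary log-log link implies a PA-SC change
probability of 0.699 — reproducing the reported ~25-point continuation
gap between the two provider-administered arms. A large-sample check
(400,000 per arm) confirms the Efron-tie proportional-hazards estimand
on this tied quarterly grid is 2.01 to within Monte-Carlo noise, so no
tie-attenuation correction is applied.

Arm sizes default to the study's 393/299/300; enrolment location is
community with per-arm probabilities (24/393, 8/299, 96/300), the
printed enrolment-location split. SI users receive two DMPA-SC
take-home units per resupply visit, every second cycle.

What the generator does *not* emulate: participant covariates (age,
parity, poverty), switching between the two provider-administered
products, "no longer needs contraception" censoring (rate defaults to
0), within-interval event timing (events sit on cycle boundaries), and
protection carried beyond the 12-month window by advance provision.
Passing tests therefore demonstrate correct estimation and accounting
under the stated stochastic structure, not robustness to real-data
features such as covariate-dependent attrition.

## Survival estimation on the wave grid

All estimators (`dmpacost.estimation`) work on discrete wave times 1–4.
A subject whose follow-up goes missing at wave w was last seen
event-free at wave w−1 and is coded censored at w; censoring is
**exclusive** — a subject censored at time t is not in the risk set for
events at t, because the censoring happened during the interval that
ends at t. (lifelines keeps censored-at-t subjects at risk at t; the
test suite reconciles the two by shifting censored durations by −0.5.)

* **Kaplan–Meier**: product-limit with Greenwood variance; with no
  censoring it reduces exactly to the empirical survival function.
* **Log-rank**: two-group observed-minus-expected with the
  hypergeometric variance, χ² on 1 df.
* **Hazard ratio**: two-group proportional-hazards fit maximising the
  Efron tie-corrected partial likelihood (quarterly data are heavily
  tied, and Efron's correction is the standard choice there) by Newton
  iteration with analytic score and information; Wald 95% CI on the log
  scale. Exact label-swap symmetry of the likelihood gives
  HR(A,B)·HR(B,A) = 1 to solver precision.
* **Cumulative SI incidence**: 1 − S(4) for the transition-to-SI event
  with a Greenwood-based Wald interval. Competing method-status changes
  do not remove subjects from the SI risk set (under the generator's
  change process the SI entry hazard is the same from every non-SI
  state, so the product-limit estimand equals `1 − (1−h·q)⁴`).
* **Days to switch**: interval-midpoint imputation, 91·(w−0.5) days;
  surveys carry no within-interval timing. This compresses mean
  switch-time differences relative to continuously observed data.
* **Transition matrices**: row-normalised counts of observed
  consecutive-wave state pairs, pooled over cycles by default
  (stationary); pairs touching `MISSING` are dropped from numerator and
  denominator; a row with no observations defaults to a self-loop with
  a logged warning. A per-cycle option (`cycle_index`) is provided.

## Visit costing

`dmpacost.costs` prices a service contact from four ingredients:
commodity (DMPA-IM unit price, with DMPA-SC at a fixed premium of
US$0.20 per unit by default), consumable supplies, provider labour
(contact minutes × a per-minute wage by location) and a pre-computed
per-visit infrastructure allocation. Four visit types: IM injection,
PA DMPA-SC injection, supervised first self-injection (the transition
visit), and SI resupply (dispensing `units_per_si_resupply` = 2
take-home units, i.e. six months of coverage per contact). All values
are USD; a documented conversion constant (default 1200 MWK/USD) is
provided for kwacha-denominated inputs.

The per-cycle cost schedule charges provider-administered states one
injection bundle per cycle; the SI state spreads one resupply bundle
over its two covered cycles, plus a one-off supervised-injection bundle
at the cycle of transition into SI. Non-DMPA states carry no DMPA
service cost.

**The shipped default inventory is calibrated, not measured.** The
itemised wage/minute/supply data behind the published per-option costs
are not publicly available, so the defaults are back-solved: with
wages of 0.08 (facility) and 0.07 (community) USD/minute and plausible
supply/infrastructure items, labour minutes are set so the steady-state
cost per person-year of each option equals the published values exactly
($11.56 IM / $13.81 PA DMPA-SC / $10.35 SI at facilities; $11.36 /
$14.05 / $6.30 in the community). This lands the labour share of a
facility PA DMPA-SC visit at 63.5%, matching the reported ~63%. Every
input can be overridden through the YAML inventory schema.

## Markov engine

`dmpacost.markov` advances a closed cohort of n₀ = 100,000 clients
(occupancy starts concentrated in the enrolment state) through 4
quarterly cycles. Accounting is intent-to-treat: switchers of product,
SI adopters, and discontinuers all remain in the model of their starting
cohort with their accumulated costs. Per cycle, in order:

1. person-years += 0.25 × (occupancy of DMPA states), and costs accrue
   on start-of-cycle occupancy — **no half-cycle correction**, since the
   visit that covers a quarter happens at its start;
2. an optional contraceptive-failure exit moves
   `1 − (1 − annual rate)^¼` of each DMPA state to `NONE` (default
   annual rate 0: the reference failure rates are not printed, and the
   unintended-pregnancy consequences are out of scope);
3. the behavioural transition matrix is applied; clients entering SI are
   charged the supervised-injection bundle if their first SI cycle falls
   inside the costed window.

Mass is conserved to 1e−6 per cycle and all metrics are linear in n₀.
In any model with a single costed DMPA state the cost per person-year
equals 4 × the per-cycle cost independently of retention — the
identity used throughout the break-even analysis.

**Input uncertainty**: every behavioural transition probability is
treated as a beta-distributed estimate, Beta(μκ, (1−μ)κ), with
concentration κ = 300 by default (the cohort arm size, i.e. inputs are
uncertain at roughly the precision the cohort provides); costs are held
fixed. Degenerate probabilities (0 or 1) and flagged inputs are not
sampled. Sampled rows are renormalised to sum to one. With 1000
replicate cohorts the replicate mean and the empirical 5th/95th
percentiles are reported; note that a 5th–95th band spans 90%
probability — it is reported under that label, and
`percentiles=(2.5, 97.5)` switches to a conventional equal-tailed 95%
interval.

## Break-even analysis

`dmpacost.breakeven` asks what share s of DMPA-SC visits must be
self-injection for DMPA-SC to cost no more per person-year than DMPA-IM
at the same location. The default **visit-level** blend follows the
definition of the share: with cadence c cycles covered per resupply
visit, mean coverage per visit is 1 − s + s·c cycles, so the blended
per-cycle cost is (s·R + (1−s)·C_PA)/(1 − s + s·c) with R the resupply
bundle and C_PA the injection bundle. A **linear** mode interpolates the
two boundary per-cycle costs directly (equivalent to person-level mixing
of steady-state users), making the cost per person-year exactly linear
in s. The cost per person-year at each share is computed through the
Markov engine with the DMPA retention implied by the supplied transition
matrix; the IM reference uses the same location and retention, isolating
the product effect. The threshold is the smallest grid share (1% grid,
matching the precision thresholds are quoted at) with SC ≤ IM,
cross-validated by bisection on the continuous blend to 1e−6, which must
agree within one grid step.

With the calibrated default inventory the visit-level thresholds are
0.49 (facility, continuous crossing 0.482) and 0.21 (community,
crossing 0.210). The published per-option costs per person-year pin the
blend's endpoints, and under any visit-level mixing those endpoints
imply a facility crossing near 0.48 — reproducing the published 40%
facility / 23% community thresholds exactly would require the
unpublished itemised cost inputs. The
threshold *solver* is therefore validated analytically (a linear curve
14 − 6s against a reference of 11.5 crosses at 5/12; grid and bisection
must agree) and the calibrated-inventory thresholds are reported as
calibration checks. Thresholds rise with the DMPA-SC premium and fall as
provider-administered DMPA-SC visits get costlier, both verified as
monotonicity properties.

## Problem sizes and numerical choices

* Cohort statistics in tests and the acceptance script use the study's
  own arm sizes (393/299/300); recovery checks average 20–50 seeds.
* Convergence checks use 20,000 (closed-form incidence, tolerance 0.01)
  and 50,000 per arm (transition-matrix recovery, max-abs 0.02).
* Monte-Carlo runs use 1000 replicates, n₀ = 100,000, seed-controlled
  (`numpy.random.default_rng`); identical seeds give byte-identical
  pipeline outputs.
* Newton iterations for the hazard ratio stop at |Δβ| < 1e−13 with
  β clipped to ±30; transition-matrix rows absorb float residue on the
  diagonal so rows sum to 1 within 1e−12.
* Report rounding follows the published tables: costs to 2 decimals,
  percentages to 1 decimal (half away from zero, typographic minus),
  person-years to integers.

## Known limitations

The cohort-level Markov outputs (absolute person-years and cost per
person-year of the IM and PA-SC *cohorts*) are not comparable to the
published cohort-model values: person-time here is counted inside the
12-month window only (the engine's occupancy accounting caps person-years
at n₀), while the published person-year totals exceed n₀ and therefore
include protection dispensed beyond the window (advance provision), and
the published models draw on transition structure (e.g. switches to the
alternative provider-administered product) that the stylised generator
does not produce. The published *table arithmetic* — relative
differences and the $0.46 cost-per-person-year gap — is reproduced from
the printed means, and the per-option steady-state costs are calibration
targets hit exactly. Costs of non-DMPA methods, unintended pregnancies,
client out-of-pocket spending, side-effect treatment, waste disposal,
training programmes and supply-chain overhead are all out of scope.
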