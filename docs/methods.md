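# Methods

## Model structure

The package simulates an assisted-reproduction program for a virtual PCOS
patient as a finite decision tree of at most three treatment cycles.

**Fresh cycle** (always cycle 1): controlled ovarian hyperstimulation,
then a chain of Bernoulli stage events — oocyte pickup, usable oocytes
after pickup, insemination technique (ICSI with probability drawn from the
"ICSI share" range, conventional IVF otherwise), fertilization, embryo
transfer, ongoing pregnancy. The first failed event terminates the cycle
and is recorded as its terminal stage (`pickup_failed`,
`no_usable_oocytes`, `fertilization_failed`, `transfer_not_reached`,
`transfer_failed`, or `pregnant`).

**Frozen cycle** (cycles 2–3 only): embryo thaw/survival, then transfer
and the ongoing-pregnancy event (`thaw_failed`, `transfer_failed`,
`pregnant`). "Pregnancy" is everywhere the same endpoint: an ongoing
pregnancy at 12 gestational weeks; the frozen-cycle clinical-pregnancy
probability is treated as that same endpoint.

**Sequencing.** After a failed first cycle the patient starts cycle 2 with
the tabulated continuation probability; cycle 2 is fresh or frozen per the
cycle-2 fresh share. A patient who is still not pregnant after the cycle-2
stage — whether that cycle was run and failed, or declined — draws the
cycle-3 continuation gate in the same way. This reading (the cycle-3 gate
conditions on "still not pregnant", not on "cycle 2 was run") follows the
tables' failure-conditioned continuation probabilities and is the variant
whose midpoint expectations match the reference results; the strict chain
variant lowers the program pregnancy rate by ≈ 0.015.

Pregnancy is absorbing: no cycle follows a pregnant cycle. One embryo is
transferred per transfer event; there is no surplus-embryo inventory, no
twin pregnancies, no OHSS cancellation pathway, no discounting.

### Sequencing modes

* `table_faithful` (default): frozen cycles are available unconditionally
  at the tabulated shares. This is what the parameter tables describe.
* `strict_embryo_gating`: a frozen transfer requires some prior fresh
  cycle to have reached successful fertilization (so a cryopreserved
  embryo can exist); otherwise the cycle falls back to fresh. Provided as
  a documented variant; it has no closed-form oracle here and is validated
  against forced scenarios (e.g. fertilization impossible ⇒ every cycle
  fresh).

## Parameters and sampling

Every parameter is a closed interval. Probabilities are fractions in
[0, 1]; costs are euros ≥ 0; `lo ≤ hi`; degenerate intervals are fixed
values. At *every use* the engine draws the parameter uniformly from its
interval and, for stage events, then draws the Bernoulli outcome — i.e.
probabilities and unit costs are redrawn per cycle and per item, not
frozen per patient. Consequences:

* the success probability of each stage event is exactly the interval
  midpoint, and every program-level expectation is **multilinear** in the
  midpoints, so the closed-form tree in `ivfsim.analytic` is the *exact*
  mean of the stochastic engine (the basis of the oracle-equivalence
  tests);
* with the narrow reference intervals, the distributional difference from
  per-patient parameter draws is negligible for the reported outcomes.

The built-in reference tables (`reference_parameters()`, also shipped as
`data/reference_parameters.csv` with probabilities in percent exactly as
printed in their source) encode the Italian setting: per-arm fresh-cycle
probabilities — the myo-inositol arm has higher usable-oocyte,
IVF-fertilization, transfer and ICSI-fertilization ranges and a €100
cheaper stimulation range (€900–1900 vs €1000–2000, the supplement cost
being contained in the combined treatment price) — and shared frozen,
sequencing and cost parameters. The "IVF versus ICSI" range 10–50% is
interpreted as the probability of ICSI; only this reading reproduces the
reference pregnancy rates (the converse pushes them above 0.40).

Cost accrual per fresh cycle: stimulation drug (arm-specific), adjunct
hormones, monitoring ultrasounds and consultations are billed
unconditionally; the pickup fee (€1000) and pickup ultrasound (fixed €30)
on successful pickup; IVF laboratory, or ICSI procedure + ICSI laboratory,
when the lab stage is reached; the technique's catheter/disposables when a
transfer is performed. Frozen cycles bill freeze-and-thaw always and the
frozen-transfer catheter on embryo survival; monitoring and consultations
do not recur in frozen cycles (this reproduces the reference per-arm
totals within 1%). OHSS treatment (€90–150) is **not** billed by default —
the reference totals are reproduced without it and no application rule is
tabulated; `ohss_prob` (CLI `--ohss-prob`) bills it per fresh cycle with
the given probability.

## Point parameterizations

`midpoint(params)` returns a `StudyParameters` in which every interval is
collapsed to its degenerate midpoint. Representing point parameterizations
as degenerate tables (rather than a parallel scalar type) keeps a single
set of types: points validate, simulate and serialize exactly like full
tables. Since expectations depend only on midpoints, the analytic
functions accept any table, degenerate or not, and are exact either way.

## Randomness and reproducibility

All stochastic code consumes a `numpy.random.Generator`. A cohort run
builds `SeedSequence([seed, arm_index])` and spawns one child stream per
patient, so: identical `(params, strategy, n, seed, mode)` give
bit-identical results; the two arms are driven by disjoint randomness for
the same seed; and per-patient substreams never overlap. Result JSON is
written with sorted keys and no timestamps, so identical configurations
produce byte-identical files.

## Aggregation conventions

* `mean_cost`, `sd_cost`: mean and SD (ddof = 1) of per-patient total cost.
* `pregnancy_rate`: pregnancies / n.
* `sd_rate`: per-patient pregnancy is binary (SD ≈ 0.48, uninformative as
  a dispersion of the *rate*), so the reported dispersion is the SD of
  pregnancy fractions over consecutive disjoint sub-cohorts of
  `subcohort_size` patients (default 150, giving binomial dispersion of
  the conventional reported magnitude ≈ 0.04). This is a declared
  reporting convention, configurable via `--subcohort-size`; patients in a
  trailing incomplete sub-cohort are excluded from this statistic only.
  Note `sd_rate` depends on the grouping and is therefore the one summary
  statistic that is not invariant under permuting patients.
* `cost_per_pregnancy = mean_cost / pregnancy_rate` (unrounded rate),
  undefined (None, never infinite) when no pregnancy occurred; its
  dispersion is `sd_cost / pregnancy_rate`.
* Between-arm tests: two-sample unequal-variance z test on per-patient
  costs and a pooled two-proportion z test on pregnancy, two-sided normal
  p-values (appropriate at n = 10⁵; displayed with a `< 0.0001` floor).
  Dominance verdict: an arm dominates iff it is strictly cheaper *and*
  strictly more effective; ties are a trade-off.

## Scenario generator

`random_scenario(seed, width_bounds)` emulates the statistical shape of
the reference tables: independent uniform intervals, probability-interval
widths drawn from `width_bounds` (default 0–0.3) with the lower bound
uniform on the feasible range, and cost lower bounds drawn log-uniformly
between €10 and €5,000 (spanning the reference table's orders of magnitude
without degenerate zeros) with relative widths from `width_bounds`. Every
output passes validation by construction. What it does *not* emulate:
correlations between stages, arm-specific effect structure (both arms are
drawn independently), or clinically calibrated magnitudes — so tests on
random scenarios establish structural correctness of the engine, not
clinical realism. Degenerate scenarios (`certain_success`,
`certain_failure`, `single_cycle_only`) force single known paths for exact
assertions.

## Numerical and testing choices

* Exactness: recursive tree evaluation (production) and a flat exhaustive
  path enumeration (test-only, `tests/_enumeration.py`) are independent
  transcriptions of the pathway structure and must agree to ≈ machine
  precision (1e-12) on reference and random tables.
* Oracle equivalence of the stochastic engine uses |simulated − exact| <
  3 Monte Carlo SE per outcome. Checks are two-stage: an excursion beyond
  3 SE is re-tested once on an independent replication cohort with a
  deterministically derived seed and must persist to fail — the standard
  guard for validating unbiased stochastic code against its exact mean,
  since a structural bias persists across replicates while a sampling
  excursion (~0.3% per check by construction) does not.
* Test problem sizes: 100,000 patients per arm for the headline
  reproduction (matching the reference cohort size; ≈ 5 s per arm),
  20,000 per random scenario for oracle equivalence — the package's
  chosen balance of statistical resolution (rate SE ≈ 0.003) and test-suite
  turnaround.
* Monotonicity is verified by finite differences of the analytic
  pregnancy in each of the 13 transition probabilities that are
  non-decreasing at the reference tables (the ICSI share qualifies there
  because the ICSI branch outperforms the IVF branch; the two
  fresh-vs-frozen shares are excluded since a fresh cycle is *less*
  effective than a frozen one at the reference midpoints).

## Known limitations

* The model reproduces tabulated transition ranges; it carries no
  patient-level covariates, no correlation between a patient's successive
  cycles beyond the tree structure, and no embryo inventory.
* Cost dispersion reflects pathway variability plus uniform price draws;
  real billing data would add heavier tails.
* The dominance conclusion is as strong as the input ranges; the package
  deliberately exposes `sensitivity_scan` and scenario generation so users
  can probe how far it persists.
* v1 supports exactly two arms and uniform sampling only (no beta/gamma
  probabilistic-sensitivity variants, no CEAC/net-monetary-benefit
  curves).
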