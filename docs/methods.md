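# Methods

## Model structure

The package evaluates two strategies for acute basilar artery occlusion
(aBAO) stroke — endovascular thrombectomy (EVT) and best medical care (BMC) —
with a decision tree feeding a cohort state-transition (Markov) model.

**Decision tree.** Each strategy cohort is split by underlying basilar
stenosis (prevalence 0.397). EVT patients with stenosis are further split by
acute stenting (probability 0.618), giving three EVT leaves (weights
0.397·0.618, 0.397·0.382, 0.603) and two BMC leaves (0.397, 0.603).
Stenosis leaves carry a relative risk of 3.4 on annual stroke recurrence;
the stented leaf additionally carries an in-stent-thrombosis hazard ratio of
1.057 on recurrence (the hazard's target is not stated in the source inputs;
recurrence is the only event it can plausibly modify in this structure).
Zero-weight leaves are pruned, so degenerate trees (e.g. stenosis prevalence
0) collapse gracefully.

**States and entry.** The Markov states are mRS 0–5 plus absorbing Death
(mRS 6 and Death share a state). Each leaf enters in its strategy's pooled
90-day mRS distribution; the published pooled rows (EVT:
6.5/16.5/14.0/9.5/7.0/12.75/33.75 %, BMC: 3.75/7.0/8.0/9.25/13.75/12.5/
45.75 %) ship as defaults. The same distribution is used for every leaf of a
strategy because no stenosis-stratified outcomes were published.

**Transitions.** Cycle length is one year. Event ordering within a cycle is
fixed and documented: death first, then recurrence among survivors, then
outcome redistribution. Annual death probability in state *s* at age *a* is
the life-table probability q(a) converted to a rate, multiplied by the
mRS-specific hazard ratio, and converted back (`1 − (1−q)^HR` for t = 1).
Risk ratios (the stenosis RR 3.4) act directly on the probability scale with
a cap at 1; both conventions are configurable (`hr_space`, `rr_space`).
Recurrence probabilities follow the published 10-year series
(0.059, 0.036, 0.025, 0.022, 0.022, 0.027, 0.027, 0.023, 0.028, 0.016);
years beyond 10 hold the year-10 value. A recurrent stroke moves the patient
to the worse of the current state and a category drawn from the
recurrent-outcome distribution (0.129/0.136/0.164/0.247/0.135/0.189 over
{mRS 0–1, 2, 3, 4, 5, 6}); the combined "mRS 0 or 1" category maps to mRS 1
by default (conservative; `recurrent_mrs01_mapping` offers mRS 0 or a 50/50
split). Survivors of a recurrent stroke use their new state's death hazard
from the next cycle on.

**Accounting.** Cycle 1 accrues acute hospitalization costs by entry group
(mRS 0–2: $26,705; 3–5: $106,533; 6: $88,159), first-90-day and day-91–365
costs for survivors, and the EVT ($17,103) and stent ($9,000) add-ons where
applicable; patients entering in mRS 6 incur the mRS 6 hospitalization cost
and zero QALYs. From cycle 2 on, state-specific long-term annual costs
($14,230 … $86,612 for mRS 0–5) replace the first-year stack (the two cost
systems never overlap, avoiding double counting) and each recurrent stroke
adds $29,259 of acute care cost in proportion to incidence. QALYs accrue on
the occupancy of the cycle at utilities (1.00, 0.91, 0.76, 0.65, 0.33, 0.00)
for mRS 0–5; cycle 1 credits one full year at the entry state. Both streams
are discounted at 3 %/year by (1+r)^−(cycle−1), i.e. year 1 undiscounted.
These last two conventions (no half-cycle correction, discounting from year
2) are the package's own choices where the source analysis is silent; a
trapezoid-style half-cycle correction is available behind
`half_cycle_correction` but off by default. The horizon is age 110 or cohort
extinction (alive mass < 1e-9), whichever comes first.

**Comparison.** Strategy cost/QALY expectations are the weight-averaged leaf
totals. Incremental analysis reports ΔC, ΔE and either the ICER or a
dominance label (dominance is checked before dividing). Net monetary benefit
is WTP·ΔE − ΔC; willingness-to-pay anchors are $63,593/QALY (1× U.S. GDP per
capita, "highly cost-effective") and $190,779/QALY (3×).

## The survivor death-hazard-ratio row

The published input table prints "annual death hazard ratios for survivors
mRS 0–5" as 0.129/0.136/0.164/0.247/0.135/0.189 — identical to the
recurrent-outcome distribution printed directly below it, summing to 1, and
all below 1. Taken literally, every stroke survivor would far outlive the
general population, roughly doubling lifetime QALYs; the row is almost
certainly a typesetting duplication. The package therefore ships two
configurations:

* `death_hr="printed"` — the row verbatim, with an unsuppressible warning;
* `death_hr="literature"` (**reference configuration**) — mRS-specific
  long-term survivor mortality hazard ratios 1.53/1.52/2.17/3.18/4.55/6.55
  from the stroke disability-outcome literature the row cites, which produce
  lifetime costs and QALYs on the scale of the published results.

## Life table

Background mortality defaults to a synthetic Gompertz–Makeham table,
`q(age) = 1 − exp(−(A + B·e^{C·age}))` with A = 7e-4, B = 3e-5, C = 0.094
and terminal age 110 (q = 1). This approximates recent U.S. all-population
period mortality (q(66) ≈ 0.0154, q(80) ≈ 0.056) but is *not* published
life-table data; a real two-column `(age, qx)` CSV can be supplied for exact
replication. Lookups are at integer ages with no interpolation (cohort age =
start age + cycle index); ages past the terminal row clamp to q = 1.

## Sensitivity analyses

**Tornado.** Every cost input (16 scalars) is set to ±25 % of base, one at a
time, and the ICER is re-computed by running the full model; entries are
sorted by ICER span. Dominant corners are represented by the signed ΔC/ΔE
ratio so spans remain defined, and the span scales continuously with the
relative range.

**Age sweep.** The whole comparison is re-run with the starting age replaced
(the life table covers ages 0–110, so sweeps of 50–99 are in range).

**Probabilistic sensitivity analysis.** Costs are gamma-distributed and
utilities beta-distributed, both fitted by the method of moments (gamma:
shape = (m/sd)², scale = sd²/m; beta: ν = m(1−m)/sd² − 1, α = mν,
β = (1−m)ν). The source analysis states the distribution families but not
their spreads, so the coefficients of variation are explicit assumptions:
`cost_cv = 0.25` (mirroring the deterministic ±25 % range) and
`util_cv = 0.10`. Utilities of exactly 0 or 1 cannot carry a beta
distribution and are held fixed, as are all decision-tree and transition
probabilities (the source marks them with no distribution). Each of the
n iterations draws one common set of parameters used by both strategies
(common random numbers). Because costs and utilities enter the accounting
linearly while state dynamics stay fixed, each draw is priced exactly
through per-leaf accounting components (discounted state-year sums,
discounted recurrence incidence, entry-group masses) extracted from a single
cohort run per strategy; a test verifies this path against full engine
re-runs at the drawn values, and zero-variance PSA reproduces the base case
exactly. The acceptability curve evaluates P(NMB > 0) on a $0–200,000 WTP
grid in $250 steps; the crossover WTP (first grid point with probability
> 0.5) is therefore resolved to $250.

## Synthetic data and validation oracle

The generator module emulates the study's inputs without any downloads:
multinomial 90-day outcome tables at trial-like arm sizes drawn from the
entry distributions; the Makeham life table above; and an individual-level
microsimulation that replays the cohort engine's own event pieces
(state-specific death probability, year-indexed recurrence, worse-of
redistribution, the full cost stack, discounting) for n independent
patients. Because the microsimulation samples from the same transition
components the cohort engine integrates, agreement (within 3 standard
errors at n = 50,000, checked on three differently-stressed parameter sets)
validates the event logic and accounting, not a re-derivation. What passing
these tests does **not** show: anything about real patient-level cost
skewness or outcome heterogeneity — the oracle validates expectations only,
and the synthetic trials assume exact multinomial sampling from the pooled
distributions (no between-trial heterogeneity, crossover, or loss to
follow-up, all of which the real trials had).

A closed-loop parameter-recovery study (simulate trials → re-pool → re-run
the CEA) confirms the pipeline recovers entry probabilities within 0.01 and
the ICER within 5 % at 10⁵ patients per arm.

## Trial pooling

The pooled entry distributions are the unweighted arithmetic means of the
four trials' arm-level mRS percentages, renormalized. This reproduces
several published pooled cells exactly (EVT mRS 4 = 7.0 %, BMC mRS 0 =
3.75 %) and is the default; a count-weighted (patient-level) pooling mode is
provided because two published cells (16.5, 13.75) match neither method
exactly and the original pooling rule is not stated. Pooling is
permutation-invariant and always returns a distribution summing to 1.

## Reproduction scope and limitations

The original analysis was run in a commercial decision-modelling package
with several conventions unstated (life-table vintage, half-cycle
correction, discount timing, the anomalous death-HR row, the exact pooling
rule), and some of its printed values are mutually inconsistent (e.g.
incrementals that are not the differences of the printed totals). The
package reproduces exactly the quantities that are convention-independent
(the pooled entry cells) and reproduces the qualitative findings — EVT
cost-effective far below the WTP threshold at every swept age, the ICER
most sensitive to the EVT procedure cost and never exceeding $25,000/QALY
under ±25 % cost variation, near-100 % probability of cost-effectiveness in
the PSA, and dominance of EVT in the late-window subgroup and (in cost
terms) the stenosis strata. Headline magnitudes differ from the published
point estimates (e.g. base-case ICER ≈ $18,400/QALY here vs ≈ $7,600
published; lifetime QALYs ≈ 2.1/3.4 vs 2.58/4.28) — with the printed
death-HR row the gap is far larger in the opposite direction, so the
difference is dominated by the unrecoverable mortality inputs rather than
the engine. All numbers above are computed by the test suite and
`scripts/acceptance.py`, not asserted from the source.

Other limitations: no tunnel states or within-cycle competing risks; no sex
stratification; costs are U.S. 2022 values with no currency or CPI
re-indexing; recurrence beyond year 10 holds the year-10 probability; the
stenosis prevalence's published ± term is stored as metadata but not drawn
in the PSA (no distribution is specified for probabilities).
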