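# baocea

Lifetime Markov cost-effectiveness model of **endovascular thrombectomy (EVT)
versus best medical care (BMC) in acute basilar artery occlusion (aBAO)
stroke**, from the perspective of the U.S. healthcare system.

Acute basilar artery occlusion is a severe posterior-circulation stroke: most
patients die or remain severely disabled under medical management alone. Four
randomized trials (ATTENTION, BAOCHE, BASICS, BEST) established that
thrombectomy improves 90-day functional outcome on the modified Rankin Scale
(mRS, 0 = no symptoms … 6 = death). This package answers the health-economic
question: given the procedure's up-front cost, is EVT good value over a
patient's remaining lifetime?

## The model

A decision tree splits each strategy cohort by underlying basilar stenosis
(prevalence 0.397) and, for EVT, by acute stenting (0.618 of stenosis
patients). Each leaf enters a Markov model in the pooled 90-day mRS
distribution of its strategy and is simulated in 1-year cycles to age 110.
Each year a survivor in state *s*

* dies with probability `1 − (1 − q(age))^HR_s` — background life-table
  mortality `q(age)` scaled on the hazard (rate) scale by an mRS-specific
  hazard ratio `HR_s`;
* otherwise suffers a recurrent stroke with the year-specific probability
  (0.059 in year 1, declining to 0.016 by year 10, held thereafter),
  multiplied by RR = 3.4 under stenosis and HR = 1.057 after stenting, and
  moves to the *worse* of the current state and a drawn recurrent-outcome
  state (which may be death);
* otherwise stays in state *s*.

Year 1 accrues acute hospitalization, first-90-day and day-91–365 costs plus
the EVT/stent procedure add-ons; later years accrue mRS-specific long-term
annual costs and acute costs for recurrent strokes. Effectiveness is
quality-adjusted life years, `QALY = Σ_t δ^t Σ_s occ_t(s)·u(s)` with
utilities u = (1.00, 0.91, 0.76, 0.65, 0.33, 0.00) for mRS 0–5 and discount
factor δ = 1/1.03. Strategies are compared by the incremental
cost-effectiveness ratio `ICER = ΔC/ΔE` against willingness-to-pay thresholds
of $63,593/QALY (1× U.S. GDP per capita) and $190,779/QALY (3×), with
dominance checked before division.

Uncertainty handling: a ±25 % one-way cost tornado, a sweep of onset age, and
a probabilistic sensitivity analysis drawing every cost from a
method-of-moments gamma and every utility from a method-of-moments beta
distribution, summarized as a cost-effectiveness acceptability curve (CEAC).

A vectorized individual-level microsimulation replays the identical event
logic patient-by-patient and serves as the engine's correctness oracle
(cohort expectations must agree within Monte Carlo error).

## Worked example

```python
from baocea import MarkovCEA

res = MarkovCEA.from_defaults().fit()
print(res.summary())
```

```
Lifetime cost-effectiveness: EVT vs best medical care (aBAO stroke)
======================================================================
start age 66 y | discount 3.0%/y | horizon to age 110
WTP thresholds: $63,593/QALY (1x GDP pc), $190,779/QALY (3x)
----------------------------------------------------------------------
cohort                                cost ($)    QALY            ICER
BMC total                              264,817    2.13
BMC stenosis_no_stent                  267,809    1.85
BMC no_stenosis                        262,847    2.32
EVT total                              287,994    3.39    $18,394/QALY
EVT stenosis_stented                   302,760    2.85    $52,483/QALY
EVT stenosis_no_stent                  293,067    2.91    $36,525/QALY
EVT no_stenosis                        280,710    3.73     $9,927/QALY
----------------------------------------------------------------------
incremental cost  $23,176
incremental QALYs 1.26
comparison        $18,394/QALY
NMB at $63,593/QALY: $56,951
```

Reading: under best medical care an average 66-year-old aBAO patient accrues
2.13 discounted QALYs and $264,817 of discounted lifetime cost; thrombectomy
adds 1.26 QALYs for $23,176 — $18,394 per QALY gained, far below the $63,593
willingness-to-pay, so EVT is clearly cost-effective (positive net monetary
benefit of ~$57,000 per patient). In the late-window (6–24 h) subgroup
modelled on the BAOCHE trial's own outcome rows
(`MarkovCEA.from_defaults("baoche_subgroup")`), EVT is *dominant*: better
outcomes and lower lifetime cost.

Two caveats, detailed in `docs/methods.md`: the published input table's
survivor death-hazard-ratio row is a typesetting duplication of another row,
so the default model uses mRS-specific hazard ratios from the stroke
outcomes literature (the printed row remains available as
`death_hr=\"printed\"` and triggers a warning); and background mortality
defaults to a synthetic Gompertz–Makeham life table unless a real `(age, qx)`
CSV is supplied.

Sensitivity analyses hang off the model object:

```python
m = MarkovCEA.from_defaults()
m.tornado()                      # ±25% one-way cost sensitivity
m.age_sweep(range(50, 100))      # ICER vs onset age
psa = m.fit_psa(30_000, seed=7)  # probabilistic sensitivity analysis
psa.prob_cost_effective(63_593)  # -> 1.0
```

There is also a CLI (`baocea run|tornado|age-sweep|psa|pool|simulate-data`)
driven by a YAML config; see `baocea --help`.

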