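"""Synthetic inputs and an individual-level microsimulation oracle.

Nothing here is downloaded: the life table is a Gompertz–Makeham
approximation of recent U.S. all-population period mortality (a real (age,
qx) CSV can be dropped in for exact replication), trial outcome tables are
multinomial draws, and the microsimulation replays the cohort engine's own
event logic (death -> recurrence -> redistribution -> accrual -> discounting)
one patient at a time, which makes it an independent check of the cohort
expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cea import incremental_analysis
from .markov import (DEAD, STRATEGY_BMC, STRATEGY_EVT, SubCohort,
                     evaluate_strategy, recurrence_probability,
                     recurrence_redistribution, sc_entry_distribution)
from .mortality import mrs_adjusted_death_prob
from .params import (LifeTable, OutcomeDistribution, ParameterSet,
                     ParameterError, TrialOutcomeTable,
                     pool_outcome_distributions)


@dataclass(frozen=True)
class MakehamParams:
    """Gompertz–Makeham mortality: hazard(age) = A + B*exp(C*age).

    A is the age-independent background rate per year, B the baseline
    senescent rate, C the exponential age coefficient per year.
    """

    A: float
    B: float
    C: float
    max_age: int = 110

    def __post_init__(self) -> None:
        if self.A < 0 or self.B <= 0 or self.C <= 0:
            raise ParameterError("Makeham parameters require A >= 0, B > 0, C > 0")
        if self.max_age < 1:
            raise ParameterError("max_age must be >= 1")

    def hazard(self, age: float) -> float:
        return self.A + self.B * math.exp(self.C * age)


#: Rough calibration to recent U.S. all-population period mortality
#: (e.g. q(66) ~ 0.016, q(80) ~ 0.06). An approximation, not published
#: life-table data.
US_LIKE_2019 = MakehamParams(A=0.0007, B=3e-5, C=0.094, max_age=110)


def synthetic_life_table(mp: MakehamParams = US_LIKE_2019) -> LifeTable:
    """Annual death probabilities q(age) = 1 - exp(-hazard(age)), terminal q = 1."""
    ages = tuple(range(0, mp.max_age + 1))
    qx = [-math.expm1(-mp.hazard(a)) for a in ages[:-1]] + [1.0]
    return LifeTable(ages=ages, qx=tuple(qx))


def simulate_trial_table(n_arm: int, true_dist: OutcomeDistribution,
                         trial_name: str, seed: int,
                         arm: str = "intervention") -> TrialOutcomeTable:
    """Multinomial 90-day mRS outcome table for one synthetic trial arm."""
    if n_arm < 1:
        raise ParameterError("n_arm must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_arm, true_dist.as_array())
    return TrialOutcomeTable.from_counts(trial_name, arm, n_arm, counts)


def microsim_oracle(sc: SubCohort, p: ParameterSet, lt: LifeTable, n: int,
                    seed: int, horizon: int | None = None
                    ) -> tuple[float, float, float, float]:
    """Individual-level replay of the cohort model for one leaf.

    Simulates ``n`` independent patients through the same event pieces the
    cohort engine composes (mRS-adjusted death, year-indexed recurrence,
    worse-of redistribution, the cycle-1 cost stack, long-term annual costs,
    recurrent-stroke acute costs, utility accrual, discounting) and returns
    ``(mean cost, mean QALY, SE cost, SE QALY)`` of the per-patient
    discounted totals. The cohort expectation must agree within Monte Carlo
    error — this is the engine's central correctness oracle.
    """
    if n < 100:
        raise ParameterError("use at least 100 individuals")
    rng = np.random.default_rng(seed)
    if horizon is None:
        horizon = max(1, p.max_age - p.start_age + 1)

    entry = sc_entry_distribution(sc, p).as_array()
    util = np.asarray(p.utilities)
    longterm = np.asarray(p.cost_longterm_annual)
    r = p.discount_rate

    states = rng.choice(7, size=n, p=entry)

    # cycle 1: the acute cost stack is identical for every patient in the
    # leaf except for the entry-state group, so price it per patient
    group_cost = np.empty(7)
    group_cost[0:3] = p.cost_hosp[0] + p.cost_first90[0] + p.cost_day91_365[0]
    group_cost[3:6] = p.cost_hosp[1] + p.cost_first90[1] + p.cost_day91_365[1]
    group_cost[6] = p.cost_hosp[2]
    addon = (p.cost_evt_addon if sc.strategy == STRATEGY_EVT else 0.0) \
        + (p.cost_stent_addon if sc.stented else 0.0)
    cost = group_cost[states] + addon
    qaly = np.where(states < 6, util[np.minimum(states, 5)], 0.0)
    if p.half_cycle_correction:
        qaly = 0.5 * qaly

    # redistribution lookup: row s = post-recurrence state distribution
    redist = np.vstack([recurrence_redistribution(s, p) for s in range(6)])
    redist_cdf = np.cumsum(redist, axis=1)

    last_alive_util = np.where(states < 6, util[np.minimum(states, 5)], 0.0)
    for c in range(2, horizon + 1):
        alive = states < DEAD
        if not alive.any():
            break
        age = p.start_age + (c - 1)
        year = c - 1
        disc = (1.0 + r) ** -(c - 1)
        rec_p = recurrence_probability(year, sc, p)

        death_p = np.array([mrs_adjusted_death_prob(lt, age, s, p) for s in range(6)])
        u = rng.random(n)
        dies = alive & (u < death_p[np.minimum(states, 5)])

        survivors = alive & ~dies
        u2 = rng.random(n)
        recurs = survivors & (u2 < rec_p)

        # redistribute recurrent strokes: inverse-CDF draw per patient
        if recurs.any():
            idx = np.nonzero(recurs)[0]
            u3 = rng.random(idx.size)
            rows = redist_cdf[states[idx]]
            new_states = (u3[:, None] < rows).argmax(axis=1)
            states[idx] = new_states
        states[dies] = DEAD

        alive_now = states < DEAD
        cyc_q = np.where(alive_now, util[np.minimum(states, 5)], 0.0)
        cyc_cost = np.where(alive_now, longterm[np.minimum(states, 5)], 0.0)
        cyc_cost = cyc_cost + np.where(recurs, p.cost_recurrent_acute, 0.0)
        qaly = qaly + disc * cyc_q
        cost = cost + disc * cyc_cost
        last_alive_util = cyc_q

    if p.half_cycle_correction:
        qaly = qaly + 0.5 * last_alive_util * (1.0 + r) ** -horizon

    mean_cost, mean_qaly = float(cost.mean()), float(qaly.mean())
    se_cost = float(cost.std(ddof=1) / math.sqrt(n))
    se_qaly = float(qaly.std(ddof=1) / math.sqrt(n))
    return mean_cost, mean_qaly, se_cost, se_qaly


def parameter_recovery_study(true_p: ParameterSet, n_arm: int, n_trials: int,
                             seed: int, lt: LifeTable | None = None) -> dict:
    """End-to-end check: simulate trials, re-pool, re-run the CEA.

    Draws ``n_trials`` synthetic trials per arm from the true entry
    distributions, pools them back with the default (unweighted) method, and
    compares the pooled probabilities and the recovered ICER against the
    truth-under-the-model. Flags wide sampling uncertainty at small arms.
    """
    if n_arm < 1 or n_trials < 1:
        raise ParameterError("n_arm and n_trials must be >= 1")
    if lt is None:
        lt = synthetic_life_table()
    rng = np.random.default_rng(seed)

    trials = []
    for k in range(n_trials):
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        trials.append(simulate_trial_table(
            n_arm, true_p.entry_dist_evt, f"synthetic_{k}", int(s1), "intervention"))
        trials.append(simulate_trial_table(
            n_arm, true_p.entry_dist_bmc, f"synthetic_{k}", int(s2), "bmc"))

    pooled_evt = pool_outcome_distributions(trials, "intervention")
    pooled_bmc = pool_outcome_distributions(trials, "bmc")

    def _icer(p: ParameterSet) -> float:
        bmc = evaluate_strategy(STRATEGY_BMC, p, lt)
        evt = evaluate_strategy(STRATEGY_EVT, p, lt)
        return incremental_analysis(bmc, evt).icer_or_signed_ratio()

    true_icer = _icer(true_p)
    recovered = true_p.replace(entry_dist_evt=pooled_evt, entry_dist_bmc=pooled_bmc)
    recovered_icer = _icer(recovered)

    bias_evt = pooled_evt.as_array() - true_p.entry_dist_evt.as_array()
    bias_bmc = pooled_bmc.as_array() - true_p.entry_dist_bmc.as_array()
    # multinomial SE of a pooled cell near p ~ 0.15 at the smallest arm size
    approx_se = math.sqrt(0.15 * 0.85 / (n_arm * n_trials))

    return {
        "n_arm": n_arm,
        "n_trials": n_trials,
        "pooled_evt": tuple(pooled_evt.p),
        "pooled_bmc": tuple(pooled_bmc.p),
        "entry_bias_evt": tuple(bias_evt),
        "entry_bias_bmc": tuple(bias_bmc),
        "max_abs_entry_bias": float(max(np.abs(bias_evt).max(), np.abs(bias_bmc).max())),
        "true_icer": true_icer,
        "recovered_icer": recovered_icer,
        "icer_rel_error": abs(recovered_icer - true_icer) / abs(true_icer),
        "wide_uncertainty": bool(approx_se > 0.02),
    }
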