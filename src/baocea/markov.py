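"""Lifetime Markov cohort engine.

Each strategy (EVT or BMC) is split by a decision tree into sub-cohorts —
underlying basilar stenosis yes/no, and for EVT with stenosis, acute stenting
yes/no. Every sub-cohort enters the Markov model in its strategy's pooled
90-day mRS distribution and is simulated in 1-year cycles until age
``max_age`` or extinction. Within a cycle, survivors either remain at their
mRS level or suffer a recurrent stroke that moves them to the worse of their
current state and a drawn recurrent-outcome state (possibly death); annual
mortality is background mortality scaled by an mRS-specific hazard ratio.

Accounting conventions (the published analysis does not state its own):
cycle 1 accrues the acute hospitalization + first-90-day + day-91–365 cost
stack and one full year of utility at the entry state; cycles >= 2 accrue
state-specific long-term annual costs, acute recurrent-stroke costs in
proportion to recurrence incidence, and utility on the post-transition
occupancy; both streams are discounted by (1+r)^-(cycle-1), i.e. year 1
undiscounted. An optional trapezoid-style half-cycle correction can be
switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mortality import HazardAdjustment, apply_adjustment, mrs_adjusted_death_prob
from .params import LifeTable, OutcomeDistribution, ParameterSet, ParameterError

STATES = ("mrs0", "mrs1", "mrs2", "mrs3", "mrs4", "mrs5", "dead")
N_STATES = 7
DEAD = 6

STRATEGY_EVT = "EVT"
STRATEGY_BMC = "BMC"


@dataclass(frozen=True)
class SubCohort:
    """One leaf of the decision tree: strategy x stenosis x stenting."""

    strategy: str
    stenosis: bool
    stented: bool
    weight: float
    recurrence_multipliers: tuple[HazardAdjustment, ...] = ()

    def __post_init__(self) -> None:
        if self.strategy not in (STRATEGY_EVT, STRATEGY_BMC):
            raise ParameterError(f"unknown strategy {self.strategy!r}")
        if self.stented and not (self.strategy == STRATEGY_EVT and self.stenosis):
            raise ParameterError("stented leaves require EVT with stenosis")
        if not 0.0 <= self.weight <= 1.0:
            raise ParameterError("leaf weight must be a probability")

    @property
    def label(self) -> str:
        if not self.stenosis:
            return "no_stenosis"
        return "stenosis_stented" if self.stented else "stenosis_no_stent"


def build_subcohorts(strategy: str, p: ParameterSet) -> list[SubCohort]:
    """Decision-tree leaves for a strategy, with recurrence-risk adjustments.

    Stenosis leaves carry the stenosis recurrence risk ratio; the stented EVT
    leaf additionally carries the in-stent-thrombosis hazard ratio on
    recurrence. Zero-weight leaves are dropped.
    """
    if strategy not in (STRATEGY_EVT, STRATEGY_BMC):
        raise ParameterError(f"unknown strategy {strategy!r}")
    rr = HazardAdjustment(p.rr_recurrence_stenosis, p.rr_space)
    hr_stent = HazardAdjustment(p.hr_instent_thrombosis, p.hr_space)
    ps = p.p_stenosis
    leaves: list[SubCohort] = []
    if strategy == STRATEGY_BMC:
        leaves = [
            SubCohort(strategy, True, False, ps, (rr,)),
            SubCohort(strategy, False, False, 1.0 - ps),
        ]
    else:
        pst = p.p_stent_given_stenosis_evt
        leaves = [
            SubCohort(strategy, True, True, ps * pst, (rr, hr_stent)),
            SubCohort(strategy, True, False, ps * (1.0 - pst), (rr,)),
            SubCohort(strategy, False, False, 1.0 - ps),
        ]
    return [sc for sc in leaves if sc.weight > 0.0]


def recurrence_probability(cycle_year: int, sc: SubCohort, p: ParameterSet) -> float:
    """Annual recurrent-stroke probability in model year ``cycle_year`` (1-based).

    Years beyond the published 10-year series hold the year-10 value. The
    leaf's multipliers (stenosis risk ratio, in-stent-thrombosis hazard
    ratio) are applied in order; the result is capped at 1.
    """
    if cycle_year < 1:
        raise ParameterError("cycle_year is 1-based")
    base = p.p_recurrence_by_year[min(cycle_year, len(p.p_recurrence_by_year)) - 1]
    for adj in sc.recurrence_multipliers:
        base = apply_adjustment(base, adj)
    return min(1.0, base)


def _recurrent_state_map(p: ParameterSet) -> list[list[tuple[int, float]]]:
    """Map the 6 recurrent-outcome categories onto model states.

    Categories are {mRS 0 or 1, 2, 3, 4, 5, 6}; the combined first category
    is mapped per ``p.recurrent_mrs01_mapping`` (worst-case mRS1 by default).
    Returns, per category, a list of (state, share-of-category) pairs.
    """
    if p.recurrent_mrs01_mapping == "mrs1":
        first = [(1, 1.0)]
    elif p.recurrent_mrs01_mapping == "mrs0":
        first = [(0, 1.0)]
    else:  # split
        first = [(0, 0.5), (1, 0.5)]
    return [first, [(2, 1.0)], [(3, 1.0)], [(4, 1.0)], [(5, 1.0)], [(DEAD, 1.0)]]


def recurrence_redistribution(state: int, p: ParameterSet) -> np.ndarray:
    """Distribution over post-recurrence states for a survivor currently in
    ``state``: the new state is the worse of the current state and the drawn
    recurrent-outcome state (death is absorbing)."""
    out = np.zeros(N_STATES)
    for cat, share in zip(_recurrent_state_map(p), p.recurrent_outcome_dist):
        for drawn, frac in cat:
            new = DEAD if drawn == DEAD else max(state, drawn)
            out[new] += share * frac
    return out


def transition_row(state: int, age: int, cycle_year: int, sc: SubCohort,
                   p: ParameterSet, lt: LifeTable) -> np.ndarray:
    """One row of the cycle transition matrix for ``state`` at ``age``.

    Ordering within the cycle: death first (mRS-adjusted background
    mortality), then recurrence among survivors, then outcome redistribution.
    """
    row = np.zeros(N_STATES)
    if state == DEAD:
        row[DEAD] = 1.0
        return row
    d = mrs_adjusted_death_prob(lt, age, state, p)
    rec = recurrence_probability(cycle_year, sc, p)
    row[DEAD] += d
    survive = 1.0 - d
    row[state] += survive * (1.0 - rec)
    row += survive * rec * recurrence_redistribution(state, p)
    s = row.sum()
    assert abs(s - 1.0) < 1e-12, f"transition row sums to {s}"
    return row


def _entry_groups(entry: np.ndarray) -> tuple[float, float, float]:
    """Entry mass in the cost groups mRS 0–2, mRS 3–5, mRS 6."""
    return float(entry[0:3].sum()), float(entry[3:6].sum()), float(entry[6])


def first_cycle_accounting(entry: OutcomeDistribution, sc: SubCohort,
                           p: ParameterSet) -> tuple[float, float, np.ndarray]:
    """Cycle-1 cost, QALY and post-cycle state vector for one leaf.

    Costs: acute hospitalization by entry group, plus the first-90-day and
    day-91–365 stacks for survivors, plus the EVT procedure add-on (EVT
    leaves) and stent add-on (stented leaf). QALYs: one year at the entry
    state's utility. The 90-day-dead (mRS 6) mass moves to the absorbing
    Dead state with zero QALYs.
    """
    e = entry.as_array()
    if e.sum() <= 0:
        raise ParameterError("entry distribution has zero mass")
    g02, g35, g6 = _entry_groups(e)
    cost = (g02 * p.cost_hosp[0] + g35 * p.cost_hosp[1] + g6 * p.cost_hosp[2]
            + g02 * (p.cost_first90[0] + p.cost_day91_365[0])
            + g35 * (p.cost_first90[1] + p.cost_day91_365[1]))
    if sc.strategy == STRATEGY_EVT:
        cost += p.cost_evt_addon
    if sc.stented:
        cost += p.cost_stent_addon
    qaly = float(e[0:6] @ np.asarray(p.utilities))
    # mRS 6 shares the Dead index, so the 90-day deaths are already absorbed
    return cost, qaly, e.copy()


@dataclass
class Trace:
    """Cycle-indexed record of one sub-cohort run.

    ``occupancy[c]`` is the state vector occupied *during* cycle ``c+1``
    (cycle 1 = entry distribution with the 90-day deaths in Dead).
    ``recurrence_mass[c]`` is the recurrent-stroke incidence feeding cycle
    ``c+1`` (zero for cycle 1). Cost/QALY arrays are per-cycle accruals.
    """

    occupancy: np.ndarray           # (T, 7)
    recurrence_mass: np.ndarray     # (T,)
    cost_cycle: np.ndarray          # (T,) undiscounted
    qaly_cycle: np.ndarray          # (T,) undiscounted
    discount_factors: np.ndarray    # (T,)
    start_age: int

    @property
    def n_cycles(self) -> int:
        return len(self.cost_cycle)

    @property
    def cost_cycle_discounted(self) -> np.ndarray:
        return self.cost_cycle * self.discount_factors

    @property
    def qaly_cycle_discounted(self) -> np.ndarray:
        return self.qaly_cycle * self.discount_factors

    @property
    def total_cost(self) -> float:
        return float(self.cost_cycle_discounted.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_cycle_discounted.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost_cycle.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly_cycle.sum())

    def to_frame(self):
        import pandas as pd

        T = self.n_cycles
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(1, T + 1))
        df.insert(1, "age", self.start_age + np.arange(T))
        df["recurrence_mass"] = self.recurrence_mass
        df["cost_cycle"] = self.cost_cycle
        df["qaly_cycle"] = self.qaly_cycle
        df["discount_factor"] = self.discount_factors
        df["cost_cycle_discounted"] = self.cost_cycle_discounted
        df["qaly_cycle_discounted"] = self.qaly_cycle_discounted
        return df


def run_cohort(sc: SubCohort, p: ParameterSet, lt: LifeTable,
               horizon: int | None = None) -> Trace:
    """Run one decision-tree leaf through the lifetime Markov model.

    Stops at ``horizon`` cycles (default: enough cycles to reach
    ``p.max_age``) or when alive mass drops below 1e-9. Raises if the life
    table does not cover the starting age.
    """
    if not lt.min_age <= p.start_age <= lt.max_age:
        raise ParameterError(
            f"life table covers ages {lt.min_age}..{lt.max_age}; cannot start a "
            f"cohort at age {p.start_age}")
    if horizon is None:
        horizon = max(1, p.max_age - p.start_age + 1)
    if horizon < 1:
        raise ParameterError("horizon must be >= 1")

    entry = sc_entry_distribution(sc, p)
    util = np.asarray(p.utilities)
    longterm = np.asarray(p.cost_longterm_annual)
    r = p.discount_rate

    occ = np.zeros((horizon, N_STATES))
    rec_mass = np.zeros(horizon)
    cost = np.zeros(horizon)
    qaly = np.zeros(horizon)

    c1_cost, c1_qaly, state = first_cycle_accounting(entry, sc, p)
    occ[0] = state
    cost[0] = c1_cost
    qaly[0] = c1_qaly

    n = 1
    for c in range(2, horizon + 1):
        age = p.start_age + (c - 1)
        year = c - 1  # recurrence-series year of the transition into cycle c
        new = np.zeros(N_STATES)
        new[DEAD] = state[DEAD]
        inc = 0.0
        for s in range(6):
            if state[s] <= 0.0:
                continue
            row = transition_row(s, age, year, sc, p, lt)
            new += state[s] * row
            d = row[DEAD]  # includes recurrence deaths; recompute incidence directly
            dm = mrs_adjusted_death_prob(lt, age, s, p)
            inc += state[s] * (1.0 - dm) * recurrence_probability(year, sc, p)
        assert abs(new.sum() - state.sum()) < 1e-9, "mass not conserved"
        state = new
        occ[c - 1] = state
        rec_mass[c - 1] = inc
        cost[c - 1] = float(state[0:6] @ longterm) + inc * p.cost_recurrent_acute
        qaly[c - 1] = float(state[0:6] @ util)
        n = c
        if state[0:6].sum() < 1e-9:
            break

    occ, rec_mass, cost, qaly = occ[:n], rec_mass[:n], cost[:n], qaly[:n]
    disc = (1.0 + r) ** -np.arange(n, dtype=float)

    if p.half_cycle_correction:
        # trapezoid-style correction on utility accrual only: half weight on
        # the first cycle, plus a terminal half-cycle at the final occupancy
        # (one-off acute/procedure costs are not half-cycled)
        qaly[0] *= 0.5
        tail_q = float(occ[-1, 0:6] @ util)
        qaly[-1] += 0.5 * tail_q * (1.0 + r) ** -1 if n > 0 else 0.0

    return Trace(occupancy=occ, recurrence_mass=rec_mass, cost_cycle=cost,
                 qaly_cycle=qaly, discount_factors=disc, start_age=p.start_age)


def sc_entry_distribution(sc: SubCohort, p: ParameterSet) -> OutcomeDistribution:
    """Entry 90-day distribution for a leaf (shared within a strategy)."""
    return p.entry_dist_evt if sc.strategy == STRATEGY_EVT else p.entry_dist_bmc


@dataclass
class LeafResult:
    subcohort: SubCohort
    trace: Trace

    @property
    def cost(self) -> float:
        return self.trace.total_cost

    @property
    def qaly(self) -> float:
        return self.trace.total_qaly


@dataclass
class StrategyResult:
    """Weight-averaged discounted cost and effectiveness of one strategy."""

    strategy: str
    leaves: list[LeafResult]

    @property
    def cost(self) -> float:
        return sum(l.subcohort.weight * l.cost for l in self.leaves)

    @property
    def qaly(self) -> float:
        return sum(l.subcohort.weight * l.qaly for l in self.leaves)

    def leaf_summary(self):
        import pandas as pd

        return pd.DataFrame([
            {"strategy": self.strategy, "leaf": l.subcohort.label,
             "weight": l.subcohort.weight, "cost": l.cost, "qaly": l.qaly}
            for l in self.leaves])


def evaluate_strategy(strategy: str, p: ParameterSet, lt: LifeTable,
                      horizon: int | None = None) -> StrategyResult:
    """Run every decision-tree leaf of a strategy and aggregate by weight."""
    leaves = [LeafResult(sc, run_cohort(sc, p, lt, horizon))
              for sc in build_subcohorts(strategy, p)]
    return StrategyResult(strategy=strategy, leaves=leaves)
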