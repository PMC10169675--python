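"""Deterministic and probabilistic sensitivity analysis.

Deterministic: a tornado analysis perturbing every cost input by a relative
range (+/-25% by default) and a one-way sweep of the starting age.
Probabilistic: Monte Carlo re-evaluation with every cost drawn from a
method-of-moments gamma distribution and every (non-degenerate) utility from
a method-of-moments beta distribution; decision-tree and transition
probabilities are held fixed, matching the published design in which only
costs and utilities carry distributions. The published table states no
spread for those distributions, so coefficients of variation are explicit,
mandatory inputs (defaults: 0.25 for costs — mirroring the deterministic
+/-25% range — and 0.10 for utilities; both are assumptions).

Because the varied quantities (costs, utilities) enter the accounting
linearly while the state dynamics stay fixed, each Monte Carlo draw is
evaluated exactly through per-leaf accounting components extracted from a
single cohort run per strategy; a test cross-checks this against full engine
re-runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import markov
from .cea import CEAResult, incremental_analysis
from .markov import (STRATEGY_BMC, STRATEGY_EVT, build_subcohorts,
                     evaluate_strategy, run_cohort, sc_entry_distribution)
from .params import LifeTable, ParameterSet, ParameterError


# ---------------------------------------------------------------------------
# Method-of-moments distribution fits
# ---------------------------------------------------------------------------

def fit_gamma(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard deviation."""
    if mean <= 0 or sd <= 0:
        raise ParameterError("gamma fit needs positive mean and sd")
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return shape, scale


def fit_beta(mean: float, sd: float, sd_floor: float = 1e-12) -> tuple[float, float]:
    """Beta (alpha, beta) matching a mean and standard deviation."""
    if not 0.0 < mean < 1.0:
        raise ParameterError("beta fit needs mean in (0, 1)")
    sd = max(sd, sd_floor)
    if sd ** 2 >= mean * (1.0 - mean):
        raise ParameterError("sd too large for a beta distribution with this mean")
    nu = mean * (1.0 - mean) / sd ** 2 - 1.0
    return mean * nu, (1.0 - mean) * nu


# ---------------------------------------------------------------------------
# Cost-parameter registry (the tornado's axes and the PSA's gamma draws)
# ---------------------------------------------------------------------------

#: (name, ParameterSet field, index within the field or None for scalars)
COST_PARAMS: tuple[tuple[str, str, int | None], ...] = (
    ("cost_hosp_mrs0_2", "cost_hosp", 0),
    ("cost_hosp_mrs3_5", "cost_hosp", 1),
    ("cost_hosp_mrs6", "cost_hosp", 2),
    ("cost_first90_mrs0_2", "cost_first90", 0),
    ("cost_first90_mrs3_5", "cost_first90", 1),
    ("cost_day91_365_mrs0_2", "cost_day91_365", 0),
    ("cost_day91_365_mrs3_5", "cost_day91_365", 1),
    ("cost_evt_addon", "cost_evt_addon", None),
    ("cost_stent_addon", "cost_stent_addon", None),
    ("cost_recurrent_acute", "cost_recurrent_acute", None),
    ("cost_longterm_mrs0", "cost_longterm_annual", 0),
    ("cost_longterm_mrs1", "cost_longterm_annual", 1),
    ("cost_longterm_mrs2", "cost_longterm_annual", 2),
    ("cost_longterm_mrs3", "cost_longterm_annual", 3),
    ("cost_longterm_mrs4", "cost_longterm_annual", 4),
    ("cost_longterm_mrs5", "cost_longterm_annual", 5),
)


def get_cost(p: ParameterSet, name: str) -> float:
    fieldname, idx = _cost_spec(name)
    val = getattr(p, fieldname)
    return float(val if idx is None else val[idx])


def set_cost(p: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a copy of ``p`` with one cost scalar replaced."""
    fieldname, idx = _cost_spec(name)
    out = p.copy()
    if idx is None:
        setattr(out, fieldname, float(value))
    else:
        seq = list(getattr(out, fieldname))
        seq[idx] = float(value)
        setattr(out, fieldname, tuple(seq))
    return out


def _cost_spec(name: str) -> tuple[str, int | None]:
    for n, f, i in COST_PARAMS:
        if n == name:
            return f, i
    raise ParameterError(f"unknown cost parameter {name!r}")


# ---------------------------------------------------------------------------
# Tornado (one-way cost sensitivity)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _icer_at(p: ParameterSet, lt: LifeTable) -> float:
    bmc = evaluate_strategy(STRATEGY_BMC, p, lt)
    evt = evaluate_strategy(STRATEGY_EVT, p, lt)
    return incremental_analysis(bmc, evt).icer_or_signed_ratio()


def tornado_analysis(p: ParameterSet, lt: LifeTable,
                     rel_range: float = 0.25) -> list[TornadoEntry]:
    """One-way sensitivity of the EVT-vs-BMC ICER to each cost input.

    Each cost is set to (1 +/- rel_range) x base with everything else at base
    case; entries come back sorted by descending ICER span. Dominant
    configurations are represented by the signed cost/QALY ratio so spans
    stay well defined.
    """
    if not 0.0 < rel_range < 1.0:
        raise ParameterError("rel_range must lie in (0, 1)")
    entries = []
    for name, _, _ in COST_PARAMS:
        base = get_cost(p, name)
        lo, hi = base * (1.0 - rel_range), base * (1.0 + rel_range)
        entries.append(TornadoEntry(
            parameter=name, low=lo, high=hi,
            icer_low=_icer_at(set_cost(p, name, lo), lt),
            icer_high=_icer_at(set_cost(p, name, hi), lt)))
    return sorted(entries, key=lambda e: e.span, reverse=True)


def age_sweep(p: ParameterSet, lt: LifeTable, ages) -> dict[int, CEAResult]:
    """Re-run the full EVT-vs-BMC comparison at each starting age."""
    out: dict[int, CEAResult] = {}
    for age in ages:
        q = p.replace(start_age=int(age))
        bmc = evaluate_strategy(STRATEGY_BMC, q, lt)
        evt = evaluate_strategy(STRATEGY_EVT, q, lt)
        out[int(age)] = incremental_analysis(bmc, evt)
    return out


# ---------------------------------------------------------------------------
# Linear accounting components (exact per-draw evaluation for the PSA)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafComponents:
    """Sufficient statistics of one leaf run for cost/utility re-pricing.

    With transition dynamics fixed, the leaf's discounted cost is linear in
    the cost inputs and its discounted QALYs linear in the utilities:

    cost  = e02*(hosp02+f90_02+d91_02) + e35*(hosp35+f90_35+d91_35) + e6*hosp6
            + [EVT]*evt_addon + [stented]*stent_addon
            + sum_s occ_from2[s]*longterm[s] + rec_mass*recurrent_cost
    qaly  = sum_s occ_all[s]*utility[s]
    """

    weight: float
    is_evt: bool
    stented: bool
    entry_groups: tuple[float, float, float]      # mass in mRS 0-2 / 3-5 / 6
    disc_occ_all: tuple[float, ...]               # (6,) discounted state-years, all cycles
    disc_occ_from2: tuple[float, ...]             # (6,) discounted state-years, cycles >= 2
    disc_rec_mass: float                          # discounted recurrence incidence

    def cost(self, costs: dict[str, np.ndarray | float]):
        e02, e35, e6 = self.entry_groups
        lt_names = [f"cost_longterm_mrs{s}" for s in range(6)]
        total = (e02 * (costs["cost_hosp_mrs0_2"] + costs["cost_first90_mrs0_2"]
                        + costs["cost_day91_365_mrs0_2"])
                 + e35 * (costs["cost_hosp_mrs3_5"] + costs["cost_first90_mrs3_5"]
                          + costs["cost_day91_365_mrs3_5"])
                 + e6 * costs["cost_hosp_mrs6"]
                 + self.disc_rec_mass * costs["cost_recurrent_acute"])
        for s, nm in enumerate(lt_names):
            total = total + self.disc_occ_from2[s] * costs[nm]
        if self.is_evt:
            total = total + costs["cost_evt_addon"]
        if self.stented:
            total = total + costs["cost_stent_addon"]
        return total

    def qaly(self, utilities: np.ndarray):
        u = np.asarray(utilities)
        coeff = np.asarray(self.disc_occ_all)
        return u @ coeff if u.ndim == 1 else u @ coeff


def leaf_components(sc: markov.SubCohort, p: ParameterSet, lt: LifeTable,
                    horizon: int | None = None) -> LeafComponents:
    trace = run_cohort(sc, p, lt, horizon)
    entry = sc_entry_distribution(sc, p).as_array()
    disc = trace.discount_factors
    occ = trace.occupancy[:, 0:6]
    w_all = disc.copy()
    if p.half_cycle_correction:
        w_all[0] *= 0.5
    disc_occ_all = w_all @ occ
    if p.half_cycle_correction:
        disc_occ_all = disc_occ_all + 0.5 * disc[-1] / (1.0 + p.discount_rate) * occ[-1]
    disc_occ_from2 = disc[1:] @ occ[1:] if trace.n_cycles > 1 else np.zeros(6)
    disc_rec = float(disc @ trace.recurrence_mass)
    return LeafComponents(
        weight=sc.weight,
        is_evt=sc.strategy == STRATEGY_EVT,
        stented=sc.stented,
        entry_groups=markov._entry_groups(entry),
        disc_occ_all=tuple(disc_occ_all),
        disc_occ_from2=tuple(np.asarray(disc_occ_from2)),
        disc_rec_mass=disc_rec,
    )


def strategy_components(strategy: str, p: ParameterSet, lt: LifeTable,
                        horizon: int | None = None) -> list[LeafComponents]:
    return [leaf_components(sc, p, lt, horizon)
            for sc in build_subcohorts(strategy, p)]


def reprice(components: list[LeafComponents], costs: dict, utilities: np.ndarray):
    """Strategy (cost, qaly) under new cost/utility values (scalar or vectorized)."""
    cost = sum(c.weight * c.cost(costs) for c in components)
    qaly = sum(c.weight * c.qaly(utilities) for c in components)
    return cost, qaly


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PsaResult:
    n_iter: int
    seed: int
    cost_cv: float
    util_cv: float
    incr_cost: np.ndarray      # (n_iter,)
    incr_qaly: np.ndarray      # (n_iter,)
    cost_bmc: np.ndarray
    cost_evt: np.ndarray
    qaly_bmc: np.ndarray
    qaly_evt: np.ndarray
    draws: "object" = None     # pandas DataFrame of drawn parameter values

    def prob_cost_effective(self, wtp: float) -> float:
        """Share of iterations in which EVT has positive net monetary benefit."""
        return float(np.mean(wtp * self.incr_qaly - self.incr_cost > 0.0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "iteration": np.arange(1, self.n_iter + 1),
            "incr_cost": self.incr_cost, "incr_qaly": self.incr_qaly,
            "cost_bmc": self.cost_bmc, "cost_evt": self.cost_evt,
            "qaly_bmc": self.qaly_bmc, "qaly_evt": self.qaly_evt})


def run_psa(p: ParameterSet, lt: LifeTable, n_iter: int, seed: int,
            cost_cv: float = 0.25, util_cv: float = 0.10) -> PsaResult:
    """Monte Carlo parameter-uncertainty analysis of EVT vs BMC.

    Per iteration every cost input is drawn from its method-of-moments gamma
    (sd = ``cost_cv`` x mean) and every utility strictly inside (0, 1) from
    its method-of-moments beta (sd = ``util_cv`` x mean); utilities of 0 or 1
    and all probabilities/ratios are held fixed. Both strategies are priced
    from the same draw (common random numbers). Fully reproducible per seed.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    if cost_cv < 0 or util_cv < 0:
        raise ParameterError("coefficients of variation must be non-negative")
    import pandas as pd

    rng = np.random.default_rng(seed)

    cost_draws: dict[str, np.ndarray] = {}
    for name, _, _ in COST_PARAMS:
        mean = get_cost(p, name)
        if cost_cv == 0.0 or mean == 0.0:
            cost_draws[name] = np.full(n_iter, mean)
        else:
            shape, scale = fit_gamma(mean, cost_cv * mean)
            cost_draws[name] = rng.gamma(shape, scale, size=n_iter)

    util_draws = np.empty((n_iter, 6))
    for s, mean in enumerate(p.utilities):
        if util_cv == 0.0 or mean <= 0.0 or mean >= 1.0:
            util_draws[:, s] = mean
        else:
            a, b = fit_beta(mean, util_cv * mean)
            util_draws[:, s] = rng.beta(a, b, size=n_iter)

    comp_bmc = strategy_components(STRATEGY_BMC, p, lt)
    comp_evt = strategy_components(STRATEGY_EVT, p, lt)
    cost_bmc, qaly_bmc = reprice(comp_bmc, cost_draws, util_draws)
    cost_evt, qaly_evt = reprice(comp_evt, cost_draws, util_draws)

    draws = pd.DataFrame(cost_draws)
    for s in range(6):
        draws[f"utility_mrs{s}"] = util_draws[:, s]

    return PsaResult(
        n_iter=n_iter, seed=seed, cost_cv=cost_cv, util_cv=util_cv,
        incr_cost=np.asarray(cost_evt - cost_bmc, dtype=float),
        incr_qaly=np.asarray(qaly_evt - qaly_bmc, dtype=float),
        cost_bmc=np.asarray(cost_bmc, dtype=float),
        cost_evt=np.asarray(cost_evt, dtype=float),
        qaly_bmc=np.asarray(qaly_bmc, dtype=float),
        qaly_evt=np.asarray(qaly_evt, dtype=float),
        draws=draws)


# ---------------------------------------------------------------------------
# Acceptability curve
# ---------------------------------------------------------------------------

#: Default WTP grid for the acceptability curve: $0..$200,000 in $250 steps.
#: The step bounds the crossover estimate's resolution.
DEFAULT_WTP_GRID = np.arange(0.0, 200_000.0 + 1, 250.0)


@dataclass(frozen=True)
class CeacCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        if len(self.wtp) != len(self.probability) or len(self.wtp) == 0:
            raise ParameterError("curve needs matching non-empty wtp/probability arrays")
        if np.any(np.diff(self.wtp) <= 0):
            raise ParameterError("wtp grid must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(r: PsaResult, wtp_grid=None) -> CeacCurve:
    """Probability that EVT is cost-effective at each willingness to pay."""
    grid = np.asarray(DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("empty WTP grid")
    nmb = grid[:, None] * r.incr_qaly[None, :] - r.incr_cost[None, :]
    return CeacCurve(wtp=grid, probability=(nmb > 0.0).mean(axis=1))


def crossover_wtp(c: CeacCurve, threshold: float = 0.5) -> float | None:
    """Smallest grid WTP where the acceptability probability exceeds
    ``threshold``; None if the curve never crosses."""
    above = np.nonzero(c.probability > threshold)[0]
    if above.size == 0:
        return None
    return float(c.wtp[above[0]])
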